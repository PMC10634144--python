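"""Small-RNA read cleaning, annotation classing, and length statistics.

Implements the front end of the sRNA pipeline: 3' adapter trimming with
length/quality/homopolymer filters, priority-ordered assignment of reads to
annotation classes (rRNA > tRNA > snRNA > snoRNA > other Rfam > repeat >
mRNA, remainder = valid sRNA), the 18-25 nt length distribution in
count-weighted (total) and distinct-sequence (unique) modes, and the
24/21-nt abundance ratio used as a proxy for RdDM-associated siRNA load.
"""

from __future__ import annotations

from dataclasses import dataclass

import math

import pandas as pd

MIN_LENGTH = 18
MAX_LENGTH = 25
HOMOPOLYMER_FRACTION = 0.8
MAX_N_FRACTION = 0.10
MIN_MEAN_QUALITY = 20.0

#: Assignment priority; a read joins the first class whose sequences contain it.
ANNOTATION_PRIORITY = ("rRNA", "tRNA", "snRNA", "snoRNA", "other", "repeat", "mRNA")
VALID_CLASS = "VsRNA"


@dataclass(frozen=True)
class ReadRecord:
    sequence: str
    count: int = 1

    @property
    def length(self) -> int:
        return len(self.sequence)


def _is_homopolymer(seq: str) -> bool:
    if not seq:
        return True
    top = max(seq.count(b) for b in "ACGTU")
    return top / len(seq) >= HOMOPOLYMER_FRACTION


def clean_reads(
    raw: list[ReadRecord],
    adapter3: str,
    qualities: dict | None = None,
) -> list[ReadRecord]:
    """Trim the 3' adapter and drop low-quality / off-length reads.

    The adapter is removed at its leftmost exact occurrence at or after
    position 18 (so the insert keeps at least the minimum length).  Reads
    are retained iff 18 <= length <= 25 after trimming, N content <= 10%,
    and no single base makes up >= 80% of the read.  ``qualities`` may map a
    sequence to its phred scores (FASTQ input); reads with mean quality
    below 20 are dropped.
    """
    if not adapter3:
        raise ValueError("adapter3 must be non-empty")
    adapter3 = adapter3.upper()
    cleaned: dict[str, int] = {}
    for rec in raw:
        seq = rec.sequence.upper()
        if qualities and seq in qualities:
            quals = qualities[seq]
            if quals and sum(quals) / len(quals) < MIN_MEAN_QUALITY:
                continue
        hit = seq.find(adapter3, MIN_LENGTH)
        if hit != -1:
            seq = seq[:hit]
        if not MIN_LENGTH <= len(seq) <= MAX_LENGTH:
            continue
        if seq.count("N") / len(seq) > MAX_N_FRACTION:
            continue
        if _is_homopolymer(seq):
            continue
        cleaned[seq] = cleaned.get(seq, 0) + rec.count
    return [ReadRecord(seq, count) for seq, count in cleaned.items()]


def annotate_reads(
    reads: list[ReadRecord], annotation_sets: dict[str, dict[str, str] | list[str]]
) -> pd.DataFrame:
    """Classify reads against annotation sequence sets.

    A read is assigned to the first class (in ``ANNOTATION_PRIORITY`` order)
    where it occurs as an exact substring of any annotation sequence;
    unmatched reads are valid sRNAs (``VsRNA``).  Returns a table with one
    row per class and ``total`` (count-weighted) and ``unique`` columns,
    conserving the cleaned-read totals.
    """
    normalized: dict[str, list[str]] = {}
    for cls, seqs in annotation_sets.items():
        values = seqs.values() if isinstance(seqs, dict) else seqs
        normalized[cls] = [s.upper() for s in values]

    totals = {cls: 0 for cls in ANNOTATION_PRIORITY + (VALID_CLASS,)}
    uniques = dict(totals)
    assignments = {}
    for rec in reads:
        assigned = VALID_CLASS
        for cls in ANNOTATION_PRIORITY:
            if any(rec.sequence in ref for ref in normalized.get(cls, ())):
                assigned = cls
                break
        assignments[rec.sequence] = assigned
        totals[assigned] += rec.count
        uniques[assigned] += 1
    table = pd.DataFrame(
        {
            "class": list(totals),
            "total": list(totals.values()),
            "unique": list(uniques.values()),
        }
    )
    table.attrs["assignments"] = assignments
    return table


def length_distribution(reads: list[ReadRecord], mode: str = "total") -> pd.DataFrame:
    """Proportion of reads per length 18-25.

    ``total`` weights each sequence by its count; ``unique`` weighs every
    distinct sequence once.  An empty input yields an all-zero table with
    ``attrs['degenerate'] = True``.
    """
    if mode not in ("total", "unique"):
        raise ValueError("mode must be 'total' or 'unique'")
    weights = {length: 0.0 for length in range(MIN_LENGTH, MAX_LENGTH + 1)}
    for rec in reads:
        if rec.length in weights:
            weights[rec.length] += rec.count if mode == "total" else 1
    total = sum(weights.values())
    table = pd.DataFrame(
        {
            "length": list(weights),
            "proportion": [w / total if total else 0.0 for w in weights.values()],
        }
    )
    table.attrs["degenerate"] = total == 0
    return table


def ratio_24_21(dist: pd.DataFrame) -> float:
    """24-nt over 21-nt proportion; NaN when 21-nt abundance is zero."""
    by_length = dict(zip(dist["length"], dist["proportion"]))
    p21 = by_length.get(21, 0.0)
    p24 = by_length.get(24, 0.0)
    if p21 == 0.0:
        return math.nan
    return p24 / p21
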