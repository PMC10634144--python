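"""Readers and writers for the plain-text formats used across the pipeline.

Small-RNA and degradome libraries are exchanged as collapsed FASTA in which
the header carries the read count (``>id_xCOUNT``), the convention used by
most sRNA pipelines.  Everything tabular goes through pandas TSV.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

_COUNT_RE = re.compile(r"_x(\d+)$")


def read_count_fasta(path: str | Path) -> list[tuple[str, str, int]]:
    """Read a collapsed FASTA; returns (id, sequence, count) triples.

    Headers without an ``_xCOUNT`` suffix get count 1.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        m = _COUNT_RE.search(rec.id)
        count = int(m.group(1)) if m else 1
        records.append((rec.id, str(rec.seq).upper(), count))
    return records


def write_count_fasta(path: str | Path, reads: Iterable[tuple[str, str, int]]) -> None:
    with open(path, "w") as fh:
        for rid, seq, count in reads:
            fh.write(f">{rid}_x{count}\n{seq}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Plain FASTA → ordered {id: sequence} map (uppercased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, seqs: Mapping[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path: str | Path) -> list[tuple[str, str, list[int]]]:
    """FASTQ → (id, sequence, phred qualities) records."""
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        out.append((rec.id, str(rec.seq).upper(), rec.letter_annotations["phred_quality"]))
    return out


def write_fastq(path: str | Path, reads: Iterable[tuple[str, str, int]], quality: int = 35) -> None:
    """Write collapsed reads as FASTQ, replicating the count in the header."""
    qchar = chr(quality + 33)
    with open(path, "w") as fh:
        for rid, seq, count in reads:
            fh.write(f"@{rid}_x{count}\n{seq}\n+\n{qchar * len(seq)}\n")


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def loci_to_bed(loci: pd.DataFrame) -> pd.DataFrame:
    """1-based inclusive locus table → BED6 (0-based half-open)."""
    bed = pd.DataFrame(
        {
            "chrom": loci["chromosome"],
            "start": loci["start"] - 1,
            "end": loci["end"],
            "name": loci["precursor_id"],
            "score": 0,
            "strand": loci["strand"],
        }
    )
    return bed


def bed_to_loci(bed: pd.DataFrame) -> pd.DataFrame:
    """BED6 → 1-based inclusive locus table."""
    return pd.DataFrame(
        {
            "precursor_id": bed.iloc[:, 3],
            "chromosome": bed.iloc[:, 0],
            "start": bed.iloc[:, 1] + 1,
            "end": bed.iloc[:, 2],
            "strand": bed.iloc[:, 5] if bed.shape[1] > 5 else "+",
        }
    )
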