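"""Degradome (PARE) tag mapping and miRNA cleavage-site identification.

Tags (>= 15 nt) are mapped to transcripts by exact matching only; the tag's
5' position marks a candidate uncapped cleavage end, and per-transcript
abundance profiles accumulate the counts.  miRNAs are aligned antisense to
transcripts under an Allen-style penalty scheme (mismatch 1, G:U wobble
0.5, single-nucleotide gap 1, at most one gap, penalties doubled opposite
miRNA positions 2-13) with a total-score ceiling of 4.  The cleavage site
(TSlice) is the transcript position paired with miRNA nucleotide 10 or 11,
whichever carries more degradome signal (ties to nucleotide 10), and each
event is ranked into categories 0-4 by how its abundance compares with the
rest of the transcript profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_MAX_SCORE = 4.0
MIN_TAG_LENGTH = 15
CORE_START, CORE_END = 2, 13  # miRNA positions with doubled penalties

_ENCODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}

# penalty[mirna_base, target_base]; complement 0, G:U wobble 0.5, else 1
_PENALTY = np.ones((5, 5))
for _m, _t in ((0, 3), (1, 2), (2, 1), (3, 0)):  # A:T C:G G:C T:A
    _PENALTY[_m, _t] = 0.0
_PENALTY[2, 3] = 0.5  # miRNA G opposite target T (G:U wobble)
_PENALTY[3, 2] = 0.5  # miRNA U opposite target G


def _encode(seq: str) -> np.ndarray:
    return np.array([_ENCODE.get(b, 4) for b in seq.upper()], dtype=np.int8)


@dataclass(frozen=True)
class DegradomeTag:
    sequence: str
    count: int
    transcript_id: str
    five_prime_position: int  # 1-based on the transcript


def map_tags(tags, transcripts: dict[str, str]):
    """Place tags on transcripts by exact substring match.

    ``tags`` is an iterable of (id, sequence, count); tags shorter than 15
    nt are rejected before mapping.  A tag contributes its full count at
    every matching position of every transcript (multi-mapping tags are not
    split).  Returns (placements, profiles) where profiles maps transcript
    id to a per-position abundance vector (index 0 = position 1).
    """
    upper = {tid: seq.upper() for tid, seq in transcripts.items()}
    profiles = {tid: np.zeros(len(seq), dtype=float) for tid, seq in upper.items()}
    placements: list[DegradomeTag] = []
    for _tag_id, seq, count in tags:
        seq = seq.upper()
        if len(seq) < MIN_TAG_LENGTH:
            continue
        for tid, tseq in upper.items():
            start = tseq.find(seq)
            while start != -1:
                placements.append(DegradomeTag(seq, count, tid, start + 1))
                profiles[tid][start] += count
                start = tseq.find(seq, start + 1)
    return placements, profiles


@dataclass
class TargetSite:
    transcript_id: str
    tstart: int  # 1-based inclusive transcript region paired to the miRNA
    tstop: int
    score: float
    pairing: dict = field(default_factory=dict)  # miRNA nt (1-based) -> transcript pos


def _weights(length: int) -> np.ndarray:
    w = np.ones(length)
    w[CORE_START - 1 : CORE_END] = 2.0
    return w


def align_mirna_target(
    mirna: str,
    transcript: str,
    transcript_id: str = "",
    max_score: float = DEFAULT_MAX_SCORE,
) -> list[TargetSite]:
    """All antisense duplex sites scoring at most ``max_score``.

    The duplex pairs the miRNA 5'->3' against the transcript 3'->5', so
    miRNA nucleotide k sits opposite transcript position TStart + L - k.
    One single-nucleotide gap is allowed on either strand (penalty 1,
    doubled when it falls in the 2-13 core).
    """
    m = _encode(mirna)
    t = _encode(transcript)
    L = len(m)
    if not 18 <= L <= 25:
        raise ValueError("miRNA length must be 18-25 nt")
    n = len(t)
    w = _weights(L)
    sites: list[TargetSite] = []

    # --- gapless scan ----------------------------------------------------
    nw = n - L + 1
    if nw > 0:
        scores = np.zeros(nw)
        for k in range(1, L + 1):
            scores += w[k - 1] * _PENALTY[m[k - 1], t[L - k : L - k + nw]]
        for s0 in np.nonzero(scores <= max_score)[0]:
            pairing = {k: int(s0) + L - k + 1 for k in range(1, L + 1)}
            sites.append(
                TargetSite(transcript_id, int(s0) + 1, int(s0) + L, float(scores[s0]), pairing)
            )

    # --- one gap in the target (miRNA nucleotide g unpaired) -------------
    nw = n - (L - 1) + 1
    if nw > 0:
        for g in range(2, L):
            gap_pen = 2.0 if CORE_START <= g <= CORE_END else 1.0
            scores = np.full(nw, gap_pen)
            offsets = {}
            for k in range(1, L + 1):
                if k == g:
                    continue
                idx = k - 1 if k < g else k - 2
                offsets[k] = (L - 2) - idx
                scores += w[k - 1] * _PENALTY[m[k - 1], t[offsets[k] : offsets[k] + nw]]
            for s0 in np.nonzero(scores <= max_score)[0]:
                pairing = {k: int(s0) + offsets[k] + 1 for k in offsets}
                pairing[g] = 0  # unpaired
                sites.append(
                    TargetSite(transcript_id, int(s0) + 1, int(s0) + L - 1,
                               float(scores[s0]), pairing)
                )

    # --- one gap in the miRNA (bulged target base at window offset jb) ---
    nw = n - (L + 1) + 1
    if nw > 0:
        for jb in range(1, L):
            flank = L - jb  # bulge sits between miRNA nts flank and flank+1
            gap_pen = 2.0 if CORE_START <= flank <= CORE_END - 1 else 1.0
            scores = np.full(nw, gap_pen)
            offsets = {}
            for k in range(1, L + 1):
                idx = L - k
                off = idx if idx < jb else idx + 1
                offsets[k] = off
                scores += w[k - 1] * _PENALTY[m[k - 1], t[off : off + nw]]
            for s0 in np.nonzero(scores <= max_score)[0]:
                pairing = {k: int(s0) + offsets[k] + 1 for k in offsets}
                sites.append(
                    TargetSite(transcript_id, int(s0) + 1, int(s0) + L + 1,
                               float(scores[s0]), pairing)
                )

    sites.sort(key=lambda s: (s.score, s.tstart, s.tstop))
    return sites


def locate_slice(site: TargetSite, profiles: dict) -> int | None:
    """Transcript position cleaved by the site's miRNA, or None.

    Candidates are the positions paired with miRNA nucleotides 10 and 11;
    the one with more degradome signal wins, ties (and missing nt-11
    pairing) resolve to nucleotide 10.  Returns None when neither position
    carries any signal (the event is dropped).
    """
    profile = profiles[site.transcript_id]

    def abundance(pos: int | None) -> float:
        if not pos or not 1 <= pos <= len(profile):
            return 0.0
        return float(profile[pos - 1])

    p10 = site.pairing.get(10) or None
    p11 = site.pairing.get(11) or None
    a10, a11 = abundance(p10), abundance(p11)
    if a10 == 0.0 and a11 == 0.0:
        return None
    if p10 and a10 >= a11:
        return p10
    return p11 if p11 else p10


def categorize_event(profile: np.ndarray, tslice: int) -> int:
    """Degradome evidence category 0-4 for a cleavage position.

    4: exactly one read; 0: the unique profile maximum; 1: tied for the
    maximum; 2: above the median of the nonzero positions but below the
    maximum; 3: anything else.
    """
    abundance = float(profile[tslice - 1])
    if abundance <= 0:
        raise ValueError("no degradome signal at the slice position")
    if abundance == 1:
        return 4
    maximum = float(profile.max())
    if abundance == maximum:
        return 0 if int((profile == maximum).sum()) == 1 else 1
    nonzero = profile[profile > 0]
    if abundance > float(np.median(nonzero)):
        return 2
    return 3


@dataclass
class CleavageEvent:
    mirna: str
    transcript_id: str
    tstart: int
    tstop: int
    tslice: int
    alignment_score: float
    category: int
    slice_abundance: float


def find_cleavage_events(
    mirnas: dict[str, str],
    transcripts: dict[str, str],
    profiles: dict,
    max_score: float = DEFAULT_MAX_SCORE,
) -> list[CleavageEvent]:
    """Scan every miRNA against every transcript and emit supported events.

    For each (miRNA, transcript) pair only the best-scoring site per slice
    position is kept.
    """
    events = []
    for name, mseq in mirnas.items():
        for tid, tseq in transcripts.items():
            if tid not in profiles:
                continue
            seen: set[int] = set()
            for site in align_mirna_target(mseq, tseq, tid, max_score=max_score):
                tslice = locate_slice(site, profiles)
                if tslice is None or tslice in seen:
                    continue
                seen.add(tslice)
                events.append(
                    CleavageEvent(
                        mirna=name,
                        transcript_id=tid,
                        tstart=site.tstart,
                        tstop=site.tstop,
                        tslice=tslice,
                        alignment_score=site.score,
                        category=categorize_event(profiles[tid], tslice),
                        slice_abundance=float(profiles[tid][tslice - 1]),
                    )
                )
    return events


def events_to_frame(events: list[CleavageEvent]) -> pd.DataFrame:
    rows = [
        {
            "mirna": e.mirna,
            "transcript_id": e.transcript_id,
            "tstart": e.tstart,
            "tstop": e.tstop,
            "tslice": e.tslice,
            "alignment_score": e.alignment_score,
            "category": e.category,
            "slice_abundance": e.slice_abundance,
        }
        for e in events
    ]
    return pd.DataFrame(
        rows,
        columns=["mirna", "transcript_id", "tstart", "tstop", "tslice",
                 "alignment_score", "category", "slice_abundance"],
    )


def tplot_data(profile: np.ndarray, events: list[CleavageEvent]) -> pd.DataFrame:
    """Per-position abundance table with slice positions flagged (T-plot)."""
    slices = {e.tslice for e in events}
    return pd.DataFrame(
        {
            "position": np.arange(1, len(profile) + 1),
            "abundance": profile,
            "is_slice": [p in slices for p in range(1, len(profile) + 1)],
        }
    )
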