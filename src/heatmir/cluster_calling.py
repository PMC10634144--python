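"""Pre-miRNA cluster (PmC) calling at a genomic spacing threshold.

Precursor loci on one chromosome are chained whenever the end-to-start gap
to the next locus is at most 50 kb (configurable); maximal chains with at
least two distinct precursors become clusters, numbered PmC1, PmC2, ... in
genome order.  Strand is ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

DEFAULT_MAX_GAP = 50_000


@dataclass
class PmC:
    cluster_id: str
    chromosome: str
    start: int  # 1-based inclusive span
    end: int
    precursor_ids: list = field(default_factory=list)
    mirna_names: list = field(default_factory=list)
    dem_names: list = field(default_factory=list)


def _as_locus_frame(loci) -> pd.DataFrame:
    df = pd.DataFrame(loci) if not isinstance(loci, pd.DataFrame) else loci.copy()
    required = {"precursor_id", "chromosome", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"locus table missing columns: {sorted(missing)}")
    if len(df) and (df["start"] > df["end"]).any():
        raise ValueError("locus with start > end")
    if "mirna" not in df.columns:
        df["mirna"] = df["precursor_id"]
    return df


def call_clusters(loci, max_gap: int = DEFAULT_MAX_GAP) -> list[PmC]:
    """Chain loci per chromosome into clusters of >= 2 precursors.

    Chaining is pairwise: each successive locus joins the chain if the gap
    from the previous chain end (``next.start - chain.end``) is at most
    ``max_gap``, so a cluster's total span may exceed the threshold.
    """
    df = _as_locus_frame(loci)
    clusters: list[PmC] = []
    for chrom in sorted(df["chromosome"].unique()):
        sub = df[df["chromosome"] == chrom].sort_values(["start", "end", "precursor_id"])
        chain: list[pd.Series] = []
        chain_end = None
        for _, row in sub.iterrows():
            if chain and row["start"] - chain_end > max_gap:
                if len(chain) >= 2:
                    clusters.append(_make_cluster(chrom, chain))
                chain = []
                chain_end = None
            chain.append(row)
            chain_end = row["end"] if chain_end is None else max(chain_end, row["end"])
        if len(chain) >= 2:
            clusters.append(_make_cluster(chrom, chain))
    for i, c in enumerate(clusters, start=1):
        c.cluster_id = f"PmC{i}"
    return clusters


def _make_cluster(chrom: str, chain: list) -> PmC:
    return PmC(
        cluster_id="",
        chromosome=chrom,
        start=int(min(r["start"] for r in chain)),
        end=int(max(r["end"] for r in chain)),
        precursor_ids=[r["precursor_id"] for r in chain],
        mirna_names=[r["mirna"] for r in chain],
    )


def annotate_dems(pmcs: list[PmC], dem_names) -> list[PmC]:
    """Fill each cluster's DEM member list from a set of DEM names."""
    dems = set(dem_names)
    for c in pmcs:
        c.dem_names = [m for m in c.mirna_names if m in dems]
    return pmcs


def summarize_clusters(pmcs: list[PmC], dem_names=()) -> pd.DataFrame:
    """Per-chromosome cluster / miRNA / DEM counts with a total row."""
    annotate_dems(pmcs, dem_names)
    rows = {}
    for c in pmcs:
        entry = rows.setdefault(c.chromosome, {"n_clusters": 0, "n_mirnas": 0, "n_dems": 0})
        entry["n_clusters"] += 1
        entry["n_mirnas"] += len(c.mirna_names)
        entry["n_dems"] += len(c.dem_names)
    table = (
        pd.DataFrame.from_dict(rows, orient="index")
        .rename_axis("chromosome")
        .sort_index()
        .reset_index()
    )
    if table.empty:
        table = pd.DataFrame(columns=["chromosome", "n_clusters", "n_mirnas", "n_dems"])
    total = pd.DataFrame(
        [{
            "chromosome": "total",
            "n_clusters": int(table["n_clusters"].sum()) if len(table) else 0,
            "n_mirnas": int(table["n_mirnas"].sum()) if len(table) else 0,
            "n_dems": int(table["n_dems"].sum()) if len(table) else 0,
        }]
    )
    return pd.concat([table, total], ignore_index=True)


def overlap_with_interval(pmcs: list[PmC], chromosome: str, start: int, end: int) -> list[PmC]:
    """Clusters whose span intersects a 1-based inclusive interval."""
    if start > end:
        raise ValueError("interval start > end")
    return [
        c for c in pmcs
        if c.chromosome == chromosome and c.start <= end and c.end >= start
    ]


def clusters_to_frame(pmcs: list[PmC]) -> pd.DataFrame:
    rows = [
        {
            "cluster_id": c.cluster_id,
            "chromosome": c.chromosome,
            "start": c.start,
            "end": c.end,
            "n_precursors": len(c.precursor_ids),
            "precursor_ids": ",".join(map(str, c.precursor_ids)),
            "mirna_names": ",".join(map(str, c.mirna_names)),
            "dem_names": ",".join(map(str, c.dem_names)),
        }
        for c in pmcs
    ]
    return pd.DataFrame(
        rows,
        columns=["cluster_id", "chromosome", "start", "end", "n_precursors",
                 "precursor_ids", "mirna_names", "dem_names"],
    )
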