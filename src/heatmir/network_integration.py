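"""Integration of DEM, DEG, and degradome evidence into regulatory pairs.

A regulatory pair joins a differentially expressed miRNA to a
differentially expressed target gene through a degradome-supported
cleavage event in the same contrast.  Pairs carry a pattern label from the
two direction signs (up-down, down-up, up-up, down-down); the
negative-regulation subset (up-down / down-up) feeds the
miRNA - transcript - gene - pathway network export.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import networkx as nx
import pandas as pd

NEGATIVE_PATTERNS = ("up-down", "down-up")
PATTERNS = ("up-down", "down-up", "up-up", "down-down")


@dataclass
class RegulatoryPair:
    mirna: str
    transcript_id: str
    gene_id: str
    gene_symbol: str
    mirna_log2fc: float
    mirna_direction: str
    mrna_log2fc: float
    mrna_direction: str
    pattern: str
    contrast: str = ""
    tslice: int = 0

    def __post_init__(self):
        expected = f"{self.mirna_direction}-{self.mrna_direction}"
        if self.pattern != expected:
            raise ValueError(f"pattern {self.pattern!r} inconsistent with directions")


def load_reference_pairs() -> pd.DataFrame:
    """The 35 curated degradome-supported negative miRNA-mRNA pairs from
    cotton pollen under heat stress, shipped with the package."""
    with resources.files("heatmir.data").joinpath("cotton_negative_pairs.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def pairs_from_frame(df: pd.DataFrame) -> list[RegulatoryPair]:
    """Build pairs from a table with miRNA/target log2FC and regulation
    columns (as in the curated reference table)."""
    pairs = []
    for _, row in df.iterrows():
        up = str(row["mirna_regulation"]).lower()
        down = str(row["target_regulation"]).lower()
        pairs.append(
            RegulatoryPair(
                mirna=row["mirna"],
                transcript_id=row["transcript"],
                gene_id=row.get("gene", row["transcript"]),
                gene_symbol=row.get("gene", ""),
                mirna_log2fc=float(row["mirna_log2fc"]),
                mirna_direction=up,
                mrna_log2fc=float(row["target_log2fc"]),
                mrna_direction=down,
                pattern=f"{up}-{down}",
                tslice=int(row.get("tslice", 0)),
            )
        )
    return pairs


def build_pairs(
    dems: pd.DataFrame,
    degs: pd.DataFrame,
    events,
    gene_map: pd.DataFrame,
    require_cleavage: bool = True,
) -> list[RegulatoryPair]:
    """Join the three evidence layers into pairs.

    ``dems``/``degs`` are de_test result frames (features are miRNA names
    and gene ids respectively; only up/down rows are used).  ``events`` is a
    list of CleavageEvent or an equivalent frame; ``gene_map`` maps
    transcript_id -> gene_id.  Transcripts without a gene mapping are
    dropped.  With ``require_cleavage=False`` every DEM x DEG combination
    sharing a predicted event is kept even without degradome support
    (exploratory mode; events must then still provide the linkage).
    """
    t2g = dict(zip(gene_map["transcript_id"], gene_map["gene_id"]))
    dem_rows = dems[dems["direction"].isin(["up", "down"])]
    deg_rows = degs[degs["direction"].isin(["up", "down"])]
    dem_info = {r["feature"]: r for _, r in dem_rows.iterrows()}
    deg_info = {r["feature"]: r for _, r in deg_rows.iterrows()}

    if not isinstance(events, pd.DataFrame):
        from .degradome_targets import events_to_frame

        events = events_to_frame(events)
    if require_cleavage is False and "supported" in events.columns:
        pass  # predicted-only rows already included by the caller

    pairs = []
    seen = set()
    for _, ev in events.iterrows():
        mirna, tid = ev["mirna"], ev["transcript_id"]
        if (mirna, tid) in seen:
            continue
        gene = t2g.get(tid)
        if gene is None:
            continue
        if mirna not in dem_info or gene not in deg_info:
            continue
        seen.add((mirna, tid))
        dem = dem_info[mirna]
        deg = deg_info[gene]
        pairs.append(
            RegulatoryPair(
                mirna=mirna,
                transcript_id=tid,
                gene_id=gene,
                gene_symbol=gene,
                mirna_log2fc=float(dem["log2fc"]),
                mirna_direction=dem["direction"],
                mrna_log2fc=float(deg["log2fc"]),
                mrna_direction=deg["direction"],
                pattern=f"{dem['direction']}-{deg['direction']}",
                contrast=str(dem.get("contrast", "")),
                tslice=int(ev.get("tslice", 0)),
            )
        )
    return pairs


def filter_negative(pairs: list[RegulatoryPair]) -> list[RegulatoryPair]:
    """Pairs with opposite expression directions, order preserved."""
    return [p for p in pairs if p.pattern in NEGATIVE_PATTERNS]


def pattern_counts(pairs: list[RegulatoryPair]) -> dict[str, int]:
    counts = {p: 0 for p in PATTERNS}
    for pair in pairs:
        counts[pair.pattern] = counts.get(pair.pattern, 0) + 1
    return counts


def count_multi_target(pairs: list[RegulatoryPair]) -> tuple[int, int, int]:
    """(n_pairs, n_multi_target_mirnas, n_one_to_one_mirnas).

    A miRNA is multi-target when it hits >= 2 distinct transcripts.
    """
    if not pairs:
        raise ValueError("no pairs to count")
    targets: dict[str, set] = {}
    for p in pairs:
        targets.setdefault(p.mirna, set()).add(p.transcript_id)
    multi = sum(1 for t in targets.values() if len(t) >= 2)
    single = sum(1 for t in targets.values() if len(t) == 1)
    return len(pairs), multi, single


def export_network(
    pairs: list[RegulatoryPair], pathway_map: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, nx.DiGraph]:
    """Node and edge tables plus a graph for the regulatory network.

    Nodes are typed miRNA / transcript / gene / pathway; miRNA->transcript
    edges carry the inhibitory flag, transcript->gene and gene->pathway
    edges do not.  Genes absent from ``pathway_map`` (gene_id, pathway
    columns) simply have no pathway edge.
    """
    graph = nx.DiGraph()
    for p in pairs:
        graph.add_node(p.mirna, node_type="miRNA")
        graph.add_node(p.transcript_id, node_type="transcript")
        graph.add_node(p.gene_id, node_type="gene")
        graph.add_edge(p.mirna, p.transcript_id, edge_type="targets", inhibitory=True)
        graph.add_edge(p.transcript_id, p.gene_id, edge_type="transcript_of", inhibitory=False)
    if pathway_map is not None and len(pathway_map):
        genes = {p.gene_id for p in pairs}
        for _, row in pathway_map.iterrows():
            if row["gene_id"] in genes:
                graph.add_node(row["pathway"], node_type="pathway")
                graph.add_edge(row["gene_id"], row["pathway"],
                               edge_type="annotated_to", inhibitory=False)
    nodes = pd.DataFrame(
        [{"node": n, "node_type": d["node_type"]} for n, d in graph.nodes(data=True)],
        columns=["node", "node_type"],
    )
    edges = pd.DataFrame(
        [
            {"source": u, "target": v, "edge_type": d["edge_type"],
             "inhibitory": d["inhibitory"]}
            for u, v, d in graph.edges(data=True)
        ],
        columns=["source", "target", "edge_type", "inhibitory"],
    )
    return nodes, edges, graph


def read_network(nodes: pd.DataFrame, edges: pd.DataFrame) -> nx.DiGraph:
    """Rebuild the graph from emitted node/edge tables (round trip)."""
    graph = nx.DiGraph()
    for _, row in nodes.iterrows():
        graph.add_node(row["node"], node_type=row["node_type"])
    for _, row in edges.iterrows():
        graph.add_edge(row["source"], row["target"],
                       edge_type=row["edge_type"], inhibitory=bool(row["inhibitory"]))
    return graph


def pairs_to_frame(pairs: list[RegulatoryPair]) -> pd.DataFrame:
    rows = [
        {
            "mirna": p.mirna,
            "transcript": p.transcript_id,
            "gene": p.gene_id,
            "gene_symbol": p.gene_symbol,
            "mirna_log2fc": p.mirna_log2fc,
            "mirna_regulation": p.mirna_direction,
            "target_log2fc": p.mrna_log2fc,
            "target_regulation": p.mrna_direction,
            "pattern": p.pattern,
            "contrast": p.contrast,
            "tslice": p.tslice,
        }
        for p in pairs
    ]
    return pd.DataFrame(
        rows,
        columns=["mirna", "transcript", "gene", "gene_symbol", "mirna_log2fc",
                 "mirna_regulation", "target_log2fc", "target_regulation",
                 "pattern", "contrast", "tslice"],
    )
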