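"""Hypergeometric over-representation testing for term annotation maps.

For each term with at least one background hit, the one-sided upper-tail
hypergeometric P of seeing at least the observed number of study hits is
computed, followed by Benjamini-Hochberg correction across the tested
terms.  This is the standard GO/KEGG over-representation test (without
read-length bias weighting or ontology ancestor propagation).
"""

from __future__ import annotations

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_ALPHA = 0.05


def enrich(
    study: set,
    background: set,
    annotation: dict[str, set],
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Term over-representation in ``study`` relative to ``background``.

    ``annotation`` maps gene id -> set of term ids.  The study set must be
    a subset of the background.  Terms with no background hits are skipped.
    Rows are sorted by raw P and report k (study hits), n (study size),
    K (background hits), N (background size), the enrichment factor
    (k/n) / (K/N), raw and corrected P, and a significance flag at
    corrected P < alpha.
    """
    study = set(study)
    background = set(background)
    offenders = study - background
    if offenders:
        raise ValueError(f"study genes not in background: {sorted(offenders)}")
    if not background:
        raise ValueError("background must be non-empty")

    term_background: dict[str, int] = {}
    term_study: dict[str, int] = {}
    for gene in background:
        for term in annotation.get(gene, ()):
            term_background[term] = term_background.get(term, 0) + 1
            if gene in study:
                term_study[term] = term_study.get(term, 0) + 1

    N, n = len(background), len(study)
    rows = []
    for term in sorted(term_background):
        K = term_background[term]
        k = term_study.get(term, 0)
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        factor = (k / n) / (K / N) if n else 0.0
        rows.append(
            {"term": term, "k": k, "n": n, "K": K, "N": N,
             "enrichment_factor": factor, "raw_p": min(p, 1.0)}
        )
    table = pd.DataFrame(
        rows, columns=["term", "k", "n", "K", "N", "enrichment_factor", "raw_p"]
    )
    if table.empty:
        table["corrected_p"] = []
        table["significant"] = []
        return table
    table["corrected_p"] = multipletests(table["raw_p"], method="fdr_bh")[1]
    table["significant"] = table["corrected_p"] < alpha
    return table.sort_values(["raw_p", "term"], kind="mergesort").reset_index(drop=True)


def annotation_from_frame(df: pd.DataFrame) -> dict[str, set]:
    """gene/term TSV (columns ``gene_id``, ``term``) -> annotation map."""
    annotation: dict[str, set] = {}
    for _, row in df.iterrows():
        annotation.setdefault(row["gene_id"], set()).add(row["term"])
    return annotation
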