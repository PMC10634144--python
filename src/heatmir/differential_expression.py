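"""Normalization, fold changes, and differential-expression testing.

miRNA counts are normalized to tags-per-million (TPM = count / library
total x 1e6), mRNA fragments to FPKM (count / (length/1e3) / (total/1e6)).
Fold changes are log2 ratios of replicate-mean normalized expression, with
+/- infinity for zero denominators/numerators.  Per-feature two-sided
Welch t-tests with Benjamini-Hochberg correction call features
differential at corrected P < 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_ALPHA = 0.05


def tpm_normalize(counts: pd.DataFrame, totals: pd.Series | None = None) -> pd.DataFrame:
    """Tags-per-million normalization: count / total clean tags x 1e6.

    ``totals`` are the per-sample clean-tag library sizes; when omitted the
    column sums of ``counts`` are used (then each normalized column sums to
    exactly 1e6).  Passing the full library sizes is preferred when
    ``counts`` covers only a feature subset (e.g. miRNAs out of all clean
    sRNA tags): it matches the formula's denominator and avoids
    compositional coupling between features.
    """
    if totals is None:
        totals = counts.sum(axis=0)
    else:
        totals = pd.Series(totals).reindex(counts.columns)
        if totals.isna().any():
            raise ValueError("totals missing for some samples")
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero-total sample(s): {', '.join(map(str, zero.index))}")
    return counts / totals * 1e6


def fpkm_normalize(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Per-kilobase per-million normalization using feature lengths (nt)."""
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(lengths[lengths.isna()].index)
        raise ValueError(f"missing length for feature(s): {missing}")
    if (lengths <= 0).any():
        raise ValueError("feature lengths must be > 0")
    totals = counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero-total sample(s): {', '.join(map(str, zero.index))}")
    return counts.div(lengths / 1e3, axis=0).div(totals / 1e6, axis=1)


def log2_fold_change(mean_a: float, mean_b: float) -> float:
    """log2(mean_a / mean_b) with +/-inf sentinels on zero means.

    Both means zero -> NaN (undefined; such features are excluded from
    testing).
    """
    if mean_a < 0 or mean_b < 0:
        raise ValueError("means must be >= 0")
    if mean_a == 0 and mean_b == 0:
        return math.nan
    if mean_b == 0:
        return math.inf
    if mean_a == 0:
        return -math.inf
    return math.log2(mean_a / mean_b)


@dataclass(frozen=True)
class Contrast:
    """Two-group contrast; fold change is group_a over group_b."""

    group_a: str
    group_b: str

    @property
    def label(self) -> str:
        return f"{self.group_a}_vs_{self.group_b}"

    @classmethod
    def parse(cls, label: str) -> "Contrast":
        a, sep, b = label.partition("_vs_")
        if not sep or not a or not b:
            raise ValueError(f"cannot parse contrast label {label!r}")
        return cls(a, b)


def _welch_p(a: np.ndarray, b: np.ndarray, equal_var: bool) -> float:
    if np.var(a) == 0 and np.var(b) == 0:
        return 1.0 if np.mean(a) == np.mean(b) else 0.0
    return float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)


def de_test(
    normalized: pd.DataFrame,
    design: pd.DataFrame,
    contrast: Contrast | str,
    alpha: float = DEFAULT_ALPHA,
    equal_var: bool = True,
    log_values: bool = True,
) -> pd.DataFrame:
    """Per-feature two-group test on normalized expression.

    ``design`` maps sample -> group (columns ``sample`` and ``group``).
    Group means and log2FC are computed on the normalized scale; the t-test
    runs on log2(x + 1)-transformed values by default (variance
    stabilization for count-derived expression; set ``log_values=False``
    to test the raw normalized values).  ``equal_var=True`` is the pooled
    (Student) test, appropriate for balanced designs at small n; False
    gives Welch.  Features with zero expression in both groups are
    excluded.  Returns one row per tested feature with group means, log2FC
    (a over b), raw and BH-corrected P, and direction (up/down/ns at
    corrected P < alpha).
    """
    if isinstance(contrast, str):
        contrast = Contrast.parse(contrast)
    groups = dict(zip(design["sample"], design["group"]))
    cols_a = [s for s in normalized.columns if groups.get(s) == contrast.group_a]
    cols_b = [s for s in normalized.columns if groups.get(s) == contrast.group_b]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("each group needs >= 2 replicates")

    rows = []
    for feature in normalized.index:
        a = normalized.loc[feature, cols_a].to_numpy(dtype=float)
        b = normalized.loc[feature, cols_b].to_numpy(dtype=float)
        mean_a, mean_b = float(a.mean()), float(b.mean())
        lfc = log2_fold_change(mean_a, mean_b)
        if math.isnan(lfc):
            continue
        ta, tb = (np.log2(a + 1), np.log2(b + 1)) if log_values else (a, b)
        rows.append(
            {
                "feature": feature,
                "mean_a": mean_a,
                "mean_b": mean_b,
                "log2fc": lfc,
                "raw_p": _welch_p(ta, tb, equal_var),
                "contrast": contrast.label,
            }
        )
    result = pd.DataFrame(
        rows, columns=["feature", "mean_a", "mean_b", "log2fc", "raw_p", "contrast"]
    )
    if result.empty:
        result["corrected_p"] = []
        result["direction"] = []
        return result
    result["corrected_p"] = multipletests(result["raw_p"], method="fdr_bh")[1]
    significant = result["corrected_p"] < alpha
    result["direction"] = "ns"
    result.loc[significant & (result["log2fc"] > 0), "direction"] = "up"
    result.loc[significant & (result["log2fc"] < 0), "direction"] = "down"
    return result


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def venn_partition(sets: dict[str, set]) -> pd.DataFrame:
    """Exclusive-region counts of a named set family.

    Returns one row per non-empty membership signature with the member
    count and its percentage of the union (2 decimals, round half-up);
    ``attrs['union_size']`` holds the union size.
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 sets")
    names = sorted(sets)
    union = set().union(*sets.values())
    rows = []
    for signature in product([False, True], repeat=len(names)):
        if not any(signature):
            continue
        inside = [n for n, flag in zip(names, signature) if flag]
        outside = [n for n, flag in zip(names, signature) if not flag]
        region = set.intersection(*(sets[n] for n in inside)) if inside else set()
        for n in outside:
            region = region - sets[n]
        pct = _round2(100.0 * len(region) / len(union)) if union else 0.0
        rows.append(
            {"region": "&".join(inside), "count": len(region), "percent_of_union": pct}
        )
    table = pd.DataFrame(rows)
    table.attrs["union_size"] = len(union)
    return table


DEFAULT_BINS = (1.0, 100.0)


def expression_bins(normalized: pd.DataFrame, bounds: tuple = DEFAULT_BINS) -> pd.Series:
    """low / moderate / high expression class from mean normalized value.

    mean < bounds[0] -> low; bounds[0] <= mean <= bounds[1] -> moderate
    (left-closed); mean > bounds[1] -> high.
    """
    lo, hi = bounds
    means = normalized.mean(axis=1)
    out = pd.Series("moderate", index=normalized.index, name="expression_bin")
    out[means < lo] = "low"
    out[means > hi] = "high"
    return out


@dataclass
class TwoGroupResult:
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    p_value: float
    significant: bool


def two_group_compare(
    values_a, values_b, alpha: float = DEFAULT_ALPHA, equal_var: bool = True
) -> TwoGroupResult:
    """Two-tailed unpaired t-test (Student by default) for measurement data."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need n >= 3 per group")
    p = _welch_p(a, b, equal_var=equal_var)
    return TwoGroupResult(
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        p_value=p,
        significant=p < alpha,
    )
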