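"""Primary-vs-metastatic differential expression per target and tumor type.

Effect size is the rank-biserial correlation r = 2*U/(n_p*n_m) - 1, where U
counts (primary > metastatic) cross-group pairs with ties worth 1/2.
Positive r means primary-enriched, negative r metastatic-enriched.
Significance is a two-sided Wilcoxon rank-sum test with Benjamini-Hochberg
FDR across all emitted (target, cancer type) comparisons; only tumor types
with at least ``min_group`` samples in each class are compared.
"""

from __future__ import annotations

import warnings
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import HousekeepingReference, PercentileMatrix, ValidationError

#: switch to exact Wilcoxon null when the smaller group is this size or less
#: and there are no ties; normal approximation with continuity correction
#: otherwise.
EXACT_MAX_N = 25


def rank_biserial(primary_values, metastatic_values) -> float:
    """Rank-biserial correlation between two groups.

    +1 when every primary value exceeds every metastatic value, -1 in the
    reverse case, 0 for identical distributions.
    """
    x = np.asarray(primary_values, dtype=float)
    y = np.asarray(metastatic_values, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both groups must be non-empty")
    u = stats.mannwhitneyu(x, y, alternative="two-sided").statistic
    return float(2.0 * u / (x.size * y.size) - 1.0)


def _wilcoxon_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum p and U, exact for small tie-free groups."""
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (min(x.size, y.size) <= EXACT_MAX_N and not has_ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.pvalue), float(res.statistic)


def met_screen(
    p: PercentileMatrix,
    ann: pd.DataFrame,
    targets: Iterable[str],
    min_group: int = 10,
) -> pd.DataFrame:
    """Screen every (target, cancer type) for primary-vs-metastatic shifts.

    Returns a long table with rank-biserial r, U, raw p, BH q, and group
    sizes.  Cancer types failing the group-size floor in either class are
    omitted.
    """
    if ann.index.name != "sample_id":
        ann = ann.set_index("sample_id")
    targets = [t for t in targets if t in p.values.index]
    rows = []
    for ctype, sub in ann.groupby("cancer_type"):
        prim = sub.index[sub["tissue_class"] == "primary"]
        met = sub.index[sub["tissue_class"] == "metastatic"]
        prim = prim.intersection(p.values.columns)
        met = met.intersection(p.values.columns)
        if len(prim) < min_group or len(met) < min_group:
            continue
        for t in targets:
            x = p.values.loc[t, prim].to_numpy(dtype=float)
            y = p.values.loc[t, met].to_numpy(dtype=float)
            x, y = x[~np.isnan(x)], y[~np.isnan(y)]
            if x.size < min_group or y.size < min_group:
                continue
            pval, u = _wilcoxon_p(x, y)
            r = 2.0 * u / (x.size * y.size) - 1.0
            rows.append((t, ctype, r, u, pval, x.size, y.size))
    if not rows:
        warnings.warn("no (target, cancer type) cell meets the group-size floor")
        return pd.DataFrame(columns=["target", "cancer_type", "r", "U", "p", "q",
                                     "n_primary", "n_metastatic"])
    out = pd.DataFrame(rows, columns=["target", "cancer_type", "r", "U", "p",
                                      "n_primary", "n_metastatic"])
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out[["target", "cancer_type", "r", "U", "p", "q",
                "n_primary", "n_metastatic"]]


def _level(median: float, hk: HousekeepingReference) -> str:
    if median > hk.pooled.p90:
        return "high"
    if median > hk.pooled.p50:
        return "medium"
    if median > hk.pooled.p01:
        return "low"
    return "very_low"


def landscape_summary(
    p: PercentileMatrix,
    ann: pd.DataFrame,
    targets: Iterable[str],
    hk_ref: HousekeepingReference,
) -> pd.DataFrame:
    """Five-number summary of target percentile expression per group.

    One row per (target, cancer type, tissue class): min, Q1, median, Q3,
    max, sample count, and an expression level flag relative to the pooled
    housekeeping thresholds (high > p90, medium > p50, low > p01,
    very_low otherwise).
    """
    if ann.index.name != "sample_id":
        ann = ann.set_index("sample_id")
    targets = [t for t in targets if t in p.values.index]
    rows = []
    for (ctype, tclass), sub in ann.groupby(["cancer_type", "tissue_class"]):
        cols = sub.index.intersection(p.values.columns)
        if len(cols) == 0:
            continue
        for t in targets:
            v = p.values.loc[t, cols].dropna().to_numpy(dtype=float)
            if v.size == 0:
                continue
            q1, med, q3 = np.percentile(v, [25, 50, 75])
            rows.append((t, ctype, tclass, float(v.min()), float(q1), float(med),
                         float(q3), float(v.max()), v.size, _level(med, hk_ref)))
    return pd.DataFrame(rows, columns=["target", "cancer_type", "tissue_class",
                                       "min", "q1", "median", "q3", "max",
                                       "n", "level"])
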