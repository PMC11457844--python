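"""Matching cell-line models to (target, tumor type) populations.

A line is a good model for a target in a tumor type when (i) its target
expression is at or above the 95th percentile of that target's expression
across the tumor samples of the (cancer type, primary/metastatic) group,
and (ii) its transcriptome-wide median Spearman correlation with the
high-purity (>= 0.6) tumors of the group is at or above the 95th percentile
of that statistic across candidate lines.  Both quantile references are
configurable (``pct``).
"""

from __future__ import annotations

import warnings
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import PercentileMatrix, ValidationError

#: below this many candidate lines the line-correlation quantile is too
#: unstable to define criterion (ii)
MIN_CANDIDATE_LINES = 5


def _spearman_block(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Spearman rho between every column of a and every column of b."""
    ra = rankdata(a, axis=0)
    rb = rankdata(b, axis=0)
    ra = (ra - ra.mean(axis=0)) / ra.std(axis=0)
    rb = (rb - rb.mean(axis=0)) / rb.std(axis=0)
    return (ra.T @ rb) / a.shape[0]


def tumor_line_correlation(
    p_tumors: PercentileMatrix,
    p_lines: PercentileMatrix,
    ann: pd.DataFrame,
    purity_min: float = 0.6,
) -> pd.DataFrame:
    """Median Spearman rho of every line against each tumor group.

    Correlations run over all genes shared between the tumor and line
    matrices, restricted to tumors with purity >= ``purity_min``; per line
    the median is taken across the tumors of each (cancer type, primary or
    metastatic) group.  Groups with no qualifying tumor are omitted with a
    warning.
    """
    if ann.index.name != "sample_id":
        ann = ann.set_index("sample_id")
    shared = p_tumors.values.index.intersection(p_lines.values.index)
    if len(shared) < 3:
        raise ValidationError("fewer than 3 genes shared between tumors and lines")
    tumors = ann[ann["tissue_class"].isin(["primary", "metastatic"])]
    if "purity" not in tumors.columns:
        raise ValidationError("tumor annotation lacks a purity column")
    rows = []
    lines = list(p_lines.values.columns)
    lmat = p_lines.values.loc[shared].to_numpy(dtype=float)
    for (ctype, tclass), sub in tumors.groupby(["cancer_type", "tissue_class"]):
        keep = sub.index[sub["purity"] >= purity_min].intersection(
            p_tumors.values.columns
        )
        if len(keep) == 0:
            warnings.warn(f"no tumor with purity >= {purity_min} in "
                          f"({ctype}, {tclass}); group omitted")
            continue
        tmat = p_tumors.values.loc[shared, keep].to_numpy(dtype=float)
        rho = _spearman_block(tmat, lmat)  # tumors x lines
        med = np.median(rho, axis=0)
        for line, m in zip(lines, med):
            rows.append((line, ctype, tclass, float(m), len(keep)))
    return pd.DataFrame(rows, columns=["cell_line", "cancer_type", "tissue_class",
                                       "median_rho", "n_tumors"])


def match(
    p_tumors: PercentileMatrix,
    p_lines: PercentileMatrix,
    ann: pd.DataFrame,
    targets: Iterable[str],
    line_ann: pd.DataFrame | None = None,
    pct: float = 0.95,
    purity_min: float = 0.6,
) -> pd.DataFrame:
    """Score every (target, cancer type, tissue class, line) combination.

    expr_pass: the line's target percentile is >= the ``pct``-quantile of
    the target's percentile values across the group's tumor samples.
    corr_pass: the line's median Spearman rho with the group's high-purity
    tumors is >= the ``pct``-quantile across candidate lines (NaN when
    fewer than 5 candidate lines exist).  overall_pass requires both.
    ``line_ann`` (indexed by sample_id with a parent_cancer_type column)
    populates the same_type flag.
    """
    if ann.index.name != "sample_id":
        ann = ann.set_index("sample_id")
    corr = tumor_line_correlation(p_tumors, p_lines, ann, purity_min=purity_min)
    targets = [t for t in targets if t in p_lines.values.index
               and t in p_tumors.values.index]
    parent = None
    if line_ann is not None:
        if line_ann.index.name != "sample_id":
            line_ann = line_ann.set_index("sample_id")
        if "parent_cancer_type" in line_ann.columns:
            parent = line_ann["parent_cancer_type"]
    tumors = ann[ann["tissue_class"].isin(["primary", "metastatic"])]
    rows = []
    for (ctype, tclass), grp in corr.groupby(["cancer_type", "tissue_class"]):
        tumor_cols = tumors.index[
            (tumors["cancer_type"] == ctype) & (tumors["tissue_class"] == tclass)
        ].intersection(p_tumors.values.columns)
        n_lines = len(grp)
        if n_lines >= MIN_CANDIDATE_LINES:
            corr_thresh = float(np.quantile(grp["median_rho"], pct))
        else:
            corr_thresh = np.nan
        for t in targets:
            tumor_vals = p_tumors.values.loc[t, tumor_cols].dropna()
            if tumor_vals.empty:
                continue
            expr_thresh = float(np.quantile(tumor_vals, pct))
            for _, lr in grp.iterrows():
                line = lr["cell_line"]
                line_pct = float(p_lines.values.loc[t, line])
                expr_pass = bool(line_pct >= expr_thresh)
                if np.isfinite(corr_thresh):
                    corr_pass = bool(lr["median_rho"] >= corr_thresh)
                    overall = expr_pass and corr_pass
                else:
                    corr_pass, overall = np.nan, False
                same = bool(parent is not None and line in parent.index
                            and parent[line] == ctype)
                rows.append((t, ctype, tclass, line, line_pct, lr["median_rho"],
                             expr_pass, corr_pass, overall, same))
    return pd.DataFrame(rows, columns=["target", "cancer_type", "tissue_class",
                                       "cell_line", "target_percentile",
                                       "median_rho", "expr_pass", "corr_pass",
                                       "overall_pass", "same_type"])


def match_counts(matches: pd.DataFrame) -> pd.DataFrame:
    """Per (target, cancer type, tissue class): counts of passing lines."""
    grouped = matches.groupby(["target", "cancer_type", "tissue_class"])
    out = grouped.agg(
        n_lines=("cell_line", "size"),
        n_pass=("overall_pass", "sum"),
        n_pass_same_type=("overall_pass",
                          lambda s: int((s & matches.loc[s.index, "same_type"]).sum())),
    ).reset_index()
    return out
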