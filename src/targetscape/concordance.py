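"""RNA -> protein high-expression concordance.

For each cell-surface target, the high-RNA indicator (above 90% of
housekeeping genes at the RNA level) is compared against the high-protein
indicator (same definition on the protein matrix).  Accuracy counts both
agreement cells — high/high and low/low — as correct; the inaccuracy rate
is one minus accuracy.  Sensitivity and specificity (protein-high as the
condition) are exported as supplementary columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .containers import HousekeepingReference, PercentileMatrix, ValidationError
from .harmonize import high_expression_call


@dataclass
class PairedOmics:
    """Percentile-transformed RNA and protein matrices on shared axes."""

    rna: PercentileMatrix
    protein: PercentileMatrix
    hk_ref_rna: HousekeepingReference
    hk_ref_protein: HousekeepingReference

    def __post_init__(self) -> None:
        if not self.rna.values.index.equals(self.protein.values.index):
            raise ValidationError("RNA and protein gene axes differ")
        if not self.rna.values.columns.equals(self.protein.values.columns):
            raise ValidationError("RNA and protein sample axes differ")


def target_accuracy(paired: PairedOmics, target: str) -> tuple[float, int]:
    """Fraction of samples where the RNA and protein high calls agree.

    Each platform is thresholded against its own housekeeping p90.  Returns
    (accuracy, n_usable_samples); accuracy is NaN when no sample has both
    measurements.
    """
    if target not in paired.rna.values.index:
        raise ValidationError(f"target {target!r} absent from paired matrices")
    r = paired.rna.values.loc[target]
    p = paired.protein.values.loc[target]
    usable = r.notna() & p.notna()
    n = int(usable.sum())
    if n == 0:
        warnings.warn(f"target {target!r}: no usable samples")
        return float("nan"), 0
    rna_high = high_expression_call(r[usable], paired.hk_ref_rna.pooled.p90)
    prot_high = high_expression_call(p[usable], paired.hk_ref_protein.pooled.p90)
    return float((rna_high == prot_high).mean()), n


def concordance_table(
    paired: PairedOmics, targets: Iterable[str], min_samples: int = 10
) -> pd.DataFrame:
    """Per-target accuracy / sensitivity / specificity table.

    Targets with fewer than ``min_samples`` usable samples get NaN accuracy
    (kept in the table with their n for transparency).
    """
    rows = []
    for t in targets:
        r = paired.rna.values.loc[t]
        p = paired.protein.values.loc[t]
        usable = r.notna() & p.notna()
        n = int(usable.sum())
        if n < min_samples:
            rows.append((t, n, np.nan, np.nan, np.nan))
            continue
        rna_high = high_expression_call(r[usable], paired.hk_ref_rna.pooled.p90)
        prot_high = high_expression_call(p[usable], paired.hk_ref_protein.pooled.p90)
        acc = float((rna_high == prot_high).mean())
        npos = int(prot_high.sum())
        sens = float((rna_high & prot_high).sum() / npos) if npos else np.nan
        nneg = n - npos
        spec = float((~rna_high & ~prot_high).sum() / nneg) if nneg else np.nan
        rows.append((t, n, acc, sens, spec))
    return pd.DataFrame(
        rows, columns=["target", "n", "accuracy", "sensitivity", "specificity"]
    )


def summarize_accuracy(accuracies: pd.Series | Iterable[float]) -> dict:
    """Median and interquartile range of per-target accuracies.

    Returns a dict with median, q1, q3 and the implied median inaccuracy
    (1 - median accuracy).
    """
    acc = pd.Series(list(accuracies), dtype=float).dropna()
    if acc.empty:
        raise ValidationError("no target with a defined accuracy")
    q1, med, q3 = np.percentile(acc, [25, 50, 75])
    return {
        "n_targets": int(acc.size),
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "median_inaccuracy": float(1.0 - med),
    }
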