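"""Cross-platform harmonization by sample-wise percentile ranks.

Bulk expression compendia mix RNA-seq and microarray studies whose raw
values live on incompatible scales.  Replacing each gene's value by its
within-sample rank divided by the number of measured genes yields a score
in (0, 1] that is comparable across samples, studies and platforms.
Housekeeping genes — ubiquitously expressed reference genes — anchor that
scale: the 1st / 50th / 90th percentiles of their pooled percentile values
define low / medium / high expression, and a gene is called *high* in a
sample when it exceeds the high threshold (i.e. is expressed above 90% of
housekeeping genes).
"""

from __future__ import annotations

import warnings
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import substream
from .containers import (
    ExpressionMatrix,
    HousekeepingReference,
    PercentileMatrix,
    Thresholds,
    ValidationError,
)


def default_housekeeping_genes() -> list[str]:
    """The bundled default housekeeping gene list (overridable everywhere)."""
    text = resources.files("targetscape.data").joinpath(
        "housekeeping_default.txt"
    ).read_text()
    return [line.strip() for line in text.splitlines() if line.strip()]


def rank_percentile(m: ExpressionMatrix, seed: int) -> PercentileMatrix:
    """Rank-transform each sample and divide ranks by the measured gene count.

    Higher expression receives higher rank; ties are broken uniformly at
    random under ``seed`` (recorded on the output so the transform is
    reproducible).  Genes missing for a sample stay missing and do not
    enter that sample's rank denominator.
    """
    if m.n_genes == 0 or m.n_samples == 0:
        raise ValidationError("cannot rank an empty matrix")
    if m.n_genes < 2:
        raise ValidationError("need at least 2 genes to rank")
    rng = substream(seed, "rank_percentile")
    vals = m.values.to_numpy(dtype=float)
    out = np.full_like(vals, np.nan)
    for j in range(vals.shape[1]):
        col = vals[:, j]
        mask = ~np.isnan(col)
        g = int(mask.sum())
        if g == 0:
            continue
        # lexsort: primary key expression, secondary key uniform noise
        order = np.lexsort((rng.random(g), col[mask]))
        ranks = np.empty(g)
        ranks[order] = np.arange(1, g + 1)
        out[mask, j] = ranks / g
    values = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return PercentileMatrix(values=values, rank_seed=int(seed),
                            study_of_sample=m.study_of_sample)


def collapse_probes(
    probe_matrix: ExpressionMatrix, probe_to_gene: Mapping[str, str]
) -> ExpressionMatrix:
    """Collapse microarray probes to genes, keeping the highest-mean probe.

    When several probes map to one gene, the probe with the highest average
    expression across samples is retained; equal means are broken by the
    lexicographically smallest probe ID for determinism.  Unmapped probes
    are dropped.
    """
    if not probe_to_gene:
        raise ValidationError("empty probe-to-gene mapping")
    means = probe_matrix.values.mean(axis=1, skipna=True)
    rows = []
    for probe in probe_matrix.values.index:
        gene = probe_to_gene.get(probe)
        if gene is not None:
            rows.append((gene, probe, means[probe]))
    if not rows:
        raise ValidationError("no probe in the matrix maps to a gene")
    table = pd.DataFrame(rows, columns=["gene", "probe", "mean"])
    # highest mean wins; ties -> smallest probe ID
    table = table.sort_values(["gene", "mean", "probe"],
                              ascending=[True, False, True])
    chosen = table.drop_duplicates("gene", keep="first")
    values = probe_matrix.values.loc[chosen["probe"]].copy()
    values.index = pd.Index(chosen["gene"].to_numpy(), name="gene")
    return ExpressionMatrix(values=values, platform=probe_matrix.platform,
                            study_of_sample=probe_matrix.study_of_sample)


def _concat(matrices: Sequence[ExpressionMatrix], genes: pd.Index) -> ExpressionMatrix:
    all_samples = pd.Index(np.concatenate([m.values.columns for m in matrices]))
    if all_samples.has_duplicates:
        dupes = all_samples[all_samples.duplicated()].unique().tolist()[:5]
        raise ValidationError(f"duplicate sample IDs across inputs: {dupes}")
    blocks = [m.values.reindex(genes) for m in matrices]
    values = pd.concat(blocks, axis=1)
    study = pd.concat([m.study_of_sample for m in matrices])
    return ExpressionMatrix(values=values, platform=matrices[0].platform,
                            study_of_sample=study)


def union_merge(matrices: Sequence[ExpressionMatrix]) -> ExpressionMatrix:
    """Merge studies on the union of their gene sets.

    Genes absent from a study are missing (NaN) for its samples — never
    zero.  Used for microarray compendia where platforms measure different
    gene panels.
    """
    if not matrices:
        raise ValidationError("need at least one matrix")
    genes: set = set()
    for m in matrices:
        genes |= set(m.values.index)
    return _concat(matrices, pd.Index(sorted(genes)))


def intersect_merge(matrices: Sequence[ExpressionMatrix]) -> ExpressionMatrix:
    """Merge studies on the intersection of their gene sets (RNA-seq path)."""
    if not matrices:
        raise ValidationError("need at least one matrix")
    genes = set(matrices[0].values.index)
    for m in matrices[1:]:
        genes &= set(m.values.index)
    if not genes:
        smallest = min(matrices, key=lambda m: m.n_genes)
        name = smallest.study_of_sample.iloc[0] if smallest.n_samples else "?"
        raise ValidationError(
            f"empty gene intersection; smallest study ({name}) has "
            f"{smallest.n_genes} genes"
        )
    return _concat(matrices, pd.Index(sorted(genes)))


def hk_reference(p: PercentileMatrix, hk_genes: Iterable[str]) -> HousekeepingReference:
    """Housekeeping thresholds: per-study 1st/50th/90th percentiles, pooled by median.

    Within each study, all housekeeping percentile values (across genes and
    samples) are pooled into one distribution and its 1st, 50th and 90th
    percentiles taken; the pooled thresholds are the medians of those
    per-study values across studies.
    """
    present = [g for g in hk_genes if g in p.values.index]
    if not present:
        raise ValidationError("no housekeeping gene present in the matrix")
    per_study = {}
    for study, cols in p.study_of_sample.groupby(p.study_of_sample).groups.items():
        block = p.values.loc[present, cols].to_numpy().ravel()
        block = block[~np.isnan(block)]
        if block.size == 0:
            continue
        q = np.percentile(block, [1, 50, 90])  # linear interpolation
        per_study[study] = q
    if not per_study:
        raise ValidationError("no housekeeping values measured in any study")
    table = pd.DataFrame.from_dict(per_study, orient="index",
                                   columns=["p01", "p50", "p90"]).sort_index()
    pooled = Thresholds(*(float(table[c].median()) for c in ("p01", "p50", "p90")))
    return HousekeepingReference(hk_genes=present, per_study=table, pooled=pooled)


def hk_fraction_score(m: ExpressionMatrix, hk_genes: Iterable[str]) -> pd.DataFrame:
    """Fraction of measured housekeeping genes each gene exceeds, per sample.

    A gene expressed above 90 of 100 housekeeping genes in a sample scores
    0.9 there.  Because the score only uses housekeeping genes measured in
    that sample, it tolerates the missing genes a union merge introduces.
    Samples with zero measured housekeeping genes get missing scores and a
    warning.
    """
    present = [g for g in hk_genes if g in m.values.index]
    if not present:
        raise ValidationError("no housekeeping gene present in the matrix")
    vals = m.values.to_numpy(dtype=float)
    hk_idx = m.values.index.get_indexer(present)
    out = np.full_like(vals, np.nan)
    empty = []
    for j in range(vals.shape[1]):
        hk = vals[hk_idx, j]
        hk = hk[~np.isnan(hk)]
        if hk.size == 0:
            empty.append(m.values.columns[j])
            continue
        hk.sort()
        col = vals[:, j]
        mask = ~np.isnan(col)
        # strictly-lower count via left insertion point into sorted hk values
        out[mask, j] = np.searchsorted(hk, col[mask], side="left") / hk.size
    if empty:
        warnings.warn(
            f"{len(empty)} sample(s) have no measured housekeeping gene; "
            f"scores set missing (e.g. {empty[:3]})"
        )
    return pd.DataFrame(out, index=m.values.index, columns=m.values.columns)


def high_expression_call(score, threshold):
    """High-expression indicator: score strictly above the high threshold.

    *High* means expressed above 90% of housekeeping genes, so equality with
    the threshold is not high.  Works elementwise on arrays/frames.
    """
    return score > threshold
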