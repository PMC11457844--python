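"""Core data containers shared by every analysis stage.

An :class:`ExpressionMatrix` holds platform-native, non-negative expression
values (genes x samples) together with the study each sample came from;
raw values are comparable within a sample but not across studies or
platforms.  A :class:`PercentileMatrix` is its sample-wise rank-percentile
transform, the common currency of all downstream stages.
"""

from __future__ import annotations

from collections import namedtuple
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PLATFORMS = ("rnaseq", "microarray")
TISSUE_CLASSES = ("normal", "primary", "metastatic", "cell_line")

#: low / medium / high expression thresholds (1st / 50th / 90th housekeeping
#: percentiles, pooled across studies by their medians).
Thresholds = namedtuple("Thresholds", ["p01", "p50", "p90"])


class ValidationError(ValueError):
    """Raised when an input container violates its invariants."""


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dupes = index[index.duplicated()].unique().tolist()[:5]
        raise ValidationError(f"duplicate {what} IDs: {dupes}")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression in platform-native units.

    Missing entries (NaN) are permitted — they arise from union-merging
    microarray studies with different gene panels — and are always treated
    as *missing*, never as zero.
    """

    values: pd.DataFrame
    platform: str
    study_of_sample: pd.Series

    def __post_init__(self) -> None:
        if self.platform not in PLATFORMS:
            raise ValidationError(
                f"platform must be one of {PLATFORMS}, got {self.platform!r}"
            )
        _check_unique(self.values.index, "gene")
        _check_unique(self.values.columns, "sample")
        vals = self.values.to_numpy()
        if vals.size:
            finite = np.isfinite(vals) | np.isnan(vals)
            if not finite.all():
                raise ValidationError("expression values must be finite or NaN")
            with np.errstate(invalid="ignore"):
                if np.nanmin(vals) < 0:
                    raise ValidationError("expression values must be >= 0")
        self.study_of_sample = pd.Series(self.study_of_sample)
        missing = self.values.columns.difference(self.study_of_sample.index)
        if len(missing):
            raise ValidationError(f"samples without a study: {list(missing[:5])}")
        self.study_of_sample = self.study_of_sample.reindex(self.values.columns)

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class PercentileMatrix:
    """Sample-wise rank percentiles in (0, 1]; NaN where the gene was unmeasured.

    Per sample the non-missing values are exactly a permutation of
    ``{1/G, 2/G, ..., 1}`` with G the number of measured genes; ties in the
    source matrix were broken uniformly at random under ``rank_seed``.
    """

    values: pd.DataFrame
    rank_seed: int
    study_of_sample: pd.Series

    def __post_init__(self) -> None:
        self.study_of_sample = pd.Series(self.study_of_sample).reindex(
            self.values.columns
        )

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


@dataclass
class HousekeepingReference:
    """Housekeeping-gene expression thresholds, per study and pooled.

    ``per_study`` rows are studies with columns p01/p50/p90 — the 1st, 50th
    and 90th percentiles of all housekeeping percentile values pooled across
    genes and samples within that study.  ``pooled`` holds the medians of
    those per-study values and defines the low / medium / high reference
    lines used everywhere downstream.
    """

    hk_genes: list = field(default_factory=list)
    per_study: pd.DataFrame = None
    pooled: Thresholds = None

    def __post_init__(self) -> None:
        if self.per_study is not None:
            bad = self.per_study[
                (self.per_study["p01"] > self.per_study["p50"])
                | (self.per_study["p50"] > self.per_study["p90"])
            ]
            if len(bad):
                raise ValidationError(
                    f"non-monotone housekeeping thresholds in studies {list(bad.index)}"
                )


ANNOTATION_COLUMNS = ("sample_id", "study_id", "cancer_type", "tissue_class")


def validate_annotation(ann: pd.DataFrame, require_purity: bool = False) -> pd.DataFrame:
    """Validate a sample annotation table and return it indexed by sample_id."""
    for col in ANNOTATION_COLUMNS:
        if col not in ann.columns and ann.index.name != col:
            raise ValidationError(f"annotation missing column {col!r}")
    if ann.index.name != "sample_id":
        ann = ann.set_index("sample_id")
    _check_unique(ann.index, "sample")
    bad = set(ann["tissue_class"]) - set(TISSUE_CLASSES)
    if bad:
        raise ValidationError(f"unknown tissue_class values: {sorted(bad)}")
    if (ann["cancer_type"].astype(str).str.len() == 0).any():
        raise ValidationError("empty cancer_type code")
    if require_purity:
        tumors = ann["tissue_class"].isin(["primary", "metastatic"])
        if "purity" not in ann.columns or ann.loc[tumors, "purity"].isna().all():
            raise ValidationError(
                "purity column required for tumor samples when matching cell lines"
            )
    if "purity" in ann.columns:
        p = ann["purity"].dropna()
        if ((p < 0) | (p > 1)).any():
            raise ValidationError("purity must lie in [0, 1]")
    return ann
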