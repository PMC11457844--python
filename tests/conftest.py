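import numpy as np
import pandas as pd
import pytest

from targetscape import (
    CohortSpec,
    ExpressionMatrix,
    HousekeepingReference,
    PercentileMatrix,
    StudyDesign,
    Thresholds,
    default_spec,
    generate_bulk,
    rank_percentile,
)


def make_matrix(values, platform="rnaseq", study=None, genes=None, samples=None):
    """Small ExpressionMatrix helper for hand-built fixtures."""
    arr = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    df = pd.DataFrame(arr, index=genes, columns=samples)
    if study is None:
        study = pd.Series("S1", index=df.columns)
    return ExpressionMatrix(values=df, platform=platform,
                            study_of_sample=pd.Series(study, index=df.columns))


def make_percentiles(values, genes=None, samples=None, study=None, seed=0):
    arr = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    df = pd.DataFrame(arr, index=genes, columns=samples)
    if study is None:
        study = pd.Series("S1", index=df.columns)
    return PercentileMatrix(values=df, rank_seed=seed,
                            study_of_sample=pd.Series(study, index=df.columns))


def make_hk_ref(p90, p50=0.5, p01=0.01):
    table = pd.DataFrame({"p01": [p01], "p50": [p50], "p90": [p90]},
                         index=["S1"])
    return HousekeepingReference(hk_genes=["HK1"], per_study=table,
                                 pooled=Thresholds(p01, p50, p90))


@pytest.fixture(scope="session")
def reference_cohort():
    """The reference synthetic cohort, generated once per session."""
    spec = default_spec(1)
    em, ann, gt = generate_bulk(spec)
    pm = rank_percentile(em, 11)
    return spec, em, ann, gt, pm


@pytest.fixture
def tiny_spec():
    return CohortSpec(
        n_genes=200,
        n_targets=4,
        studies=[StudyDesign("S1", 90, 1.0)],
        cancer_types={"CA": {"TGT01": 2.0}},
        normal_tissues=("N1",),
        met_shift={"TGT02": 1.0},
        concordance_rate={f"TGT{i + 1:02d}": 0.9 for i in range(4)},
        hk_genes=["HK%02d" % i for i in range(20)],
        seed=3,
    )
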