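"""Synthetic-cohort generator: determinism, validation, planted structure."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from targetscape import (
    CohortSpec,
    StudyDesign,
    default_spec,
    generate_bulk,
    generate_paired_omics,
    generate_single_cell,
    rank_percentile,
)
from targetscape.simulate import SpecError


class TestDeterminism:
    def test_bulk_bitwise_identical(self, tiny_spec):
        em1, ann1, _ = generate_bulk(tiny_spec)
        em2, ann2, _ = generate_bulk(tiny_spec)
        pd.testing.assert_frame_equal(em1.values, em2.values)
        pd.testing.assert_frame_equal(ann1, ann2)

    def test_single_cell_identical(self, tiny_spec):
        c1, g1, a1, _ = generate_single_cell(tiny_spec)
        c2, g2, a2, _ = generate_single_cell(tiny_spec)
        assert (c1 != c2).nnz == 0
        pd.testing.assert_frame_equal(a1, a2)

    def test_different_seeds_differ(self, tiny_spec):
        em1, _, _ = generate_bulk(tiny_spec)
        tiny_spec.seed = tiny_spec.seed + 1
        em2, _, _ = generate_bulk(tiny_spec)
        assert not em1.values.equals(em2.values)


class TestValidation:
    def test_too_few_genes_names_field(self):
        spec = CohortSpec(n_genes=10, n_targets=8)
        with pytest.raises(SpecError, match="n_genes"):
            spec.validate()

    def test_bad_concordance_rate(self):
        spec = default_spec(0)
        spec.concordance_rate["TGT01"] = 1.5
        with pytest.raises(SpecError, match="concordance_rate"):
            spec.validate()

    def test_unknown_met_shift_target(self):
        spec = default_spec(0)
        spec.met_shift["NOPE"] = 1.0
        with pytest.raises(SpecError, match="met_shift"):
            spec.validate()

    def test_pair_outside_target_list(self):
        spec = default_spec(0)
        spec.separable_pairs = [("BG00001", "TGT01", "BLCA", "LUNG")]
        with pytest.raises(SpecError, match="separable_pairs"):
            spec.validate()

    def test_bad_sc_detection_probability(self):
        spec = default_spec(0)
        spec.sc_detection["TGT01"]["malignant"] = -0.2
        with pytest.raises(SpecError, match="sc_detection"):
            spec.validate()


class TestPlantedStructure:
    def test_null_met_shift_gives_equal_medians(self):
        """With met_shift = 0 the primary and metastatic target
        distributions coincide up to Monte-Carlo error."""
        spec = CohortSpec(
            n_genes=150, n_targets=2,
            studies=[StudyDesign("S1", 600, 1.0)],
            cancer_types={"CA": {}}, normal_tissues=("N1",),
            hk_genes=[f"HK{i}" for i in range(20)], seed=5,
        )
        em, ann, _ = generate_bulk(spec)
        pm = rank_percentile(em, 1)
        prim = ann.loc[ann.tissue_class == "primary", "sample_id"]
        met = ann.loc[ann.tissue_class == "metastatic", "sample_id"]
        for t in spec.targets:
            d = abs(pm.values.loc[t, prim].median()
                    - pm.values.loc[t, met].median())
            assert d < 0.06

    def test_study_scale_preserves_percentile_distribution(self):
        """A 10x study scale shifts raw values but not within-sample ranks:
        the two studies' percentile CDFs agree by a two-sample KS test."""
        spec = CohortSpec(
            n_genes=150, n_targets=2,
            studies=[StudyDesign("A", 200, 1.0), StudyDesign("B", 200, 10.0)],
            cancer_types={"CA": {"TGT01": 1.0}}, normal_tissues=("N1",),
            hk_genes=[f"HK{i}" for i in range(20)], seed=8,
        )
        em, ann, _ = generate_bulk(spec)
        a_cols = ann.loc[ann.study_id == "A", "sample_id"]
        b_cols = ann.loc[ann.study_id == "B", "sample_id"]
        ratio = (em.values[b_cols].median(axis=1).median()
                 / em.values[a_cols].median(axis=1).median())
        assert ratio > 5  # raw values really are incomparable
        pm = rank_percentile(em, 2)
        x = pm.values.loc["TGT01", a_cols].to_numpy()
        y = pm.values.loc["TGT01", b_cols].to_numpy()
        ks = stats.ks_2samp(x, y)
        crit = 1.3581 * np.sqrt(2 / 200)  # alpha = 0.05 critical value
        assert ks.statistic < crit

    def test_ground_truth_keys_match_identifiers(self, reference_cohort):
        spec, em, ann, gt, _ = reference_cohort
        for key, line in gt.best_line.items():
            target, ctype = key.split("|")
            assert target in em.values.index
            assert line in em.values.columns
            assert ctype in spec.cancer_types
        assert set(gt.met_shift) <= set(spec.targets)
        for t in gt.sc_detection:
            assert t in spec.targets

    def test_all_tissue_classes_represented(self, reference_cohort):
        _, _, ann, _, _ = reference_cohort
        assert set(ann.tissue_class) == {"normal", "primary", "metastatic",
                                         "cell_line"}


class TestPairedOmics:
    def test_perfect_concordance_exact(self):
        spec = CohortSpec(
            n_genes=200, n_targets=3,
            studies=[StudyDesign("S1", 150, 1.0)],
            cancer_types={"CA": {"TGT01": 1.5}}, normal_tissues=("N1",),
            concordance_rate={"TGT01": 1.0, "TGT02": 1.0, "TGT03": 1.0},
            hk_genes=[f"HK{i}" for i in range(30)], seed=4,
        )
        from targetscape import concordance_table
        paired, _, _ = generate_paired_omics(spec)
        table = concordance_table(paired, spec.targets)
        assert (table.accuracy == 1.0).all()

    def test_missing_rate_errors(self):
        spec = CohortSpec(
            n_genes=200, n_targets=3,
            studies=[StudyDesign("S1", 30, 1.0)],
            cancer_types={"CA": {}}, normal_tissues=("N1",),
            concordance_rate={"TGT01": 0.9},
            hk_genes=[f"HK{i}" for i in range(30)], seed=4,
        )
        with pytest.raises(SpecError, match="concordance_rate"):
            generate_paired_omics(spec)


class TestSingleCellGeneration:
    def test_detection_extremes_and_sparsity(self):
        spec = CohortSpec(
            n_genes=120, n_targets=3,
            studies=[StudyDesign("S1", 30, 1.0)],
            cancer_types={"CA": {}}, normal_tissues=("N1",),
            sc_detection={
                "TGT01": {"malignant": 0.0},
                "TGT02": {"malignant": 1.0},
                "TGT03": {"malignant": 0.44},
            },
            hk_genes=[f"HK{i}" for i in range(20)], seed=9,
        )
        counts, genes, cells, gt = generate_single_cell(spec)
        mal = cells.malignant.to_numpy()
        dense = np.asarray(counts.todense())
        col = {t: genes.get_loc(t) for t in spec.targets}
        frac0 = (dense[mal, col["TGT01"]] > 0).mean()
        frac1 = (dense[mal, col["TGT02"]] > 0).mean()
        frac = (dense[mal, col["TGT03"]] > 0).mean()
        assert frac0 == 0.0
        assert frac1 == 1.0
        n = int(mal.sum())
        ci = 2.576 * np.sqrt(0.44 * 0.56 / n)
        assert abs(frac - 0.44) < ci + 0.01
        # zero fraction of the planted column is 1 - detection
        assert abs((dense[mal, col["TGT03"]] == 0).mean() - 0.56) < ci + 0.01
        assert gt.sc_detection["TGT03"]["malignant"] == 0.44

    def test_every_cell_annotated(self, tiny_spec):
        counts, genes, cells, _ = generate_single_cell(tiny_spec)
        assert counts.shape == (len(cells), len(genes))
        assert cells[["sample_id", "cell_type", "malignant"]].notna().all().all()
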