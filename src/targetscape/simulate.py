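"""Synthetic cohorts with planted, recorded ground truth.

The generator emulates the statistical structure the landscape analysis
assumes in real compendia: per-study multiplicative scale differences
(raw values incomparable across studies, within-sample ranks preserved),
tumor-type-specific target elevation, signed primary/metastatic shifts,
RNA->protein high-call agreement at a planted rate, cell-line /
tumor-type transcriptome similarity, and per-cell Bernoulli detection
with dropout.  Every planted parameter is serialized in a
:class:`GroundTruth` sidecar so downstream stages can be tested for
recovery.

All randomness flows from one root seed through named substreams, so a
(spec, seed) pair reproduces every dataset byte-for-byte and changing one
dataset's parameters never perturbs another's draws.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from ._rng import child_seed, substream
from .containers import ExpressionMatrix, ValidationError
from .harmonize import default_housekeeping_genes, hk_reference, rank_percentile

#: log-scale sd of per-sample, per-gene biological + technical noise
NOISE_SD = 0.7
#: log-scale sd of the per-cancer-type background-gene signature that
#: drives tumor/cell-line transcriptome similarity
SIGNATURE_SD = 0.8
#: log-scale target elevation / suppression planting separable pairs; sized
#: so the two-gene percentile clouds separate strongly (F1 well above 0.95)
#: while still overlapping enough that maximum-likelihood logistic fits are
#: identified and each gene's Wald test carries information
PAIR_BOOST = 1.3
PAIR_NORMAL_SUPPRESSION = -0.65
#: extra log-scale target elevation given to each type's designated best
#: cell line so it clears the tumor-expression quantile criterion
BEST_LINE_TARGET_BOOST = 3.0


class SpecError(ValidationError):
    """A cohort spec violates its invariants; the message names the field."""


@dataclass
class StudyDesign:
    study_id: str
    n_samples: int
    scale_factor: float = 1.0


@dataclass
class ScGroup:
    cell_type: str
    n_cells: int
    malignant: bool = False


@dataclass
class ScSample:
    sample_id: str
    tissue: str
    groups: list


@dataclass
class CohortSpec:
    """Everything the generators need, with planted effect sizes.

    ``cancer_types`` maps a type code to {target: log-scale elevation};
    ``met_shift`` is a signed per-target log-scale shift, positive meaning
    higher in metastatic samples; ``concordance_rate`` is the per-target
    probability that the protein high call agrees with the RNA high call;
    ``sc_detection`` maps target -> {cell_type: Bernoulli detection
    probability}.  ``separable_pairs`` entries are (gene_a, gene_b,
    cancer_type, normal_tissue) and are planted by elevating both genes in
    the cancer type and suppressing them in the normal tissue.
    """

    n_genes: int = 2000
    n_targets: int = 12
    studies: list = field(default_factory=lambda: [
        StudyDesign("S1", 400, 1.0), StudyDesign("S2", 400, 5.0),
    ])
    cancer_types: dict = field(default_factory=dict)
    normal_tissues: tuple = ("LUNG", "LIVER", "COLON")
    met_shift: dict = field(default_factory=dict)
    concordance_rate: dict = field(default_factory=dict)
    n_cell_lines: dict = field(default_factory=dict)
    sc_detection: dict = field(default_factory=dict)
    sc_design: list = field(default_factory=list)
    separable_pairs: list = field(default_factory=list)
    hk_genes: list = field(default_factory=lambda: default_housekeeping_genes()[:50])
    seed: int = 0

    # ---- derived names -------------------------------------------------
    @property
    def targets(self) -> list:
        return [f"TGT{i + 1:02d}" for i in range(self.n_targets)]

    @property
    def background_genes(self) -> list:
        n_bg = self.n_genes - self.n_targets - len(self.hk_genes)
        return [f"BG{i + 1:05d}" for i in range(n_bg)]

    @property
    def genes(self) -> list:
        return self.targets + list(self.hk_genes) + self.background_genes

    def validate(self) -> None:
        if self.n_genes < self.n_targets + len(self.hk_genes):
            raise SpecError(
                "n_genes must be >= n_targets + housekeeping set size "
                f"(got n_genes={self.n_genes})"
            )
        tset = set(self.targets)
        for ct, effects in self.cancer_types.items():
            bad = set(effects) - tset
            if bad:
                raise SpecError(f"cancer_types[{ct!r}] references unknown "
                                f"targets {sorted(bad)}")
        bad = set(self.met_shift) - tset
        if bad:
            raise SpecError(f"met_shift references unknown targets {sorted(bad)}")
        for t, r in self.concordance_rate.items():
            if t not in tset:
                raise SpecError(f"concordance_rate references unknown target {t!r}")
            if not 0.0 <= r <= 1.0:
                raise SpecError(f"concordance_rate[{t!r}]={r} outside [0, 1]")
        for t, per_ct in self.sc_detection.items():
            for ctype, p in per_ct.items():
                if not 0.0 <= p <= 1.0:
                    raise SpecError(
                        f"sc_detection[{t!r}][{ctype!r}]={p} outside [0, 1]")
        for pair in self.separable_pairs:
            ga, gb, ct, nt = pair
            if ga not in tset or gb not in tset:
                raise SpecError(f"separable_pairs entry {pair} references genes "
                                "outside the target list")
            if nt not in self.normal_tissues:
                raise SpecError(f"separable_pairs entry {pair} references "
                                f"unknown normal tissue {nt!r}")
        ids = [s.study_id for s in self.studies]
        if len(set(ids)) != len(ids):
            raise SpecError("studies contain duplicate study_id values")


@dataclass
class GroundTruth:
    """Planted parameters, serialized alongside every generated dataset."""

    target_effects: dict = field(default_factory=dict)
    met_shift: dict = field(default_factory=dict)
    concordance_rate: dict = field(default_factory=dict)
    best_line: dict = field(default_factory=dict)
    sc_detection: dict = field(default_factory=dict)
    separable_pairs: list = field(default_factory=list)
    study_scale: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# bulk expression
# ---------------------------------------------------------------------------

def _gene_means(spec: CohortSpec) -> pd.Series:
    rng = substream(spec.seed, "gene_means")
    mu = pd.Series(0.0, index=spec.genes)
    mu[spec.targets] = rng.normal(0.5, 0.5, spec.n_targets)
    # housekeeping genes: high expression spread over a range so the
    # 1st/50th/90th percentile thresholds are well separated
    mu[list(spec.hk_genes)] = np.linspace(3.0, 5.0, len(spec.hk_genes))
    mu[spec.background_genes] = rng.normal(1.0, 1.0, len(spec.background_genes))
    return mu


def _signatures(spec: CohortSpec) -> dict:
    """Per-group background-gene log offsets (targets and hk stay clean)."""
    n_bg = len(spec.background_genes)
    sigs = {}
    for code in list(spec.cancer_types) + list(spec.normal_tissues):
        rng = substream(spec.seed, "signature", str(code))
        sigs[code] = rng.normal(0.0, SIGNATURE_SD, n_bg)
    return sigs


def _sample_roster(spec: CohortSpec) -> list:
    roster = []
    for ct in spec.cancer_types:
        roster.append((ct, "primary"))
        roster.append((ct, "metastatic"))
    for nt in spec.normal_tissues:
        roster.append((nt, "normal"))
    if not roster:
        raise SpecError("spec defines no cancer_types and no normal_tissues")
    return roster


def _pair_adjustments(spec: CohortSpec):
    """Extra elevations/suppressions that plant separable pairs."""
    cancer_boost: dict = {}
    normal_shift: dict = {}
    for ga, gb, ct, nt in spec.separable_pairs:
        for g in (ga, gb):
            if spec.cancer_types.get(ct, {}).get(g, 0.0) < PAIR_BOOST:
                cancer_boost[(g, ct)] = PAIR_BOOST
            normal_shift[(g, nt)] = PAIR_NORMAL_SUPPRESSION
    return cancer_boost, normal_shift


def generate_bulk(spec: CohortSpec):
    """Bulk expression cohort: (ExpressionMatrix, annotation, GroundTruth).

    Log-normal background per gene; study-specific multiplicative scale;
    targets elevated in their assigned cancer types, shifted in metastases
    by ``met_shift``; cell lines share their parent type's background
    signature (tumors carry it attenuated by purity).  Tissue classes
    normal / primary / metastatic / cell_line are all represented.
    """
    spec.validate()
    genes = spec.genes
    mu = _gene_means(spec).to_numpy()
    sigs = _signatures(spec)
    roster = _sample_roster(spec)
    bg_slice = slice(spec.n_targets + len(spec.hk_genes), spec.n_genes)
    tgt_index = {t: i for i, t in enumerate(spec.targets)}
    cancer_boost, normal_shift = _pair_adjustments(spec)

    columns, ann_rows = [], []
    blocks = []
    for study in spec.studies:
        rng = substream(spec.seed, "bulk", study.study_id)
        block = np.empty((spec.n_genes, study.n_samples))
        for k in range(study.n_samples):
            code, tclass = roster[k % len(roster)]
            sid = f"{study.study_id}_{k:04d}"
            logv = mu + rng.normal(0.0, NOISE_SD, spec.n_genes)
            purity = np.nan
            if tclass in ("primary", "metastatic"):
                purity = rng.uniform(0.5, 1.0)
                logv[bg_slice] += purity * sigs[code]
                for t, eff in spec.cancer_types[code].items():
                    logv[tgt_index[t]] += eff
                for (g, ct), boost in cancer_boost.items():
                    if ct == code:
                        logv[tgt_index[g]] += boost
                if tclass == "metastatic":
                    for t, shift in spec.met_shift.items():
                        logv[tgt_index[t]] += shift
            else:  # normal tissue
                logv[bg_slice] += sigs[code]
                for (g, nt), shift in normal_shift.items():
                    if nt == code:
                        logv[tgt_index[g]] += shift
            block[:, k] = np.exp(logv) * study.scale_factor
            columns.append(sid)
            ann_rows.append((sid, study.study_id, code, tclass, purity, ""))
        blocks.append(block)

    # cell lines: one designated "best" line per parent type (index 0) is a
    # low-noise draw from the type centroid with boosted target expression
    gt_best: dict = {}
    line_block, line_cols = [], []
    for ptype, count in spec.n_cell_lines.items():
        if ptype not in spec.cancer_types:
            raise SpecError(f"n_cell_lines references unknown cancer type {ptype!r}")
        rng = substream(spec.seed, "lines", str(ptype))
        for i in range(count):
            sid = f"CL_{ptype}_{i:02d}"
            noise_sd = 0.15 if i == 0 else 0.9
            logv = mu + rng.normal(0.0, noise_sd, spec.n_genes)
            logv[bg_slice] += sigs[ptype]
            for t, eff in spec.cancer_types[ptype].items():
                logv[tgt_index[t]] += eff
                if i == 0:
                    logv[tgt_index[t]] += BEST_LINE_TARGET_BOOST
                    gt_best[f"{t}|{ptype}"] = sid
            line_block.append(np.exp(logv))
            line_cols.append(sid)
            ann_rows.append((sid, "CELLLINES", ptype, "cell_line", np.nan, ptype))
    if line_cols:
        blocks.append(np.column_stack(line_block))
        columns.extend(line_cols)

    values = pd.DataFrame(np.hstack(blocks), index=pd.Index(genes, name="gene"),
                          columns=columns)
    ann = pd.DataFrame(ann_rows, columns=["sample_id", "study_id", "cancer_type",
                                          "tissue_class", "purity",
                                          "parent_cancer_type"])
    study_map = ann.set_index("sample_id")["study_id"]
    em = ExpressionMatrix(values=values, platform="rnaseq",
                          study_of_sample=study_map)
    gt = GroundTruth(
        target_effects={ct: dict(eff) for ct, eff in spec.cancer_types.items()},
        met_shift=dict(spec.met_shift),
        concordance_rate=dict(spec.concordance_rate),
        best_line=gt_best,
        sc_detection={t: dict(d) for t, d in spec.sc_detection.items()},
        separable_pairs=[list(p) for p in spec.separable_pairs],
        study_scale={s.study_id: s.scale_factor for s in spec.studies},
    )
    return em, ann, gt


# ---------------------------------------------------------------------------
# paired RNA + protein
# ---------------------------------------------------------------------------

def generate_paired_omics(spec: CohortSpec):
    """Paired RNA/protein cohort with planted high-call agreement.

    The RNA matrix is a bulk cohort; per target and sample the protein
    matrix is constructed so its high-expression indicator equals the RNA
    indicator with probability ``concordance_rate[target]`` and is flipped
    otherwise.  Protein values are placed deterministically above or below
    the housekeeping band (with rank-neutral filler genes keeping the band
    position identical in every sample), so the planted agreement survives
    the percentile transform and thresholding exactly.

    Returns (PairedOmics, annotation, GroundTruth).  Import of PairedOmics
    is deferred to avoid a cycle.
    """
    from .concordance import PairedOmics

    spec.validate()
    missing = [t for t in spec.targets if t not in spec.concordance_rate]
    if missing:
        raise SpecError(f"concordance_rate missing for targets {missing}")
    em, ann, gt = generate_bulk(spec)
    rna_pm = rank_percentile(em, child_seed(spec.seed, "rna_rank"))
    hk_rna = hk_reference(rna_pm, spec.hk_genes)
    rna_high = rna_pm.values.loc[spec.targets] > hk_rna.pooled.p90

    rng = substream(spec.seed, "concordance")
    n_s = em.n_samples
    flips = pd.DataFrame(
        {t: rng.random(n_s) >= spec.concordance_rate[t] for t in spec.targets}
    ).T.set_axis(em.sample_ids, axis=1).set_axis(spec.targets, axis=0)
    protein_high = rna_high ^ flips

    # protein matrix: background ~ lognormal; housekeeping proteins occupy a
    # fixed high band; targets sit above the band when "high", far below when
    # not; filler genes keep the number of genes above the band constant per
    # sample so the percentile threshold is identical everywhere
    prng = substream(spec.seed, "protein")
    n_g = spec.n_genes
    vals = np.exp(prng.normal(0.0, 1.0, (n_g, n_s)))
    gene_pos = {g: i for i, g in enumerate(spec.genes)}
    hk_rows = [gene_pos[g] for g in spec.hk_genes]
    vals[hk_rows, :] = np.exp(
        np.linspace(3.0, 4.0, len(hk_rows))[:, None]
        + prng.uniform(0.0, 0.05, (len(hk_rows), n_s))
    )
    n_t = spec.n_targets
    filler_rows = [gene_pos[g] for g in spec.background_genes[:n_t]]
    high_arr = protein_high.to_numpy()
    for j in range(n_s):
        n_high = int(high_arr[:, j].sum())
        for i, t in enumerate(spec.targets):
            row = gene_pos[t]
            if high_arr[i, j]:
                vals[row, j] = np.exp(8.0 + prng.uniform(0, 0.5))
            else:
                vals[row, j] = np.exp(-6.0 - prng.uniform(0, 0.5))
        for k, row in enumerate(filler_rows):
            if k < n_t - n_high:
                vals[row, j] = np.exp(6.0 + prng.uniform(0, 0.5))

    prot_em = ExpressionMatrix(
        values=pd.DataFrame(vals, index=em.values.index, columns=em.sample_ids),
        platform="rnaseq", study_of_sample=em.study_of_sample,
    )
    prot_pm = rank_percentile(prot_em, child_seed(spec.seed, "prot_rank"))
    hk_prot = hk_reference(prot_pm, spec.hk_genes)
    paired = PairedOmics(rna=rna_pm, protein=prot_pm,
                         hk_ref_rna=hk_rna, hk_ref_protein=hk_prot)
    return paired, ann, gt


# ---------------------------------------------------------------------------
# single cell
# ---------------------------------------------------------------------------

def _default_sc_design(spec: CohortSpec) -> list:
    design = []
    tumor_types = list(spec.cancer_types) or ["TUM"]
    for i in range(6):
        ct = tumor_types[i % len(tumor_types)]
        design.append(ScSample(
            sample_id=f"SC_T{i:02d}", tissue=ct,
            groups=[ScGroup("malignant", 300, True),
                    ScGroup("T_cell", 100), ScGroup("fibroblast", 50)],
        ))
    for nt in spec.normal_tissues:
        for rep in range(2):
            design.append(ScSample(
                sample_id=f"SC_{nt}_{rep}", tissue=nt,
                groups=[ScGroup("epithelial", 150), ScGroup("immune", 100),
                        ScGroup("stromal", 50)],
            ))
    return design


def generate_single_cell(spec: CohortSpec):
    """Sparse single-cell counts with planted per-(target, cell type) detection.

    A cell of type c detects target t with probability
    ``sc_detection[t][c]`` (default 0.1); a detected cell draws a positive
    count (1 + Poisson), an undetected cell is exactly zero.  Background
    genes get gene-specific moderate detection rates; housekeeping genes
    are detected in most cells.  Returns (counts CSR cells x genes, genes,
    cell annotation, GroundTruth).
    """
    spec.validate()
    design = spec.sc_design or _default_sc_design(spec)
    genes = spec.genes
    rng = substream(spec.seed, "sc_background")
    base_p = np.empty(spec.n_genes)
    base_p[: spec.n_targets] = 0.1
    n_hk = len(spec.hk_genes)
    base_p[spec.n_targets: spec.n_targets + n_hk] = 0.8
    base_p[spec.n_targets + n_hk:] = rng.uniform(0.02, 0.3,
                                                 spec.n_genes - spec.n_targets - n_hk)
    tgt_index = {t: i for i, t in enumerate(spec.targets)}

    rows, cols, data = [], [], []
    ann_rows = []
    cell_i = 0
    crng = substream(spec.seed, "sc_cells")
    for sample in design:
        for grp in sample.groups:
            p = base_p.copy()
            for t, per_ct in spec.sc_detection.items():
                if grp.cell_type in per_ct:
                    p[tgt_index[t]] = per_ct[grp.cell_type]
            for _ in range(grp.n_cells):
                detected = np.nonzero(crng.random(spec.n_genes) < p)[0]
                counts = 1 + crng.poisson(1.3, detected.size)
                rows.extend([cell_i] * detected.size)
                cols.extend(detected.tolist())
                data.extend(counts.tolist())
                ann_rows.append((f"cell{cell_i:06d}", sample.sample_id,
                                 grp.cell_type, bool(grp.malignant),
                                 sample.tissue))
                cell_i += 1
    counts = sparse.csr_matrix(
        (data, (rows, cols)), shape=(cell_i, spec.n_genes), dtype=np.int64
    )
    cells = pd.DataFrame(ann_rows, columns=["cell_id", "sample_id", "cell_type",
                                            "malignant", "tissue"]
                         ).set_index("cell_id")
    gt = GroundTruth(
        met_shift=dict(spec.met_shift),
        concordance_rate=dict(spec.concordance_rate),
        sc_detection={t: dict(d) for t, d in spec.sc_detection.items()},
        separable_pairs=[list(p) for p in spec.separable_pairs],
    )
    return counts, pd.Index(genes, name="gene"), cells, gt


def default_spec(seed: int = 0) -> CohortSpec:
    """The reference synthetic cohort used by examples and the pipeline.

    Five tumor types with distinct elevated targets, three normal tissues,
    two studies on different scales, signed metastatic shifts in both
    directions, a spread of concordance rates, twenty cell lines across the
    five types, heterogeneous single-cell detection, and one planted
    separable pair (with TGT09/TGT10 left null).
    """
    types = {
        "BLCA": {"TGT01": 2.5, "TGT02": 1.5},
        "LUAD": {"TGT03": 2.5, "TGT04": 1.5},
        "PRAD": {"TGT05": 2.5},
        "SKCM": {"TGT06": 2.5},
        "COAD": {"TGT07": 2.0, "TGT08": 2.0},
    }
    return CohortSpec(
        n_genes=2000,
        n_targets=12,
        studies=[StudyDesign("S1", 390, 1.0), StudyDesign("S2", 390, 5.0)],
        cancer_types=types,
        normal_tissues=("LUNG", "LIVER", "COLON"),
        met_shift={"TGT01": -1.0, "TGT03": 1.0, "TGT05": 0.8},
        concordance_rate={t: r for t, r in zip(
            [f"TGT{i + 1:02d}" for i in range(12)],
            [0.5, 0.8, 0.9, 0.97, 0.9, 0.9, 0.85, 0.95, 0.9, 0.9, 0.9, 0.9])},
        n_cell_lines={ct: 4 for ct in types},
        sc_detection={
            "TGT01": {"malignant": 0.94, "T_cell": 0.05, "fibroblast": 0.05,
                      "epithelial": 0.6, "immune": 0.05, "stromal": 0.05},
            "TGT05": {"malignant": 0.44, "T_cell": 0.02, "fibroblast": 0.02},
            "TGT06": {"malignant": 0.05},
        },
        separable_pairs=[("TGT11", "TGT12", "BLCA", "LUNG")],
        seed=int(seed),
    )
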