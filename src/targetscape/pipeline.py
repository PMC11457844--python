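"""End-to-end pipeline: simulate -> harmonize -> all analysis stages.

``run_pipeline`` executes the enabled stages in dependency order on either
a generated reference cohort (default) or user-supplied inputs, writing
versioned TSV/JSON outputs plus a provenance record (seed, config hash,
package version) into the output directory.  Identical (config, seed)
runs produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from ._rng import child_seed
from . import cellline, combos, concordance, differential, single_cell
from .containers import ValidationError
from .harmonize import hk_reference, rank_percentile
from .io import (
    FLOAT_FORMAT,
    write_annotation,
    write_hk_reference,
    write_matrix,
    write_sparse_cells,
)
from .simulate import CohortSpec, default_spec, generate_bulk, \
    generate_paired_omics, generate_single_cell

log = logging.getLogger("targetscape")

ALL_STAGES = ("simulate", "normalize", "concordance", "diffmet",
              "match-lines", "sc-het", "combo-screen")


@dataclass
class RunConfig:
    """Pipeline configuration; round-trips losslessly through YAML/JSON."""

    seed: int = 0
    outdir: str = "targetscape_out"
    platform: str = "rnaseq"
    hk_list: str | None = None
    min_group: int = 10
    purity_min: float = 0.6
    pct: float = 0.95
    alpha: float = 0.05
    f1_min: float = 0.95
    min_cells: int = 20
    stages: tuple = ALL_STAGES

    def validate(self) -> None:
        checks = [
            ("min_group", self.min_group >= 1),
            ("purity_min", 0.0 <= self.purity_min <= 1.0),
            ("pct", 0.0 <= self.pct <= 1.0),
            ("alpha", 0.0 < self.alpha < 1.0),
            ("f1_min", 0.0 <= self.f1_min <= 1.0),
            ("min_cells", self.min_cells >= 1),
        ]
        for name, ok in checks:
            if not ok:
                raise ValidationError(f"config field {name} out of range")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValidationError(f"unknown stages {sorted(unknown)}")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        payload = yaml.safe_load(text)
        cfg = cls(**payload)
        cfg.stages = tuple(cfg.stages)
        cfg.validate()
        return cfg

    def to_file(self, path) -> None:
        payload = dataclasses.asdict(self)
        payload["stages"] = list(self.stages)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))

    def digest(self) -> str:
        # outdir is excluded: where outputs land is not part of the
        # analysis identity
        payload = dataclasses.asdict(self)
        payload.pop("outdir")
        payload["stages"] = list(self.stages)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA",
              float_format=FLOAT_FORMAT)


def run_pipeline(config: RunConfig, spec: CohortSpec | None = None) -> dict:
    """Run the enabled stages and return a report bundle (paths + summaries).

    With no explicit ``spec`` the reference synthetic cohort for
    ``config.seed`` is generated.  A stage failure aborts its dependents
    but independent stages still run; any failure is re-raised at the end.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if spec is None:
        spec = default_spec(config.seed)
    enabled = set(config.stages)
    report: dict = {"outdir": str(outdir), "outputs": [], "failures": {}}

    em, ann, gt = generate_bulk(spec)
    targets = spec.targets
    if "simulate" in enabled:
        write_matrix(em, outdir / "bulk_expression.tsv")
        write_annotation(ann, outdir / "sample_annotation.tsv")
        gt.to_json(outdir / "ground_truth.json")
        report["outputs"] += ["bulk_expression.tsv", "sample_annotation.tsv",
                              "ground_truth.json"]

    pm = hk = None
    if "normalize" in enabled:
        pm = rank_percentile(em, child_seed(config.seed, "pipeline_rank"))
        hk = hk_reference(pm, spec.hk_genes)
        write_matrix(pm, outdir / "percentiles.tsv")
        write_hk_reference(hk, outdir / "hk_reference.json")
        report["outputs"] += ["percentiles.tsv", "hk_reference.json"]

    ann_idx = ann.set_index("sample_id")

    if "concordance" in enabled:
        try:
            paired, p_ann, _ = generate_paired_omics(spec)
            table = concordance.concordance_table(paired, targets,
                                                  min_samples=config.min_group)
            _write_tsv(table, outdir / "concordance.tsv")
            summary = concordance.summarize_accuracy(table["accuracy"])
            (outdir / "concordance_summary.json").write_text(
                json.dumps(summary, indent=1, sort_keys=True))
            report["outputs"] += ["concordance.tsv", "concordance_summary.json"]
            report["concordance_summary"] = summary
        except Exception as exc:
            log.exception("concordance stage failed")
            report["failures"]["concordance"] = str(exc)

    if pm is not None and "diffmet" in enabled:
        try:
            diff = differential.met_screen(pm, ann_idx, targets,
                                           min_group=config.min_group)
            _write_tsv(diff, outdir / "diffmet.tsv")
            wide = diff.pivot(index="target", columns="cancer_type", values="r")
            wide.to_csv(outdir / "diffmet_r_matrix.tsv", sep="\t", na_rep="NA",
                        float_format=FLOAT_FORMAT)
            land = differential.landscape_summary(pm, ann_idx, targets, hk)
            _write_tsv(land, outdir / "landscape.tsv")
            report["outputs"] += ["diffmet.tsv", "diffmet_r_matrix.tsv",
                                  "landscape.tsv"]
        except Exception as exc:
            log.exception("diffmet stage failed")
            report["failures"]["diffmet"] = str(exc)

    if pm is not None and "match-lines" in enabled:
        try:
            is_line = ann_idx["tissue_class"] == "cell_line"
            p_lines = type(pm)(values=pm.values.loc[:, is_line[is_line].index],
                               rank_seed=pm.rank_seed,
                               study_of_sample=pm.study_of_sample[is_line])
            p_tum = type(pm)(values=pm.values.loc[:, is_line[~is_line].index],
                             rank_seed=pm.rank_seed,
                             study_of_sample=pm.study_of_sample[~is_line])
            matches = cellline.match(p_tum, p_lines, ann_idx, targets,
                                     line_ann=ann_idx[is_line],
                                     pct=config.pct,
                                     purity_min=config.purity_min)
            _write_tsv(matches, outdir / "cellline_matches.tsv")
            _write_tsv(cellline.match_counts(matches),
                       outdir / "cellline_match_counts.tsv")
            report["outputs"] += ["cellline_matches.tsv",
                                  "cellline_match_counts.tsv"]
        except Exception as exc:
            log.exception("match-lines stage failed")
            report["failures"]["match-lines"] = str(exc)

    if "sc-het" in enabled:
        try:
            counts, genes, cells, _ = generate_single_cell(spec)
            write_sparse_cells(counts, genes, cells, outdir)
            b = single_cell.binarize(counts, genes, cells)
            tf = single_cell.tumor_fraction_positive(b, targets,
                                                     min_cells=config.min_cells)
            _write_tsv(tf, outdir / "sc_tumor_fractions.tsv")
            frames = []
            for tissue in spec.normal_tissues:
                cf = single_cell.celltype_fraction_positive(b, targets,
                                                            tissue=tissue)
                cf.insert(0, "tissue", tissue)
                frames.append(cf)
            if frames:
                _write_tsv(pd.concat(frames, ignore_index=True),
                           outdir / "sc_celltype_fractions.tsv")
            report["outputs"] += ["sc_counts.mtx", "sc_genes.txt",
                                  "sc_cells.tsv", "sc_tumor_fractions.tsv",
                                  "sc_celltype_fractions.tsv"]
        except Exception as exc:
            log.exception("sc-het stage failed")
            report["failures"]["sc-het"] = str(exc)

    if pm is not None and "combo-screen" in enabled:
        try:
            not_line = ann_idx["tissue_class"] != "cell_line"
            fits, summary = combos.screen_all(
                pm, ann_idx[not_line], targets, alpha=config.alpha,
                f1_min=config.f1_min, min_group=config.min_group)
            _write_tsv(fits, outdir / "combo_fits.tsv")
            _write_tsv(summary, outdir / "combo_summary.tsv")
            report["outputs"] += ["combo_fits.tsv", "combo_summary.tsv"]
        except Exception as exc:
            log.exception("combo-screen stage failed")
            report["failures"]["combo-screen"] = str(exc)

    provenance = {
        "seed": config.seed,
        "config_digest": config.digest(),
        "version": __version__,
        "stages": sorted(enabled),
        "quantile_definition": "linear interpolation between order statistics",
        "wilcoxon": "exact when min group size <= 25 and tie-free, else "
                    "normal approximation with continuity correction",
        "fdr": "Benjamini-Hochberg, one family per screen",
    }
    (outdir / "provenance.json").write_text(
        json.dumps(provenance, indent=1, sort_keys=True))
    report["outputs"].append("provenance.json")
    report["provenance"] = provenance
    if report["failures"]:
        raise RuntimeError(f"stage failures: {report['failures']}")
    return report
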