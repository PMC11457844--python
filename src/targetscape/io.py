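"""Readers and writers for the delimited formats shared by all stages.

Bulk matrices are TSV with genes as rows and a header of sample IDs;
annotations are TSV with sample_id / study_id / cancer_type /
tissue_class / purity columns; single-cell counts are Matrix Market
triplets with a gene list and a cell-annotation TSV.  The missing-value
token is "NA".  Readers validate invariants and fail loudly rather than
coercing malformed input.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .containers import (
    ExpressionMatrix,
    HousekeepingReference,
    PercentileMatrix,
    Thresholds,
    ValidationError,
    validate_annotation,
)

NA_TOKEN = "NA"
FLOAT_FORMAT = "%.8g"


def read_matrix(path, platform: str, study_of_sample=None,
                ann_path=None) -> ExpressionMatrix:
    """Read a genes x samples TSV into an ExpressionMatrix.

    The study map comes from ``study_of_sample`` (sample -> study), from an
    annotation TSV at ``ann_path``, or — failing both — every sample is
    assigned to a single study "S1".
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA_TOKEN],
                         keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ValidationError(f"cannot parse matrix {path}: {exc}") from exc
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()[:5]
        raise ValidationError(f"{path}: duplicated gene rows {dupes}")
    non_numeric = df.columns[df.dtypes == object]
    if len(non_numeric):
        raise ValidationError(
            f"{path}: non-numeric cells in columns {list(non_numeric[:5])}"
        )
    if study_of_sample is None:
        if ann_path is not None:
            ann = read_annotation(ann_path)
            study_of_sample = ann["study_id"]
        else:
            study_of_sample = pd.Series("S1", index=df.columns)
    return ExpressionMatrix(values=df, platform=platform,
                            study_of_sample=pd.Series(study_of_sample))


def write_matrix(m, path) -> None:
    """Write an Expression/Percentile matrix (or frame) as TSV with NA tokens."""
    df = m.values if hasattr(m, "values") and isinstance(
        getattr(m, "values"), pd.DataFrame) else m
    df.to_csv(path, sep="\t", na_rep=NA_TOKEN, float_format=FLOAT_FORMAT)


def read_annotation(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", na_values=[NA_TOKEN], keep_default_na=False)
    return validate_annotation(ann)


def write_annotation(ann: pd.DataFrame, path) -> None:
    out = ann.reset_index() if ann.index.name == "sample_id" else ann
    out.to_csv(path, sep="\t", index=False, na_rep=NA_TOKEN,
               float_format=FLOAT_FORMAT)


def read_sparse_cells(mtx_path, genes_path, ann_path):
    """Read Matrix Market counts + gene list + cell annotations, aligned.

    The matrix is cells x genes; annotation row order must cover exactly the
    matrix rows (cell_id column).  Dimension or identity mismatches raise.
    """
    counts = sparse.csr_matrix(spio.mmread(mtx_path))
    genes = pd.Index(
        [line.strip() for line in Path(genes_path).read_text().splitlines()
         if line.strip()],
        name="gene",
    )
    cells = pd.read_csv(ann_path, sep="\t")
    if "cell_id" not in cells.columns:
        raise ValidationError(f"{ann_path}: missing cell_id column")
    cells = cells.set_index("cell_id")
    if counts.shape[0] == 0 or counts.shape[1] == 0:
        raise ValidationError(f"{mtx_path}: empty matrix")
    if counts.shape[1] != len(genes):
        raise ValidationError(
            f"matrix has {counts.shape[1]} genes but gene list has {len(genes)}"
        )
    if counts.shape[0] != len(cells):
        raise ValidationError(
            f"matrix has {counts.shape[0]} cells but annotation has {len(cells)}"
        )
    if "malignant" in cells.columns:
        cells["malignant"] = cells["malignant"].astype(bool)
    return counts, genes, cells


def write_sparse_cells(counts, genes, cells: pd.DataFrame, outdir,
                       prefix: str = "sc") -> None:
    outdir = Path(outdir)
    spio.mmwrite(str(outdir / f"{prefix}_counts.mtx"), sparse.coo_matrix(counts))
    (outdir / f"{prefix}_genes.txt").write_text("\n".join(genes) + "\n")
    out = cells.reset_index() if cells.index.name == "cell_id" else cells
    out.to_csv(outdir / f"{prefix}_cells.tsv", sep="\t", index=False)


def write_hk_reference(ref: HousekeepingReference, path) -> None:
    payload = {
        "hk_genes": list(ref.hk_genes),
        "per_study": {str(k): [float(x) for x in row]
                      for k, row in ref.per_study.iterrows()},
        "pooled": {"p01": ref.pooled.p01, "p50": ref.pooled.p50,
                   "p90": ref.pooled.p90},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def read_hk_reference(path) -> HousekeepingReference:
    with open(path) as fh:
        payload = json.load(fh)
    per_study = pd.DataFrame.from_dict(payload["per_study"], orient="index",
                                       columns=["p01", "p50", "p90"]).sort_index()
    pooled = Thresholds(**payload["pooled"])
    return HousekeepingReference(hk_genes=payload["hk_genes"],
                                 per_study=per_study, pooled=pooled)


def write_percentiles(p: PercentileMatrix, path) -> None:
    write_matrix(p, path)


def read_percentiles(path, rank_seed: int, study_of_sample=None) -> PercentileMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA_TOKEN],
                     keep_default_na=False)
    if study_of_sample is None:
        study_of_sample = pd.Series("S1", index=df.columns)
    return PercentileMatrix(values=df, rank_seed=rank_seed,
                            study_of_sample=pd.Series(study_of_sample))


def read_gene_list(path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines()
            if line.strip()]
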