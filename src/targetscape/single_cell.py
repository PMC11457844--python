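"""Single-cell target detection fractions.

Because scRNA-seq dropout makes quantitative per-cell values unreliable,
counts are binarized (any non-zero value -> detected) and heterogeneity is
summarized as the fraction of cells in which a target is detected: per
tumor sample over malignant cells, and per cell type within normal
tissues.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import sparse

from .containers import ValidationError


@dataclass
class BinaryCellMatrix:
    """Cells x genes 0/1 detection matrix with per-cell annotations.

    ``cells`` is indexed by cell_id and carries sample_id, cell_type and a
    boolean malignant flag (plus optional tissue).
    """

    matrix: sparse.csr_matrix
    genes: pd.Index
    cells: pd.DataFrame

    def __post_init__(self) -> None:
        self.genes = pd.Index(self.genes)
        if self.matrix.shape != (len(self.cells), len(self.genes)):
            raise ValidationError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.cells)} cells x {len(self.genes)} genes"
            )
        for col in ("sample_id", "cell_type", "malignant"):
            if col not in self.cells.columns:
                raise ValidationError(f"cell annotation missing column {col!r}")
        if self.matrix.nnz and not np.all(self.matrix.data == 1):
            raise ValidationError("binary matrix must contain only 0/1 values")


def binarize(counts, genes: Iterable[str], cells: pd.DataFrame) -> BinaryCellMatrix:
    """Map any positive count to 1 (detected). Idempotent; rejects negatives."""
    m = sparse.csr_matrix(counts)
    if m.nnz and m.data.min() < 0:
        raise ValidationError("negative counts are not allowed")
    b = m.copy()
    b.data = (b.data > 0).astype(np.int8)
    b.eliminate_zeros()
    return BinaryCellMatrix(matrix=b, genes=pd.Index(genes), cells=cells)


def _fraction(b: BinaryCellMatrix, cell_mask: np.ndarray, gene_idx: int) -> float:
    col = b.matrix[:, gene_idx]
    pos = np.asarray(col.todense()).ravel()[cell_mask].sum()
    return float(pos) / int(cell_mask.sum())


def tumor_fraction_positive(
    b: BinaryCellMatrix, targets: Iterable[str], min_cells: int = 20
) -> pd.DataFrame:
    """Per (target, sample) fraction of malignant cells detecting the target.

    Samples with no malignant cell are omitted with a warning; samples with
    fewer than ``min_cells`` malignant cells are kept but flagged
    low-confidence.
    """
    targets = [t for t in targets if t in b.genes]
    gidx = {t: b.genes.get_loc(t) for t in targets}
    mal = b.cells["malignant"].to_numpy(dtype=bool)
    dense = None
    rows = []
    skipped = []
    for sample, sub in b.cells.groupby("sample_id"):
        mask = (b.cells["sample_id"] == sample).to_numpy() & mal
        n = int(mask.sum())
        if n == 0:
            skipped.append(sample)
            continue
        if dense is None:
            cols = sorted(gidx.values())
            dense = np.asarray(b.matrix[:, cols].todense())
            colpos = {g: i for i, g in enumerate(cols)}
        for t in targets:
            frac = float(dense[mask, colpos[gidx[t]]].sum()) / n
            rows.append((t, sample, n, frac, n < min_cells))
    if skipped:
        warnings.warn(f"{len(skipped)} sample(s) with no malignant cells omitted")
    return pd.DataFrame(rows, columns=["target", "sample_id", "n_cells",
                                       "fraction", "low_confidence"])


def celltype_fraction_positive(
    b: BinaryCellMatrix, targets: Iterable[str], tissue: str | None = None
) -> pd.DataFrame:
    """Per (target, cell type) detection fraction, per replicate and pooled.

    When a ``tissue`` column is present and ``tissue`` is given, only cells
    of that tissue enter.  Replicate samples are reported individually
    (scope='replicate') and pooled across replicates (scope='pooled',
    sample_id empty); the pooled fraction equals the cell-count-weighted
    mean of replicate fractions.
    """
    targets = [t for t in targets if t in b.genes]
    cells = b.cells
    row_mask = np.ones(len(cells), dtype=bool)
    if tissue is not None:
        if "tissue" not in cells.columns:
            raise ValidationError("cell annotation has no tissue column")
        row_mask = (cells["tissue"] == tissue).to_numpy()
    cols = [b.genes.get_loc(t) for t in targets]
    dense = np.asarray(b.matrix[:, cols].todense())
    rows = []
    sub = cells[row_mask]
    for ctype, cgrp in sub.groupby("cell_type"):
        type_mask = row_mask & (cells["cell_type"] == ctype).to_numpy()
        for j, t in enumerate(targets):
            for sample, sgrp in cgrp.groupby("sample_id"):
                smask = type_mask & (cells["sample_id"] == sample).to_numpy()
                n = int(smask.sum())
                if n == 0:
                    continue
                rows.append((t, ctype, sample, "replicate", n,
                             float(dense[smask, j].sum()) / n))
            n_all = int(type_mask.sum())
            if n_all:
                rows.append((t, ctype, "", "pooled", n_all,
                             float(dense[type_mask, j].sum()) / n_all))
    return pd.DataFrame(rows, columns=["target", "cell_type", "sample_id",
                                       "scope", "n_cells", "fraction"])
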