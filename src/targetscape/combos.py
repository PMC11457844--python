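"""Two-target combination screening.

For every pair of cell-surface targets and every (cancer type, normal
tissue) comparison, a logistic regression of class (cancer = 1) on the two
genes' percentile values is fitted.  A pair passes a comparison when
(i) the fit separates the classes well — F1 for the cancer class above
``f1_min`` (default 0.95) — with both coefficients positive (expression
higher in cancer), and (ii) each gene contributes independently — both
per-gene Wald p values, corrected for multiple testing across the whole
screen, below ``alpha``.  A pair is highlighted when it passes in strictly
more than 90% of its comparisons.

Perfectly separable comparisons make the maximum-likelihood estimates
diverge; those fits fall back to a lightly ridge-penalized model
(lambda = 1e-4) whose 0.5-probability rule supplies F1 and whose penalized
information matrix supplies Wald statistics, with ``separation_flag`` set.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, asdict
from typing import Iterable

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import f1_score
from statsmodels.stats.multitest import multipletests

from .containers import PercentileMatrix, ValidationError

RIDGE_LAMBDA = 1e-4
#: |coefficient| beyond which an unpenalized logistic fit is treated as
#: divergent (separation); percentile-scale predictors make legitimate
#: coefficients of a few tens, so this is deliberately generous
DIVERGENCE_BETA = 200.0


@dataclass
class ComboFit:
    gene_a: str
    gene_b: str
    cancer_type: str
    normal_tissue: str
    intercept: float
    beta_a: float
    beta_b: float
    p_a: float
    p_b: float
    f1: float
    direction_ok: bool
    separation_flag: bool
    n_cancer: int
    n_normal: int


def _ridge_logistic(X: np.ndarray, y: np.ndarray, lam: float = RIDGE_LAMBDA):
    """Ridge-penalized logistic IRLS; returns (beta, covariance)."""
    n, k = X.shape
    beta = np.zeros(k)
    for _ in range(100):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        grad = X.T @ (y - mu) - lam * beta
        hess = (X.T * w) @ X + lam * np.eye(k)
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-8:
            break
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    cov = np.linalg.inv((X.T * w) @ X + lam * np.eye(k))
    return beta, cov


def fit_pair(
    p: PercentileMatrix,
    ann: pd.DataFrame,
    gene_a: str,
    gene_b: str,
    cancer_type: str,
    normal_tissue: str,
    min_group: int = 10,
) -> ComboFit | None:
    """Fit one two-gene logistic comparison; None when a class floor fails.

    Cancer samples are the primary and metastatic tumors of ``cancer_type``;
    normal samples are the normal-tissue samples annotated with
    ``normal_tissue`` as their type code.
    """
    for g in (gene_a, gene_b):
        if g not in p.values.index:
            raise ValidationError(f"gene {g!r} absent from matrix")
    if ann.index.name != "sample_id":
        ann = ann.set_index("sample_id")
    cancer = ann.index[
        (ann["cancer_type"] == cancer_type)
        & ann["tissue_class"].isin(["primary", "metastatic"])
    ].intersection(p.values.columns)
    normal = ann.index[
        (ann["cancer_type"] == normal_tissue) & (ann["tissue_class"] == "normal")
    ].intersection(p.values.columns)
    if len(cancer) < min_group or len(normal) < min_group:
        return None
    cols = cancer.append(normal)
    X2 = p.values.loc[[gene_a, gene_b], cols].to_numpy(dtype=float).T
    y = np.concatenate([np.ones(len(cancer)), np.zeros(len(normal))])
    keep = ~np.isnan(X2).any(axis=1)
    X2, y = X2[keep], y[keep]
    if y.sum() < min_group or (1 - y).sum() < min_group:
        return None
    X = sm.add_constant(X2, has_constant="add")

    constant_pred = np.any(X2.std(axis=0) == 0)
    beta = cov = None
    separated = False
    if not constant_pred:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.Logit(y, X).fit(disp=0, maxiter=200)
                ok = (res.mle_retvals.get("converged", False)
                      and np.all(np.isfinite(res.bse))
                      and np.max(np.abs(res.params)) < DIVERGENCE_BETA)
                if ok:
                    beta, cov = res.params, res.cov_params()
            except Exception:
                pass
    if beta is None:
        separated = not constant_pred
        beta, cov = _ridge_logistic(X, y)
    prob = 1.0 / (1.0 + np.exp(-np.clip(X @ beta, -35, 35)))
    pred = prob >= 0.5
    f1 = float(f1_score(y, pred, zero_division=0.0))
    if f1 == 1.0:
        separated = True
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    if constant_pred:
        pvals = np.array([pvals[0], np.nan, np.nan])
    return ComboFit(
        gene_a=gene_a, gene_b=gene_b, cancer_type=cancer_type,
        normal_tissue=normal_tissue,
        intercept=float(beta[0]), beta_a=float(beta[1]), beta_b=float(beta[2]),
        p_a=float(pvals[1]), p_b=float(pvals[2]), f1=f1,
        direction_ok=bool(beta[1] > 0 and beta[2] > 0),
        separation_flag=bool(separated),
        n_cancer=int(y.sum()), n_normal=int((1 - y).sum()),
    )


def screen_all(
    p: PercentileMatrix,
    ann: pd.DataFrame,
    targets: Iterable[str],
    alpha: float = 0.05,
    f1_min: float = 0.95,
    min_group: int = 10,
    highlight_min: float = 0.90,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Screen all target pairs across every (cancer type, normal tissue).

    Returns (fits, summary).  ``fits`` has one row per attempted comparison
    with corrected per-gene Wald q values (BH across all per-gene tests in
    the screen) and the three criteria; ``summary`` has per-pair pass
    proportions with highlight = proportion strictly above
    ``highlight_min``.
    """
    targets = [t for t in targets if t in p.values.index]
    if len(targets) < 2:
        raise ValidationError("need at least two targets present in the matrix")
    if ann.index.name != "sample_id":
        ann = ann.set_index("sample_id")
    cancers = sorted(
        ann.loc[ann["tissue_class"].isin(["primary", "metastatic"]),
                "cancer_type"].unique()
    )
    normals = sorted(
        ann.loc[ann["tissue_class"] == "normal", "cancer_type"].unique()
    )
    fits: list[ComboFit] = []
    for ga, gb in itertools.combinations(targets, 2):
        for ct in cancers:
            for nt in normals:
                fit = fit_pair(p, ann, ga, gb, ct, nt, min_group=min_group)
                if fit is not None:
                    fits.append(fit)
    if not fits:
        warnings.warn("no comparison met the class-size floors")
        empty = pd.DataFrame()
        return empty, empty
    df = pd.DataFrame([asdict(f) for f in fits])
    raw = np.concatenate([df["p_a"].to_numpy(), df["p_b"].to_numpy()])
    finite = np.isfinite(raw)
    q = np.full(raw.size, np.nan)
    if finite.any():
        q[finite] = multipletests(raw[finite], method="fdr_bh")[1]
    df["q_a"] = q[: len(df)]
    df["q_b"] = q[len(df):]
    df["f1_ok"] = df["f1"] > f1_min
    df["wald_ok"] = (df["q_a"] < alpha) & (df["q_b"] < alpha)
    df["pass"] = df["f1_ok"] & df["wald_ok"] & df["direction_ok"]
    summary = (
        df.groupby(["gene_a", "gene_b"])
        .agg(n_comparisons=("pass", "size"), n_pass=("pass", "sum"))
        .reset_index()
    )
    summary["proportion_pass"] = summary["n_pass"] / summary["n_comparisons"]
    summary["highlight"] = summary["proportion_pass"] > highlight_min
    return df, summary
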