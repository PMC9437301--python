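"""Parametric empirical-Bayes batch correction and batch-severity diagnostics.

``combat_adjust`` implements the classical location/scale batch model: genes
are standardized against their batch-weighted grand mean and pooled variance,
per-batch location (gamma) and scale (delta^2) effects are estimated and then
shrunk towards batch-level priors — a normal prior on gamma and an
inverse-gamma prior on delta^2, with method-of-moments hyperparameters and
iterated conditional updates — before back-transforming. No covariate model
is fit. As a centring convention the corrected matrix is re-anchored per gene
to its pre-correction pooled (batch-weighted) mean, so correction never moves
a gene's overall level.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort_io import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class BatchModel:
    """Fitted EB batch model (arrays are gene-by-batch unless noted)."""

    batches: list
    grand_mean: pd.Series          # per gene
    pooled_var: pd.Series          # per gene
    gamma_hat: pd.DataFrame        # raw location effects (standardized scale)
    delta2_hat: pd.DataFrame       # raw scale effects
    gamma_star: pd.DataFrame       # EB-shrunken location
    delta2_star: pd.DataFrame      # EB-shrunken scale
    gamma_bar: pd.Series           # per batch: prior mean of gamma
    tau2: pd.Series                # per batch: prior variance of gamma
    lam: pd.Series                 # per batch: inverse-gamma shape
    theta: pd.Series               # per batch: inverse-gamma scale
    n_iter: pd.Series              # per batch: EB iterations run
    constant_genes: list           # zero-pooled-variance genes passed through


def _inverse_gamma_moments(delta2: np.ndarray) -> tuple[float, float]:
    """Method-of-moments (shape, scale) of an inverse-gamma from sample
    mean/variance of the per-gene delta^2 estimates."""
    m = float(np.mean(delta2))
    s2 = float(np.var(delta2, ddof=1)) if delta2.size > 1 else 0.0
    if s2 <= 0:
        return np.inf, m
    lam = (2 * s2 + m**2) / s2
    theta = (m * s2 + m**3) / s2
    return lam, theta


def _eb_fit_batch(
    z: np.ndarray, tol: float, max_iter: int
) -> tuple[np.ndarray, np.ndarray, float, float, float, float, int]:
    """Iterated conditional EB estimates for one batch of standardized data.

    ``z`` is genes x samples. Returns (gamma*, delta2*, gamma_bar, tau2,
    lambda, theta, iterations).
    """
    n = z.shape[1]
    gamma_hat = z.mean(axis=1)
    delta2_hat = z.var(axis=1, ddof=1)
    gamma_bar = float(gamma_hat.mean())
    tau2 = float(gamma_hat.var(ddof=1)) if gamma_hat.size > 1 else 0.0
    lam, theta = _inverse_gamma_moments(delta2_hat)

    gamma_star = gamma_hat.copy()
    delta2_star = delta2_hat.copy()
    for it in range(1, max_iter + 1):
        prev = gamma_star.copy()
        if tau2 > 0:
            gamma_star = (n * tau2 * gamma_hat + delta2_star * gamma_bar) / (
                n * tau2 + delta2_star
            )
        else:
            gamma_star = np.full_like(gamma_hat, gamma_bar)
        ss = ((z - gamma_star[:, None]) ** 2).sum(axis=1)
        if np.isfinite(lam):
            delta2_star = (theta + 0.5 * ss) / (n / 2 + lam - 1)
        else:
            delta2_star = np.full_like(ss, theta)
        if np.max(np.abs(gamma_star - prev)) < tol:
            break
    return gamma_star, delta2_star, gamma_bar, tau2, lam, theta, it


def combat_adjust(
    matrix: ExpressionMatrix,
    batch: pd.Series | None = None,
    tol: float = 1e-4,
    max_iter: int = 100,
) -> tuple[ExpressionMatrix, BatchModel | None]:
    """Remove additive/multiplicative batch effects by parametric EB.

    A single batch is a no-op (warning, model ``None``). Genes with zero
    pooled variance pass through unchanged and are logged. Requires at least
    2 samples per batch.
    """
    if batch is None:
        batch = matrix.batch
    if batch is None:
        raise ValueError("no batch labels provided")
    batch = pd.Series(batch).reindex(matrix.values.columns)
    if batch.isna().any():
        raise ValueError("batch labels missing for some samples")
    levels = list(pd.unique(batch))
    if len(levels) < 2:
        warnings.warn("single batch: returning input unchanged", stacklevel=2)
        return matrix, None
    counts = batch.value_counts()
    small = counts.index[counts < 2].tolist()
    if small:
        raise ValueError(f"batches with <2 samples: {small}")

    x = matrix.values.to_numpy(dtype=float)
    genes = matrix.values.index
    n_total = x.shape[1]
    masks = {b: (batch == b).to_numpy() for b in levels}
    weights = {b: masks[b].sum() / n_total for b in levels}

    batch_means = np.column_stack([x[:, masks[b]].mean(axis=1) for b in levels])
    w = np.array([weights[b] for b in levels])
    grand = batch_means @ w
    col_of_sample = np.array([levels.index(b) for b in batch])
    resid = x - batch_means[:, col_of_sample]
    pooled_var = (resid**2).sum(axis=1) / n_total

    constant = pooled_var <= 0
    const_genes = genes[constant].tolist()
    if const_genes:
        logger.info("%d zero-variance genes passed through unchanged", len(const_genes))
    ok = ~constant
    sd = np.sqrt(pooled_var[ok])
    z = (x[ok] - grand[ok, None]) / sd[:, None]

    gamma_hat = np.column_stack([z[:, masks[b]].mean(axis=1) for b in levels])
    delta2_hat = np.column_stack([z[:, masks[b]].var(axis=1, ddof=1) for b in levels])

    gamma_star = np.empty_like(gamma_hat)
    delta2_star = np.empty_like(delta2_hat)
    gbar, tau2_, lam_, theta_, iters = {}, {}, {}, {}, {}
    adjusted = x.copy()
    for j, b in enumerate(levels):
        gs, ds, gb, t2, lm, th, it = _eb_fit_batch(z[:, masks[b]], tol, max_iter)
        gamma_star[:, j], delta2_star[:, j] = gs, ds
        gbar[b], tau2_[b], lam_[b], theta_[b], iters[b] = gb, t2, lm, th, it
        z_adj = (z[:, masks[b]] - gs[:, None]) / np.sqrt(ds)[:, None]
        block = z_adj * sd[:, None] + grand[ok, None]
        rows = np.where(ok)[0]
        adjusted[np.ix_(rows, np.where(masks[b])[0])] = block

    # centring convention: preserve each gene's pooled batch-weighted mean
    new_means = np.column_stack(
        [adjusted[ok][:, masks[b]].mean(axis=1) for b in levels]
    ) @ w
    adjusted[ok] += (grand[ok] - new_means)[:, None]

    gi = genes[ok]
    model = BatchModel(
        batches=levels,
        grand_mean=pd.Series(grand, index=genes),
        pooled_var=pd.Series(pooled_var, index=genes),
        gamma_hat=pd.DataFrame(gamma_hat, index=gi, columns=levels),
        delta2_hat=pd.DataFrame(delta2_hat, index=gi, columns=levels),
        gamma_star=pd.DataFrame(gamma_star, index=gi, columns=levels),
        delta2_star=pd.DataFrame(delta2_star, index=gi, columns=levels),
        gamma_bar=pd.Series(gbar),
        tau2=pd.Series(tau2_),
        lam=pd.Series(lam_),
        theta=pd.Series(theta_),
        n_iter=pd.Series(iters),
        constant_genes=const_genes,
    )
    out = ExpressionMatrix(
        pd.DataFrame(adjusted, index=genes, columns=matrix.values.columns),
        matrix.unit,
        batch,
    )
    return out, model


def batch_severity(matrix: ExpressionMatrix, batch: pd.Series | None = None) -> dict:
    """Quantify residual batch structure.

    Reports the mean per-gene one-way F statistic across batches and the
    silhouette of batch labels in the space of the top-2 principal
    components of the sample-by-gene matrix.
    """
    from sklearn.decomposition import PCA
    from sklearn.metrics import silhouette_score

    if batch is None:
        batch = matrix.batch
    if batch is None:
        raise ValueError("no batch labels provided")
    batch = pd.Series(batch).reindex(matrix.values.columns)
    levels = list(pd.unique(batch))
    if len(levels) < 2:
        raise ValueError("batch severity needs >= 2 batches")

    x = matrix.values.to_numpy(dtype=float)
    n = x.shape[1]
    masks = [(batch == b).to_numpy() for b in levels]
    ns = np.array([m.sum() for m in masks])
    means = np.column_stack([x[:, m].mean(axis=1) for m in masks])
    grand = x.mean(axis=1)
    ss_between = ((means - grand[:, None]) ** 2 * ns).sum(axis=1)
    ss_within = np.zeros(x.shape[0])
    for m, mu in zip(masks, means.T):
        ss_within += ((x[:, m] - mu[:, None]) ** 2).sum(axis=1)
    df_b, df_w = len(levels) - 1, n - len(levels)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / df_b) / (ss_within / df_w)
    f = f[np.isfinite(f)]

    pcs = PCA(n_components=2, svd_solver="full").fit_transform(x.T)
    sil = float(silhouette_score(pcs, batch.to_numpy()))
    return {
        "mean_f_statistic": float(f.mean()) if f.size else 0.0,
        "pc_silhouette": sil,
        "n_batches": len(levels),
        "n_samples": int(n),
    }
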