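"""Ridge-regression drug-sensitivity imputation from a reference panel,
plus gene-drug correlation mining.

The workflow mirrors the classical cell-line-to-tumor transfer approach:
the reference panel and the cohort are homogenized as two batches
(empirical-Bayes batch correction on the shared gene space), a ridge model
per drug is trained on gene-standardized reference expression with the
penalty chosen by k-fold cross-validated mean squared error over a grid,
and cohort log-IC50 values are imputed by the linear model. Group contrasts
of the predictions use the rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Ridge
from sklearn.model_selection import KFold

from .batchfx import combat_adjust
from .cohort_io import ExpressionMatrix
from .degstats import bh_adjust

DEFAULT_LAMBDA_GRID = tuple(float(v) for v in np.logspace(-2, 4, 13))


@dataclass
class DrugModel:
    coef: pd.Series          # per gene, on the standardized scale
    intercept: float
    lam: float
    cv_mse: pd.Series        # mean CV error per grid lambda


@dataclass
class RidgeModel:
    drugs: dict[str, DrugModel]
    gene_mean: pd.Series     # training standardization
    gene_sd: pd.Series
    genes: list[str]
    folds: int
    seed: int


def homogenize(
    reference: ExpressionMatrix,
    cohort: ExpressionMatrix,
    min_overlap: int = 100,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Batch-correct reference and cohort as two batches on their shared
    gene space. Returns the corrected (reference, cohort) pair."""
    shared = [g for g in reference.values.index if g in set(cohort.values.index)]
    if len(shared) == 0:
        raise ValueError("reference and cohort share no genes")
    if len(shared) < min_overlap:
        raise ValueError(
            f"gene overlap {len(shared)} below required minimum {min_overlap}"
        )
    ref_sub = reference.values.loc[shared]
    coh_sub = cohort.values.loc[shared]
    combined = pd.concat([ref_sub, coh_sub], axis=1)
    batch = pd.Series(
        ["reference"] * ref_sub.shape[1] + ["cohort"] * coh_sub.shape[1],
        index=combined.columns,
    )
    corrected, _ = combat_adjust(ExpressionMatrix(combined, reference.unit), batch)
    ref_c = ExpressionMatrix(corrected.values.iloc[:, : ref_sub.shape[1]], reference.unit)
    coh_c = ExpressionMatrix(corrected.values.iloc[:, ref_sub.shape[1]:], cohort.unit)
    return ref_c, coh_c


def train_ridge(
    reference: ExpressionMatrix,
    responses: pd.DataFrame,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    folds: int = 10,
    seed: int = 0,
) -> RidgeModel:
    """Per-drug ridge regression on gene-standardized reference expression.

    The penalty is the grid value minimizing k-fold CV mean squared error;
    ties go to the larger (more regularized) lambda.
    """
    grid = sorted(float(v) for v in lambda_grid)
    if not grid:
        raise ValueError("empty lambda grid")
    if responses.columns.has_duplicates:
        raise ValueError("duplicate drug names")
    common = [s for s in reference.values.columns if s in responses.index]
    n = len(common)
    if n < folds:
        raise ValueError(f"fewer samples ({n}) than folds ({folds})")
    if n < 30:
        raise ValueError(f"need >= 30 reference samples (got {n})")
    y_all = responses.loc[common]
    if y_all.isna().any().any():
        raise ValueError("missing drug responses")

    x_raw = reference.values[common].to_numpy(dtype=float).T  # samples x genes
    mean = x_raw.mean(axis=0)
    sd = x_raw.std(axis=0, ddof=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    x = (x_raw - mean) / sd_safe

    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(kf.split(x))
    drugs = {}
    for drug in responses.columns:
        y = y_all[drug].to_numpy(dtype=float)
        mse = {}
        for lam in grid:
            err = 0.0
            for tr, te in splits:
                model = Ridge(alpha=lam, fit_intercept=True)
                model.fit(x[tr], y[tr])
                err += float(((model.predict(x[te]) - y[te]) ** 2).sum())
            mse[lam] = err / n
        # ties -> larger lambda
        best = max(grid, key=lambda l: (-round(mse[l], 12), l))
        final = Ridge(alpha=best, fit_intercept=True)
        final.fit(x, y)
        drugs[drug] = DrugModel(
            coef=pd.Series(final.coef_, index=reference.values.index),
            intercept=float(final.intercept_),
            lam=best,
            cv_mse=pd.Series(mse),
        )
    return RidgeModel(
        drugs=drugs,
        gene_mean=pd.Series(mean, index=reference.values.index),
        gene_sd=pd.Series(sd_safe, index=reference.values.index),
        genes=list(reference.values.index),
        folds=folds,
        seed=seed,
    )


def predict_ic50(model: RidgeModel, cohort: ExpressionMatrix) -> pd.DataFrame:
    """Impute per-sample log-IC50 for every trained drug."""
    missing = [g for g in model.genes if g not in cohort.values.index]
    if missing:
        raise ValueError(f"cohort lacks model genes: {missing[:10]}")
    x = cohort.values.loc[model.genes].to_numpy(dtype=float).T
    z = (x - model.gene_mean.to_numpy()) / model.gene_sd.to_numpy()
    out = {}
    for drug, dm in model.drugs.items():
        out[drug] = z @ dm.coef.to_numpy() + dm.intercept
    return pd.DataFrame(out, index=cohort.values.columns)


def gene_drug_correlation(
    expression: ExpressionMatrix,
    responses: pd.DataFrame,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Pearson correlation of each selected gene against each drug's
    response, with BH-adjusted p-values across all pairs, sorted by |r|.
    Constant gene or drug vectors yield flagged NA rows."""
    gene_list = list(genes) if genes is not None else list(expression.values.index)
    common = [s for s in expression.values.columns if s in responses.index]
    if len(common) < 3:
        raise ValueError("need >= 3 shared samples")
    sub = expression.values.loc[gene_list, common]
    resp = responses.loc[common]
    rows = []
    for g in gene_list:
        gv = sub.loc[g].to_numpy(dtype=float)
        for drug in resp.columns:
            dv = resp[drug].to_numpy(dtype=float)
            if np.std(gv) == 0 or np.std(dv) == 0:
                rows.append((g, drug, np.nan, np.nan, True))
                continue
            r, p = stats.pearsonr(gv, dv)
            rows.append((g, drug, float(r), float(p), False))
    out = pd.DataFrame(rows, columns=["gene", "drug", "r", "p", "degenerate"])
    ok = ~out["degenerate"]
    fdr = np.full(len(out), np.nan)
    if ok.any():
        fdr[ok.to_numpy()] = bh_adjust(out.loc[ok, "p"].to_numpy())
    out["fdr"] = fdr
    return out.sort_values("r", key=lambda s: s.abs(), ascending=False).reset_index(drop=True)
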