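"""Cuproptosis score (CUS) construction.

The prognostic signature genes (CSRGs) are split by the sign of their
point-biserial correlation with a reference gene-cluster into sigC1
(positive) and sigC2 (negative). After optional Boruta all-relevant feature
selection against the gene-cluster label, each signature set is reduced to
its first principal-component score per sample, giving PsigC1 and PsigC2,
and the per-sample score is

    CUS = PsigC1 - PsigC2.

PC1 signs are mathematically arbitrary; each score is oriented to correlate
non-negatively with the mean scaled expression of its signature genes, so
CUS has a reproducible sign. Whether high CUS marks poor prognosis is then
an empirical finding asserted downstream, not an assumption.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import ExpressionMatrix


@dataclass
class SignatureSplit:
    sig_c1: list[str]               # positively associated with the reference cluster
    sig_c2: list[str]               # negatively associated
    association: pd.Series          # point-biserial r per gene
    reference_cluster: object = None
    excluded: list[str] = field(default_factory=list)  # zero-correlation genes


@dataclass
class BorutaReport:
    status: pd.Series               # confirmed / rejected / tentative per feature
    hits: pd.Series
    iterations: int
    importance_history: pd.DataFrame
    shadow_max_history: np.ndarray
    alpha: float
    seed: int

    @property
    def confirmed(self) -> list[str]:
        return self.status.index[self.status == "confirmed"].tolist()

    @property
    def rejected(self) -> list[str]:
        return self.status.index[self.status == "rejected"].tolist()

    @property
    def tentative(self) -> list[str]:
        return self.status.index[self.status == "tentative"].tolist()


@dataclass
class CUSResult:
    table: pd.DataFrame             # sample x [PsigC1, PsigC2, CUS, (group)]
    variance_explained: dict[str, float]
    cutoff: float | None = None

    @property
    def cus(self) -> pd.Series:
        return self.table["CUS"]


def split_signature(
    matrix: ExpressionMatrix,
    csrg_genes: list[str],
    cluster_labels: pd.Series,
    reference_cluster,
) -> SignatureSplit:
    """Split genes by the sign of their correlation with the reference
    cluster indicator. Zero-correlation genes are excluded with a warning
    entry; zero-variance genes are an error."""
    labels = pd.Series(cluster_labels).reindex(matrix.values.columns)
    levels = pd.unique(labels.dropna())
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 clusters, got {list(levels)}")
    if reference_cluster not in levels:
        raise ValueError(f"reference cluster {reference_cluster!r} not among {list(levels)}")
    indicator = (labels == reference_cluster).to_numpy(dtype=float)
    sub = matrix.subset_genes(csrg_genes).values
    sig_c1, sig_c2, excluded, assoc = [], [], [], {}
    for g in csrg_genes:
        expr = sub.loc[g].to_numpy(dtype=float)
        if np.std(expr) == 0:
            raise ValueError(f"gene {g!r} has zero variance")
        r = float(stats.pearsonr(expr, indicator)[0])
        assoc[g] = r
        if r > 0:
            sig_c1.append(g)
        elif r < 0:
            sig_c2.append(g)
        else:
            excluded.append(g)
    return SignatureSplit(
        sig_c1=sig_c1,
        sig_c2=sig_c2,
        association=pd.Series(assoc),
        reference_cluster=reference_cluster,
        excluded=excluded,
    )


def _default_importance(x: np.ndarray, y: np.ndarray, seed: int) -> np.ndarray:
    """Permutation-style random-forest importance.

    Accuracy drop when one column is permuted, evaluated with a single
    batched forest prediction over all column permutations. Better null
    calibration than impurity importances, which credit every in-sample
    split and let spuriously correlated noise beat the shadow bar.
    """
    from sklearn.ensemble import RandomForestClassifier

    # individual trees predict encoded class indices, so fit on the encoding
    _, y = np.unique(y, return_inverse=True)
    rf = RandomForestClassifier(
        n_estimators=50, max_depth=7, n_jobs=1, random_state=seed
    )
    rf.fit(x, y)
    n, p = x.shape
    rng = np.random.default_rng(seed)
    drops = np.zeros(p)
    n_eval = 0
    for tree, inbag in zip(rf.estimators_, rf.estimators_samples_):
        oob = np.setdiff1d(np.arange(n), inbag)
        if oob.size < 5:
            continue
        xo, yo = x[oob], y[oob]
        base = float(np.mean(tree.predict(xo) == yo))
        big = np.broadcast_to(xo, (p, oob.size, p)).copy()
        for j in range(p):
            big[j, :, j] = xo[rng.permutation(oob.size), j]
        preds = tree.predict(big.reshape(p * oob.size, p)).reshape(p, oob.size)
        drops += base - (preds == yo[None, :]).mean(axis=1)
        n_eval += 1
    return np.maximum(drops / max(n_eval, 1), 0.0)


def boruta_select(
    features: pd.DataFrame,
    target: pd.Series,
    importance_fn=None,
    alpha: float = 0.01,
    max_iter: int = 100,
    seed: int = 0,
    mc_adjust: bool = True,
) -> BorutaReport:
    """Boruta all-relevant feature selection with shadow features.

    Each iteration appends an independently shuffled shadow copy of every
    active feature, computes importances (default: random-forest impurity
    importance), and scores a "hit" for every undecided feature beating the
    maximum shadow importance. After each iteration a two-sided binomial
    test at level ``alpha`` (Bonferroni-adjusted across the features under
    test by default, following the canonical algorithm) confirms (more hits
    than chance) or rejects (fewer) features; rejected features leave the
    design. The loop stops when all features are decided or after
    ``max_iter`` iterations, leaving the rest tentative.
    """
    if max_iter < 10:
        raise ValueError("max_iter must be >= 10")
    x = features.to_numpy(dtype=float)
    y = pd.Series(target).reindex(features.index).to_numpy()
    if pd.isna(y).any():
        raise ValueError("target missing for some samples")
    if len(pd.unique(y)) < 2:
        raise ValueError("constant target")
    n, p = x.shape
    if n < 20:
        raise ValueError(f"need >= 20 samples (got {n})")
    if p < 2:
        raise ValueError("need >= 2 features")
    if importance_fn is None:
        importance_fn = _default_importance

    rng = np.random.default_rng(seed)
    names = list(features.columns)
    status = pd.Series("tentative", index=names)
    hits = pd.Series(0, index=names, dtype=int)
    history = []
    shadow_max = []
    it = 0
    for it in range(1, max_iter + 1):
        active = status != "rejected"
        cols = np.flatnonzero(active.to_numpy())
        xa = x[:, cols]
        shadow = xa.copy()
        for j in range(shadow.shape[1]):
            rng.shuffle(shadow[:, j])
        aug = np.hstack([xa, shadow])
        imp = np.asarray(importance_fn(aug, y, int(rng.integers(2**31 - 1))))
        if imp.shape[0] != 2 * cols.size or (imp < 0).any():
            raise ValueError("importance_fn must return one non-negative value per column")
        real = pd.Series(imp[: cols.size], index=[names[c] for c in cols])
        thresh = imp[cols.size:].max()
        shadow_max.append(thresh)
        history.append(real.reindex(names))
        undecided = status == "tentative"
        hits[undecided & (real.reindex(names) > thresh).fillna(False)] += 1
        # two-sided binomial decision at level alpha, Bonferroni-adjusted
        # across the features still under test (canonical default)
        level = alpha / 2
        if mc_adjust:
            level /= max(int(undecided.sum()), 1)
        lo = stats.binom.cdf(hits[undecided], it, 0.5)
        hi = stats.binom.sf(hits[undecided] - 1, it, 0.5)
        names_u = hits.index[undecided]
        status[names_u[hi < level]] = "confirmed"
        status[names_u[lo < level]] = "rejected"
        if not (status == "tentative").any():
            break
    return BorutaReport(
        status=status,
        hits=hits,
        iterations=it,
        importance_history=pd.DataFrame(history, columns=names),
        shadow_max_history=np.asarray(shadow_max),
        alpha=alpha,
        seed=seed,
    )


def pc_scores(
    matrix: ExpressionMatrix,
    genes: list[str] | None = None,
    n_components: int = 1,
) -> tuple[pd.Series, float]:
    """Per-sample principal-component score sum of a gene subset.

    Genes are centred and unit-scaled across samples before the SVD; each
    retained component's score is the sample projection on that right
    singular direction, oriented to correlate non-negatively with the mean
    scaled expression of the subset, and the returned score sums the first
    ``n_components`` of them (1 by default). Returns (scores, variance
    explained by the retained components). A single gene returns that
    gene's scaled values with full variance explained.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    sub = matrix.values if genes is None else matrix.subset_genes(genes).values
    if sub.shape[1] < 3:
        raise ValueError("need >= 3 samples")
    x = sub.to_numpy(dtype=float)
    sd = x.std(axis=1, ddof=0)
    if (sd == 0).any():
        bad = sub.index[sd == 0].tolist()
        raise ValueError(f"zero-variance genes in signature: {bad}")
    z = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    if z.shape[0] == 1:
        return pd.Series(z[0], index=sub.columns), 1.0
    # SVD of genes x samples: right singular vectors live in sample space
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    k = min(n_components, s.size)
    mean_expr = z.mean(axis=0)
    total = np.zeros(z.shape[1])
    for c in range(k):
        score = vt[c] * s[c]
        if np.dot(score - score.mean(), mean_expr) < 0:
            score = -score
        total += score
    var_explained = float((s[:k] ** 2).sum() / (s**2).sum())
    return pd.Series(total, index=sub.columns), var_explained


def pc1_scores(
    matrix: ExpressionMatrix, genes: list[str] | None = None
) -> tuple[pd.Series, float]:
    """First-principal-component score per sample (see :func:`pc_scores`)."""
    return pc_scores(matrix, genes, n_components=1)


def compute_cus(
    matrix: ExpressionMatrix,
    split: SignatureSplit,
    boruta: BorutaReport | None = None,
    keep_tentative: bool = True,
    n_components: int = 1,
) -> CUSResult:
    """Per-sample CUS = PsigC1 - PsigC2 from the two signature PC scores.

    With a Boruta report, each signature set is intersected with the
    confirmed (and, by default, tentative) features first; a set emptied by
    the filter is an error naming the set. ``n_components=2`` adds the PC2
    score to each signature term.
    """
    c1, c2 = list(split.sig_c1), list(split.sig_c2)
    if boruta is not None:
        keep = set(boruta.confirmed)
        if keep_tentative:
            keep |= set(boruta.tentative)
        c1 = [g for g in c1 if g in keep]
        c2 = [g for g in c2 if g in keep]
        if split.sig_c1 and not c1:
            raise ValueError("feature selection emptied sigC1")
        if split.sig_c2 and not c2:
            raise ValueError("feature selection emptied sigC2")
    if not c1 and not c2:
        raise ValueError("both signature sets are empty")

    samples = matrix.values.columns
    var = {}
    if c1:
        p1, var["sigC1"] = pc_scores(matrix, c1, n_components)
    else:
        p1 = pd.Series(0.0, index=samples)
    if c2:
        p2, var["sigC2"] = pc_scores(matrix, c2, n_components)
    else:
        p2 = pd.Series(0.0, index=samples)
    table = pd.DataFrame({"PsigC1": p1, "PsigC2": p2})
    table["CUS"] = table["PsigC1"] - table["PsigC2"]
    return CUSResult(table=table, variance_explained=var)


def assign_cus_groups(cus: pd.Series, cutoff: float) -> pd.Series:
    """High/low grouping at a cutoff; scores exactly at the cutoff go low."""
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    return pd.Series(np.where(cus > cutoff, "high", "low"), index=cus.index)
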