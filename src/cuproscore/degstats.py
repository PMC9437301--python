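"""Moderated two-group differential expression, DEG filtering,
over-representation analysis, generic group tests, BH adjustment and the
delta-delta-Ct fold change.

The moderated t borrows strength across genes by an empirical-Bayes
inverse-chi-square prior on the residual variances: the prior degrees of
freedom d0 and prior variance s0^2 are estimated by method-of-moments on
log s^2 (digamma/trigamma matching), each gene's posterior variance is
s~^2 = (d0 s0^2 + d s^2) / (d0 + d), and the t statistic uses d0 + d
degrees of freedom. With d0 = 0 this reduces to the ordinary pooled
two-sample t.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .cohort_io import ExpressionMatrix, GeneSetCollection


@dataclass
class ModeratedTPrior:
    d0: float
    s0_sq: float


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (monotone decreasing)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_variance_prior(s_sq: np.ndarray, df: float) -> ModeratedTPrior:
    """Method-of-moments fit of the (d0, s0^2) variance prior on log s^2."""
    s_sq = np.asarray(s_sq, dtype=float)
    ok = s_sq > 0
    if ok.sum() < 2:  # nothing to pool across: no moderation
        return ModeratedTPrior(d0=0.0, s0_sq=0.0)
    z = np.log(s_sq[ok])
    e_mean = float(np.mean(z)) - special.digamma(df / 2) + np.log(df / 2)
    e_var = float(np.var(z, ddof=1)) - float(special.polygamma(1, df / 2))
    if e_var <= 0:
        return ModeratedTPrior(d0=np.inf, s0_sq=float(np.exp(e_mean)))
    d0 = 2 * _trigamma_inverse(e_var)
    s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2) - np.log(d0 / 2)))
    return ModeratedTPrior(d0=d0, s0_sq=s0_sq)


def moderated_t_table(
    matrix: ExpressionMatrix,
    labels: pd.Series,
    group_order: tuple | None = None,
    d0_override: float | None = None,
) -> pd.DataFrame:
    """Per-gene moderated t test between two sample groups.

    logFC is mean(second group) - mean(first group); ``group_order`` fixes
    which group is second (default: sorted label order). ``d0_override=0``
    switches shrinkage off (ordinary pooled t). Returns a DataFrame indexed
    by gene with columns logFC, t, p, p_adj, mean_A, mean_B.
    """
    labels = pd.Series(labels).reindex(matrix.values.columns)
    if labels.isna().any():
        raise ValueError("labels missing for some samples")
    levels = sorted(pd.unique(labels)) if group_order is None else list(group_order)
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {levels}")
    a_mask = (labels == levels[0]).to_numpy()
    b_mask = (labels == levels[1]).to_numpy()
    n_a, n_b = int(a_mask.sum()), int(b_mask.sum())
    if min(n_a, n_b) < 2:
        raise ValueError("each group needs >= 2 samples")

    x = matrix.values.to_numpy(dtype=float)
    mean_a = x[:, a_mask].mean(axis=1)
    mean_b = x[:, b_mask].mean(axis=1)
    logfc = mean_b - mean_a
    df = n_a + n_b - 2
    ss = ((x[:, a_mask] - mean_a[:, None]) ** 2).sum(axis=1) + (
        (x[:, b_mask] - mean_b[:, None]) ** 2
    ).sum(axis=1)
    s_sq = ss / df

    if d0_override is not None:
        prior = ModeratedTPrior(d0=float(d0_override), s0_sq=0.0)
        if d0_override > 0:
            prior = ModeratedTPrior(
                d0=float(d0_override), s0_sq=estimate_variance_prior(s_sq, df).s0_sq
            )
    else:
        prior = estimate_variance_prior(s_sq, df)

    if np.isinf(prior.d0):
        s_tilde_sq = np.full_like(s_sq, prior.s0_sq)
        df_total = np.inf
    else:
        s_tilde_sq = (prior.d0 * prior.s0_sq + df * s_sq) / (prior.d0 + df)
        df_total = prior.d0 + df
    se = np.sqrt(s_tilde_sq * (1 / n_a + 1 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, logfc / se, np.sign(logfc) * np.inf)
    t = np.where((se == 0) & (logfc == 0), 0.0, t)
    if np.isinf(df_total):
        p = 2 * stats.norm.sf(np.abs(t))
    else:
        p = 2 * stats.t.sf(np.abs(t), df_total)
    p = np.where((se == 0) & (logfc == 0), 1.0, p)
    p_adj = bh_adjust(p)
    out = pd.DataFrame(
        {
            "logFC": logfc,
            "t": t,
            "p": p,
            "p_adj": p_adj,
            "mean_A": mean_a,
            "mean_B": mean_b,
        },
        index=matrix.values.index,
    )
    out.attrs["prior"] = prior
    out.attrs["groups"] = tuple(levels)
    return out


def filter_degs(
    records: pd.DataFrame,
    lfc_thresh: float = 1.0,
    p_thresh: float = 0.05,
    use_adjusted: bool = False,
) -> list[str]:
    """Differentially expressed genes: |logFC| > lfc_thresh AND p < p_thresh
    (strict inequalities), ordered by ascending p."""
    if lfc_thresh <= 0:
        raise ValueError("lfc_thresh must be > 0")
    if not 0 < p_thresh < 1:
        raise ValueError("p_thresh must be in (0, 1)")
    if len(records) == 0:
        return []
    pcol = "p_adj" if use_adjusted else "p"
    hit = records[(records["logFC"].abs() > lfc_thresh) & (records[pcol] < p_thresh)]
    return hit.sort_values(pcol).index.tolist()


def ora_enrich(
    genes: list[str],
    universe: list[str],
    sets: GeneSetCollection,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Over-representation analysis: hypergeometric upper tail per set,
    BH-adjusted across sets, sorted by adjusted p."""
    uni = set(universe)
    stray = [g for g in genes if g not in uni]
    if stray:
        raise ValueError(f"genes not in universe: {stray}")
    glist = set(genes)
    n_uni, n_list = len(uni), len(glist)
    rows = []
    for name, members in sets.items():
        in_uni = uni & set(members)
        k = len(glist & in_uni)
        big_k = len(in_uni)
        # P(X >= k), X ~ Hypergeometric(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, n_uni, big_k, n_list))
        rows.append((name, k, big_k, n_list, n_uni, p))
    out = pd.DataFrame(
        rows, columns=["geneset", "overlap", "set_size", "list_size", "universe_size", "p"]
    ).set_index("geneset")
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["p_adj"] < alpha
    return out.sort_values("p_adj")


def rank_sum_test(x, y) -> tuple[float, float]:
    """Mann-Whitney/Wilcoxon rank-sum test (two-sided).

    Exact enumeration when nx + ny <= 12 and there are no ties; otherwise
    the normal approximation with tie and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    combined = np.concatenate([x, y])
    no_ties = np.unique(combined).size == combined.size
    method = "exact" if (x.size + y.size <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis_test(groups: list) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction; p from chi-square (g-1 df)."""
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty group")
    allv = np.concatenate(arrays)
    if np.unique(allv).size == 1:
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ddct_fold_change(
    ct_target_case: float,
    ct_ref_case: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative expression by the 2^-ddCt method."""
    vals = [ct_target_case, ct_ref_case, ct_target_ctrl, ct_ref_ctrl]
    if not np.all(np.isfinite(vals)):
        raise ValueError("Ct values must be finite")
    ddct = (ct_target_case - ct_ref_case) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-ddct))
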