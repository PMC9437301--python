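"""Survival analysis: univariate Cox screening, Kaplan-Meier curves,
log-rank tests, optimal cutpoint selection, and contingency testing.

The Cox fit maximizes the partial likelihood by Newton-Raphson with Efron
handling of tied event times (Breslow available as a switch). Monotone
partial likelihoods (perfect separation) are not an error: |beta| is capped
at 15 and the result flagged, so genome-wide screens always complete.

The optimal cutpoint is the maximally selected log-rank statistic over all
feasible score splits (both groups at least ceil(minprop * n) samples). The
selection makes the associated log-rank p-value anti-conservative, so it is
reported as descriptive only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

BETA_CAP = 15.0


@dataclass
class CoxResult:
    name: str
    beta: float
    hr: float
    ci_low: float
    ci_high: float
    se: float
    z: float
    p: float
    n: int
    events: int
    converged: bool
    monotone: bool = False


@dataclass
class KMCurve:
    times: np.ndarray       # distinct event times
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray    # S(t) just after each event time
    variance: np.ndarray    # Greenwood variance of S(t)


@dataclass
class CutpointResult:
    cutoff: float
    statistic: float        # standardized log-rank |z| at the cutoff
    candidates: np.ndarray = field(default_factory=lambda: np.array([]))
    statistics: np.ndarray = field(default_factory=lambda: np.array([]))
    minprop: float = 0.1


def _event_blocks(time: np.ndarray, event: np.ndarray, x: np.ndarray):
    """Group samples by distinct event time; return per-block risk/death info."""
    order = np.argsort(time, kind="stable")
    return time[order], event[order].astype(float), x[order]


def _cox_derivs(beta: float, t: np.ndarray, e: np.ndarray, x: np.ndarray, ties: str):
    """Log partial likelihood and its first two derivatives (scalar covariate).

    Inputs must be sorted by ascending time.
    """
    n = t.size
    eta = np.clip(beta * x, -500, 500)
    w = np.exp(eta)
    # suffix sums: risk set at time t_i = samples with time >= t_i
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum((w * x)[::-1])[::-1]
    s2 = np.cumsum((w * x * x)[::-1])[::-1]

    ut, start = np.unique(t, return_index=True)
    ll = grad = hess = 0.0
    for b, st in enumerate(start):
        end = start[b + 1] if b + 1 < start.size else n
        ev = np.nonzero(e[st:end])[0] + st
        d = ev.size
        if d == 0:
            continue
        r0, r1, r2 = s0[st], s1[st], s2[st]
        dw, dx = w[ev], x[ev]
        ll += float((beta * dx).sum())
        grad += float(dx.sum())
        if ties == "efron" and d > 1:
            d0, d1_, d2 = dw.sum(), (dw * dx).sum(), (dw * dx * dx).sum()
            frac = np.arange(d) / d
            phi0 = r0 - frac * d0
            phi1 = r1 - frac * d1_
            phi2 = r2 - frac * d2
        else:
            phi0 = np.full(d, r0)
            phi1 = np.full(d, r1)
            phi2 = np.full(d, r2)
        ll -= float(np.log(phi0).sum())
        grad -= float((phi1 / phi0).sum())
        hess -= float((phi2 / phi0 - (phi1 / phi0) ** 2).sum())
    return ll, grad, hess


def cox_log_partial_likelihood(
    beta: float, time, event, covariate, ties: str = "efron"
) -> float:
    """Evaluate the (Efron or Breslow) log partial likelihood at beta."""
    t, e, x = _event_blocks(
        np.asarray(time, float), np.asarray(event, int), np.asarray(covariate, float)
    )
    return _cox_derivs(beta, t, e, x, ties)[0]


def cox_fit_univariate(
    time,
    event,
    covariate,
    name: str = "covariate",
    ties: str = "efron",
    tol: float = 1e-8,
    max_iter: int = 50,
) -> CoxResult:
    """Newton-Raphson univariate Cox fit with Wald CI and p-value."""
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown tie handling {ties!r}")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    x = np.asarray(covariate, dtype=float)
    n = time.size
    n_events = int(event.sum())
    if n < 8:
        raise ValueError(f"need n >= 8 (got {n})")
    if n_events < 3:
        raise ValueError(f"need >= 3 events (got {n_events})")
    if np.std(x) == 0:
        raise ValueError(f"constant covariate {name!r}")

    t, e, xs = _event_blocks(time, event, x)
    beta, converged, monotone = 0.0, False, False
    for _ in range(max_iter):
        ll, grad, hess = _cox_derivs(beta, t, e, xs, ties)
        if hess >= -1e-12:
            monotone = True
            break
        step = -grad / hess
        step = float(np.clip(step, -2.0, 2.0))  # damp early overshoot
        beta += step
        if abs(beta) > BETA_CAP:
            beta = float(np.sign(beta) * BETA_CAP)
            monotone = True
            break
        if abs(step) < tol:
            converged = True
            break
    _, _, hess = _cox_derivs(beta, t, e, xs, ties)
    se = float(np.sqrt(-1.0 / hess)) if hess < 0 else np.inf
    z = beta / se if np.isfinite(se) and se > 0 else 0.0
    p = float(2 * stats.norm.sf(abs(z)))
    zcrit = stats.norm.ppf(0.975)
    return CoxResult(
        name=name,
        beta=float(beta),
        hr=float(np.exp(beta)),
        ci_low=float(np.exp(beta - zcrit * se)),
        ci_high=float(np.exp(beta + zcrit * se)),
        se=se,
        z=float(z),
        p=p,
        n=n,
        events=n_events,
        converged=converged,
        monotone=monotone,
    )


SCREEN_RULES = ("csrg", "potential_cpg")


def screen_prognostic(matrix, clinical, rule: str = "csrg", genes=None, ties: str = "efron"):
    """Per-gene univariate Cox screen of expression against overall survival.

    rule ``csrg`` keeps genes with p < 0.05; rule ``potential_cpg`` keeps
    protective genes with p < 0.001 and (1 - HR) > 0.4 (i.e. HR < 0.6).
    Returns (kept gene list, full Cox table).
    """
    if rule not in SCREEN_RULES:
        raise ValueError(f"unknown rule {rule!r}; expected one of {SCREEN_RULES}")
    gene_list = list(genes) if genes is not None else list(matrix.values.index)
    common = [s for s in matrix.values.columns if s in clinical.data.index]
    time = clinical.data.loc[common, "time"].to_numpy(dtype=float)
    event = clinical.data.loc[common, "event"].to_numpy(dtype=int)
    sub = matrix.values.loc[gene_list, common]
    rows = []
    for g in gene_list:
        res = cox_fit_univariate(time, event, sub.loc[g].to_numpy(), name=g, ties=ties)
        rows.append((g, res.beta, res.hr, res.ci_low, res.ci_high, res.p, res.monotone))
    table = pd.DataFrame(
        rows, columns=["gene", "beta", "HR", "ci_low", "ci_high", "p", "monotone"]
    ).set_index("gene")
    if rule == "csrg":
        kept = table.index[table["p"] < 0.05].tolist()
    else:
        kept = table.index[(table["p"] < 0.001) & ((1 - table["HR"]) > 0.4)].tolist()
    return kept, table


def km_curve(time, event) -> KMCurve:
    """Product-limit survival estimate with Greenwood variance."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if (time < 0).any():
        raise ValueError("negative survival time")
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    n = t.size
    ut, start = np.unique(t, return_index=True)
    at_risk = n - start
    d = np.add.reduceat(e.astype(float), start)
    has_event = d > 0
    ut, at_risk, d = ut[has_event], at_risk[has_event], d[has_event]
    frac = 1.0 - d / at_risk
    surv = np.cumprod(frac)
    with np.errstate(divide="ignore", invalid="ignore"):
        green = np.cumsum(np.where(at_risk > d, d / (at_risk * (at_risk - d)), 0.0))
    var = surv**2 * green
    return KMCurve(times=ut, at_risk=at_risk, events=d, survival=surv, variance=var)


def _logrank_two(time, event, in_group) -> tuple[float, float]:
    """(O - E, V) for group 1 in a two-group log-rank test (vectorized)."""
    order = np.argsort(time, kind="stable")
    t = time[order]
    e = event[order].astype(float)
    g = in_group[order].astype(float)
    n = t.size
    ut, start = np.unique(t, return_index=True)
    n_at_risk = (n - start).astype(float)
    n1_suffix = np.cumsum(g[::-1])[::-1]
    n1 = n1_suffix[start]
    d = np.add.reduceat(e, start)
    d1 = np.add.reduceat(e * g, start)
    mask = d > 0
    N, n1_, dd, dd1 = n_at_risk[mask], n1[mask], d[mask], d1[mask]
    exp1 = dd * n1_ / N
    denom = np.maximum(N - 1, 1.0)
    var = dd * (n1_ / N) * (1 - n1_ / N) * (N - dd) / denom
    return float((dd1 - exp1).sum()), float(var.sum())


def logrank_test(time, event, groups) -> tuple[float, int, float]:
    """Multi-group log-rank test: observed-minus-expected with
    hypergeometric variance at each distinct event time.

    Returns (chi-square, df, p).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    g = len(levels)
    if g < 2:
        raise ValueError("need >= 2 groups")
    for lev in levels:
        if (groups == lev).sum() == 0:
            raise ValueError(f"group {lev!r} has no subjects")
    if g == 2:
        ome, v = _logrank_two(time, event, groups == levels[0])
        chi2 = ome**2 / v if v > 0 else 0.0
        return float(chi2), 1, float(stats.chi2.sf(chi2, 1))

    order = np.argsort(time, kind="stable")
    t, e, grp = time[order], event[order], groups[order]
    member = np.column_stack([(grp == lev) for lev in levels]).astype(float)
    n = t.size
    ut, start = np.unique(t, return_index=True)
    ome = np.zeros(g)
    cov = np.zeros((g, g))
    n_at = np.cumsum(member[::-1], axis=0)[::-1]  # suffix counts per group
    d_tot = np.add.reduceat(e.astype(float), start)
    d_grp = np.add.reduceat(e[:, None] * member, start, axis=0)
    for b, st in enumerate(start):
        d = d_tot[b]
        if d == 0:
            continue
        nj = n_at[st]
        N = n - st
        ome += d_grp[b] - d * nj / N
        if N > 1:
            c = d * (N - d) / (N - 1) * (np.diag(nj) * N - np.outer(nj, nj)) / N**2
            cov += c
    sub = slice(0, g - 1)
    chi2 = float(ome[sub] @ np.linalg.solve(cov[sub, sub], ome[sub]))
    df = g - 1
    return chi2, df, float(stats.chi2.sf(chi2, df))


def logrank_z(time, event, in_group) -> float:
    """Standardized two-group log-rank statistic (O - E)/sqrt(V)."""
    ome, v = _logrank_two(
        np.asarray(time, float), np.asarray(event, int), np.asarray(in_group, bool)
    )
    return ome / np.sqrt(v) if v > 0 else 0.0


def optimal_cutpoint(score, time, event, minprop: float = 0.1) -> CutpointResult:
    """Maximally selected log-rank cutpoint.

    Scans the midpoints between consecutive sorted unique score values whose
    split leaves both groups with at least ceil(minprop * n) samples and
    returns the cutoff maximizing |standardized log-rank statistic|; ties go
    to the lower cutoff. The implied p-value is descriptive only (selection
    inflates the statistic).
    """
    score = np.asarray(score, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n = score.size
    uniq = np.unique(score)
    if uniq.size < 2:
        raise ValueError("constant score: no feasible split")
    min_n = max(int(np.ceil(minprop * n)), 1)
    mids = (uniq[:-1] + uniq[1:]) / 2
    feasible, zs = [], []
    for c in mids:
        high = score > c
        nh = int(high.sum())
        if nh < min_n or n - nh < min_n:
            continue
        feasible.append(c)
        zs.append(abs(logrank_z(time, event, high)))
    if not feasible:
        raise ValueError("no split satisfies the minprop constraint")
    feasible = np.asarray(feasible)
    zs = np.asarray(zs)
    best = int(np.argmax(zs))  # argmax returns the first (lowest cutoff) on ties
    return CutpointResult(
        cutoff=float(feasible[best]),
        statistic=float(zs[best]),
        candidates=feasible,
        statistics=zs,
        minprop=minprop,
    )


def chi_square_2xk(table, yates: bool = False) -> tuple[float, int, float]:
    """Pearson chi-square on a contingency table (no continuity correction
    by default; ``yates=True`` applies Yates for 2x2)."""
    tab = np.asarray(table, dtype=float)
    if (tab < 0).any():
        raise ValueError("counts must be non-negative")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise ValueError("table has an all-zero row or column")
    chi2, p, df, _ = stats.chi2_contingency(tab, correction=yates)
    return float(chi2), int(df), float(p)
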