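"""Resampled (Monti-style) consensus clustering with a PAM inner clusterer.

Used twice in the pipeline: first on the CPG program genes to derive the
molecular subtypes, then on the prognostic signature genes (CSRGs) for the
secondary gene-cluster typing. Defaults follow the standard protocol:
50 repetitions, 80% sample subsampling without replacement, per-subsample
gene z-scoring, Euclidean distances, PAM (BUILD + SWAP k-medoids) per
repetition, and an average-linkage cut of the consensus dissimilarity for
the final call. k is selected by minimum PAC (proportion of ambiguous
clustering: consensus entries in (0.1, 0.9)), with a fixed-k override.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .cohort_io import ExpressionMatrix


@dataclass
class PAMResult:
    assignment: np.ndarray   # cluster index 0..k-1 per point
    medoids: np.ndarray      # indices of the k medoids
    cost: float              # total distance to nearest medoid


@dataclass
class ConsensusResult:
    """Per-k consensus matrices and summaries plus the chosen k."""

    samples: list[str]
    consensus: dict[int, np.ndarray] = field(default_factory=dict)
    assignments: dict[int, pd.Series] = field(default_factory=dict)
    pac: dict[int, float] = field(default_factory=dict)
    cdf: dict[int, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    delta_area: dict[int, float] = field(default_factory=dict)
    chosen_k: int | None = None
    seed: int | None = None
    reps: int = 50
    subsample: float = 0.8
    never_cosampled: int = 0


def _as_distance(data: np.ndarray, metric_is_distance: bool) -> np.ndarray:
    if metric_is_distance:
        d = np.asarray(data, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("distance matrix must be square")
        if np.isnan(d).any():
            raise ValueError("NaN in distance matrix")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0):
            raise ValueError("distance matrix must have zero diagonal")
    else:
        x = np.asarray(data, dtype=float)
        sq = (x**2).sum(axis=1)
        d = np.sqrt(np.maximum(sq[:, None] + sq[None, :] - 2 * x @ x.T, 0.0))
        np.fill_diagonal(d, 0.0)
    if np.isnan(d).any():
        raise ValueError("NaN in distance matrix")
    return d


def pam_cluster(
    data: np.ndarray,
    k: int,
    seed: int | None = None,
    precomputed: bool = False,
    max_iter: int = 100,
) -> PAMResult:
    """k-medoids by BUILD then SWAP until no cost-reducing swap exists.

    ``data`` is either an n-by-p point matrix (Euclidean distances) or, with
    ``precomputed=True``, an n-by-n distance matrix. Deterministic given the
    input order; ``seed`` is accepted for interface symmetry only.
    """
    d = _as_distance(data, precomputed)
    n = d.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range for n={n}")

    # BUILD: greedy medoid initialisation
    medoids = [int(np.argmin(d.sum(axis=0)))]
    dnear = d[medoids[0]].copy()
    while len(medoids) < k:
        gain = np.minimum(d, dnear[None, :]).sum(axis=1)
        gain[medoids] = np.inf
        best = int(np.argmin(gain))
        medoids.append(best)
        dnear = np.minimum(dnear, d[best])

    medoids = np.array(sorted(medoids))
    for _ in range(max_iter):
        dm = d[medoids]                         # k x n
        order = np.argsort(dm, axis=0)
        nearest = order[0]                      # index into medoid list per point
        dnear = dm[nearest, np.arange(n)]
        dsec = dm[order[1], np.arange(n)] if k > 1 else np.full(n, np.inf)

        best_delta, best_swap = -1e-12, None
        for j in range(k):
            owned = nearest == j
            # cost change of replacing medoid j by each candidate h (vectorized over h)
            loss = np.where(owned, np.minimum(d, dsec[None, :]) - dnear[None, :], 0.0).sum(axis=1)
            gain = np.where(~owned, np.minimum(d - dnear[None, :], 0.0), 0.0).sum(axis=1)
            delta = loss + gain                 # per candidate h
            delta[medoids] = np.inf
            h = int(np.argmin(delta))
            if delta[h] < best_delta:
                best_delta, best_swap = delta[h], (j, h)
        if best_swap is None:
            break
        j, h = best_swap
        medoids[j] = h
        medoids = np.sort(medoids)

    dm = d[medoids]
    assignment = np.argmin(dm, axis=0)
    cost = float(dm[assignment, np.arange(n)].sum())
    return PAMResult(assignment=assignment, medoids=medoids, cost=cost)


def consensus_cluster(
    matrix: ExpressionMatrix,
    genes: list[str] | None = None,
    kmax: int = 5,
    reps: int = 50,
    subsample: float = 0.8,
    seed: int = 0,
    scale_genes: bool = True,
) -> ConsensusResult:
    """Consensus clustering of samples on a restricted gene list.

    Per repetition, ceil(subsample*n) samples are drawn without replacement,
    genes are z-scored on the subsample (optional), and PAM with Euclidean
    distance is run for each k in 2..kmax. consensus(i, j) = co-cluster
    count / co-sampled count; pairs never co-sampled get 0 (warned if >1%
    of pairs). The final assignment at each k is an average-linkage cut of
    1 - consensus.
    """
    if not 0 < subsample <= 1:
        raise ValueError("subsample must be in (0, 1]")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    sub = matrix.values if genes is None else matrix.subset_genes(genes).values
    if sub.shape[0] < 2:
        raise ValueError("need >= 2 genes for clustering")
    n = sub.shape[1]
    if n < max(10, kmax):
        raise ValueError(f"need >= {max(10, kmax)} samples (got {n})")

    rng = np.random.default_rng(seed)
    x_full = sub.to_numpy(dtype=float).T  # samples x genes
    m = int(np.ceil(subsample * n))

    ks = range(2, kmax + 1)
    co_cluster = {k: np.zeros((n, n)) for k in ks}
    co_sampled = np.zeros((n, n))

    for _ in range(reps):
        idx = np.sort(rng.choice(n, size=m, replace=False))
        x = x_full[idx]
        if scale_genes:
            sd = x.std(axis=0, ddof=0)
            sd[sd == 0] = 1.0
            x = (x - x.mean(axis=0)) / sd
        d = _as_distance(x, False)
        co_sampled[np.ix_(idx, idx)] += 1
        for k in ks:
            res = pam_cluster(d, k, precomputed=True)
            onehot = np.eye(k)[res.assignment]
            co_cluster[k][np.ix_(idx, idx)] += onehot @ onehot.T

    never = co_sampled == 0
    np.fill_diagonal(never, False)
    n_never = int(never.sum() // 2)
    if n_never > 0.01 * n * (n - 1) / 2:
        warnings.warn(
            f"{n_never} sample pairs never co-sampled; consensus set to 0 for them",
            stacklevel=2,
        )

    result = ConsensusResult(
        samples=list(sub.columns), seed=seed, reps=reps, subsample=subsample,
        never_cosampled=n_never,
    )
    iu = np.triu_indices(n, k=1)
    prev_auc = None
    for k in ks:
        with np.errstate(divide="ignore", invalid="ignore"):
            cons = np.where(co_sampled > 0, co_cluster[k] / co_sampled, 0.0)
        cons = (cons + cons.T) / 2
        np.fill_diagonal(cons, 1.0)
        result.consensus[k] = cons

        vals = np.sort(cons[iu])
        grid = np.linspace(0, 1, 101)
        cdf = np.searchsorted(vals, grid, side="right") / vals.size
        result.cdf[k] = (grid, cdf)
        auc = float(np.trapezoid(cdf, grid))
        result.delta_area[k] = auc if prev_auc is None else (auc - prev_auc) / prev_auc
        prev_auc = auc
        result.pac[k] = float(np.mean((vals > 0.1) & (vals < 0.9)))

        link = linkage(squareform(1.0 - cons, checks=False), method="average")
        labels = fcluster(link, t=k, criterion="maxclust")
        if len(np.unique(labels)) != k:
            # fall back to a height cut that yields exactly k groups
            heights = np.sort(link[:, 2])
            for h in heights[::-1]:
                labels = fcluster(link, t=h - 1e-12, criterion="distance")
                if len(np.unique(labels)) >= k:
                    break
        result.assignments[k] = pd.Series(labels, index=result.samples)
    result.chosen_k = choose_k(result)
    return result


def choose_k(result: ConsensusResult, policy: str = "min-PAC", fixed_k: int | None = None) -> int:
    """Select k: ``min-PAC`` (default, ties to the smallest k) or ``fixed``."""
    if not result.pac:
        raise ValueError("empty consensus result")
    if policy == "fixed":
        if fixed_k is None:
            raise ValueError("policy 'fixed' requires fixed_k")
        return fixed_k
    if policy != "min-PAC":
        raise ValueError(f"unknown policy {policy!r}")
    best = min(sorted(result.pac), key=lambda k: (result.pac[k], k))
    return best
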