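"""Single-sample gene-set enrichment (ssGSEA), stromal/immune composite
scores and score-to-score correlation.

The ssGSEA statistic is the integrated running-sum of Barbie et al.: per
sample, genes are ranked by expression (descending; ties broken by
ascending gene id so output is platform-independent), in-set steps are
weighted by rank^alpha and out-of-set steps uniformly, and the enrichment
score is the sum over the ranked list of the difference between the
cumulative in-set weight fraction and the cumulative out-of-set fraction.
Being rank-based, the score is invariant under strictly monotone transforms
of a sample's expression vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import ExpressionMatrix, GeneSetCollection


@dataclass
class EnrichmentScores:
    scores: pd.DataFrame  # samples x gene sets
    normalized: bool
    alpha: float


@dataclass
class EstimateScores:
    """StromalScore + ImmuneScore = ESTIMATEScore, exactly."""

    table: pd.DataFrame  # samples x [StromalScore, ImmuneScore, ESTIMATEScore]


def _check_sets(matrix: ExpressionMatrix, sets: GeneSetCollection) -> dict[str, np.ndarray]:
    if len(sets) == 0:
        raise ValueError("empty gene set collection")
    genes = pd.Index(matrix.values.index)
    members: dict[str, np.ndarray] = {}
    missing = []
    for name, gs in sets.items():
        mask = np.asarray(genes.isin(gs))
        if not mask.any():
            missing.append(name)
        members[name] = mask
    if missing:
        raise ValueError(f"gene sets with no overlap with the matrix: {missing}")
    return members


def ssgsea_scores(
    matrix: ExpressionMatrix,
    sets: GeneSetCollection,
    alpha: float = 0.25,
    normalize: bool = True,
) -> EnrichmentScores:
    """ssGSEA enrichment score per sample per gene set.

    With ``normalize=True`` all scores are rescaled by the global
    (max - min) over the entire score matrix.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    members = _check_sets(matrix, sets)
    genes = matrix.values.index.to_numpy()
    x = matrix.values.to_numpy(dtype=float)
    n_genes, n_samples = x.shape

    # order genes descending by expression; ties broken by ascending gene id
    tie = np.argsort(genes)  # lexicographic gene order
    es = np.zeros((n_samples, len(members)))
    set_names = list(members)
    masks = np.column_stack([members[name] for name in set_names])  # genes x sets

    rank_stat = (np.arange(n_genes, 0, -1)).astype(float) ** alpha
    for j in range(n_samples):
        col = x[:, j]
        # stable sort on (-expression) over id-sorted genes => desired tie-break
        order = tie[np.argsort(-col[tie], kind="stable")]
        in_set = masks[order]                               # n_genes x sets
        w = rank_stat[:, None] * in_set
        denom_in = w.sum(axis=0)
        cum_in = np.cumsum(w, axis=0) / denom_in
        n_out = n_genes - in_set.sum(axis=0)
        cum_out = np.cumsum(~in_set, axis=0) / n_out
        es[j] = (cum_in - cum_out).sum(axis=0)

    if normalize:
        rng_ = es.max() - es.min()
        if rng_ > 0:
            es = es / rng_
    scores = pd.DataFrame(es, index=matrix.values.columns, columns=set_names)
    return EnrichmentScores(scores=scores, normalized=normalize, alpha=alpha)


def estimate_scores(
    matrix: ExpressionMatrix,
    stromal_set: list[str],
    immune_set: list[str],
    alpha: float = 0.25,
) -> EstimateScores:
    """Stromal and immune composite scores (unnormalized ssGSEA ES) and
    their sum (the ESTIMATE composite, inversely tracking tumor purity)."""
    sets = GeneSetCollection({"StromalScore": list(stromal_set), "ImmuneScore": list(immune_set)})
    es = ssgsea_scores(matrix, sets, alpha=alpha, normalize=False).scores
    table = es[["StromalScore", "ImmuneScore"]].copy()
    table["ESTIMATEScore"] = table["StromalScore"] + table["ImmuneScore"]
    return EstimateScores(table=table)


def correlate_scores(
    x: pd.Series,
    scores: EnrichmentScores,
    method: str = "pearson",
) -> pd.DataFrame:
    """Correlate a per-sample score against every gene set's ES.

    Returns a table (geneset, r, p, significant) with two-sided p from the
    t-distribution on n-2 df. Zero-variance inputs yield NA rows with a
    flag rather than an exception.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    common = scores.scores.index.intersection(x.index)
    if len(common) < 3:
        raise ValueError("need >= 3 shared samples")
    xv = x.loc[common].to_numpy(dtype=float)
    rows = []
    degenerate_x = np.std(xv) == 0
    for name in scores.scores.columns:
        yv = scores.scores.loc[common, name].to_numpy(dtype=float)
        if degenerate_x or np.std(yv) == 0:
            rows.append((name, np.nan, np.nan, False, True))
            continue
        if method == "pearson":
            r, p = stats.pearsonr(xv, yv)
        else:
            r, p = stats.spearmanr(xv, yv)
        rows.append((name, float(r), float(p), bool(p < 0.05), False))
    return pd.DataFrame(
        rows, columns=["geneset", "r", "p", "significant", "degenerate"]
    ).set_index("geneset")
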