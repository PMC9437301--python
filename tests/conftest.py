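"""Shared fixtures.

Heavy simulation studies (the 10-seed end-to-end recovery run and the null
calibration experiments) are session-scoped so that unit tests and the
end-to-end acceptance checks share one computation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from cuproscore import batchfx, consensus, cuscore, degstats, drugresp, survstats
from cuproscore.cohort_io import ExpressionMatrix
from cuproscore.pipeline import _order_clusters_by_prognosis
from cuproscore.syncohort import SimConfig, simulate_cohort, simulate_reference_panel


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition cohort (n=400, seed 7) with ground truth."""
    config = SimConfig(seed=7)
    matrix, clinical, truth = simulate_cohort(config)
    corrected, _ = batchfx.combat_adjust(matrix)
    return {
        "config": config,
        "raw": matrix,
        "matrix": corrected,
        "clinical": clinical,
        "truth": truth,
    }


def _run_recovery_seed(seed: int) -> dict:
    config = SimConfig(seed=seed)
    matrix, clinical, truth = simulate_cohort(config)
    corrected, _ = batchfx.combat_adjust(matrix)

    cons1 = consensus.consensus_cluster(
        corrected, genes=config.program_genes, kmax=3, seed=seed + 1000
    )
    subtype = cons1.assignments[2]
    ari = adjusted_rand_score(subtype, truth.subtype.loc[subtype.index])

    deg_table = degstats.moderated_t_table(corrected, truth.subtype)
    degs = degstats.filter_degs(deg_table)
    n_sig_recovered = len(set(degs) & set(config.signature_genes))

    csrgs, _ = survstats.screen_prognostic(corrected, clinical, rule="csrg", genes=degs)
    cons2 = consensus.consensus_cluster(
        corrected, genes=csrgs, kmax=3, seed=seed + 2000
    )
    gene_cluster = _order_clusters_by_prognosis(cons2.assignments[2], clinical, ("C2", "C1"))
    split = cuscore.split_signature(corrected, csrgs, gene_cluster, "C1")
    # true sign convention: sigC1 = up in the poor-prognosis cluster = sign -1
    signs = truth.signature_signs
    sign_hits = sum(1 for g in split.sig_c1 if g in signs.index and signs[g] == -1)
    sign_hits += sum(1 for g in split.sig_c2 if g in signs.index and signs[g] == +1)

    cus = cuscore.compute_cus(corrected, split)
    r = float(np.corrcoef(cus.cus.loc[truth.activity.index], truth.activity)[0, 1])

    cut = survstats.optimal_cutpoint(
        cus.cus.loc[clinical.samples].to_numpy(), clinical.time, clinical.event
    )
    group = cuscore.assign_cus_groups(cus.cus, cut.cutoff).loc[clinical.samples]
    _, _, logrank_p = survstats.logrank_test(clinical.time, clinical.event, group.to_numpy())
    cox_group = survstats.cox_fit_univariate(
        clinical.time, clinical.event, (group == "high").astype(float).to_numpy()
    )
    cox_activity = survstats.cox_fit_univariate(
        clinical.time, clinical.event, truth.activity.loc[clinical.samples].to_numpy()
    )
    return {
        "ari": ari,
        "n_sig_recovered": n_sig_recovered,
        "n_signature": config.n_signature_genes,
        "n_csrgs": len(csrgs),
        "sign_hits": sign_hits,
        "cus_activity_corr": r,
        "logrank_p": logrank_p,
        "hr": cox_group.hr,
        "hr_ci": (cox_group.ci_low, cox_group.ci_high),
        "beta_activity": cox_activity.beta,
        "censor_frac": 1.0 - clinical.event.mean(),
    }


@pytest.fixture(scope="session")
def recovery_stats():
    """End-to-end ground-truth recovery over 10 default-condition seeds."""
    return [_run_recovery_seed(seed) for seed in range(10)]


@pytest.fixture(scope="session")
def boruta_null():
    """Boruta on 50 pure-noise features (n=200), 10 seeds: returns
    (mean rejected fraction, total confirmed)."""
    rejected_fracs, confirmed = [], 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        n, p = 200, 50
        y = pd.Series(rng.integers(0, 2, n), index=[f"s{i}" for i in range(n)])
        features = pd.DataFrame(
            rng.normal(size=(n, p)), index=y.index, columns=[f"f{i}" for i in range(p)]
        )
        report = cuscore.boruta_select(features, y, seed=seed, max_iter=30)
        rejected_fracs.append(len(report.rejected) / p)
        confirmed += len(report.confirmed)
    return float(np.mean(rejected_fracs)), confirmed


@pytest.fixture(scope="session")
def boruta_recovery():
    """Boruta on 5 informative + 50 noise features, 10 seeds: returns the
    number of seeds in which all 5 informative features were confirmed."""
    all_found = 0
    for seed in range(10):
        rng = np.random.default_rng(100 + seed)
        n = 200
        y_num = rng.integers(0, 2, n)
        y = pd.Series(y_num, index=[f"s{i}" for i in range(n)])
        info = y_num[:, None] * 2.0 + rng.normal(size=(n, 5))
        noise = rng.normal(size=(n, 50))
        features = pd.DataFrame(
            np.hstack([info, noise]), index=y.index,
            columns=[f"inf{i}" for i in range(5)] + [f"n{i}" for i in range(50)],
        )
        report = cuscore.boruta_select(features, y, seed=seed, max_iter=30)
        all_found += all(report.status[f"inf{i}"] == "confirmed" for i in range(5))
    return all_found


@pytest.fixture(scope="session")
def ranksum_type1():
    """Empirical type-I error of the rank-sum test at nominal 0.05
    (n=20 vs 20 normal null, 5000 replicates)."""
    rng = np.random.default_rng(42)
    rejections = 0
    reps = 5000
    for _ in range(reps):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        _, p = degstats.rank_sum_test(x, y)
        rejections += p < 0.05
    return rejections / reps


@pytest.fixture(scope="session")
def logrank_type1():
    """Empirical type-I error of the two-group log-rank test at 0.05
    (exchangeable exponential groups with censoring, 5000 replicates)."""
    rng = np.random.default_rng(43)
    rejections = 0
    reps = 5000
    for _ in range(reps):
        time = rng.exponential(1.0, size=100)
        censor = rng.exponential(2.0, size=100)
        obs = np.minimum(time, censor)
        event = (time <= censor).astype(int)
        groups = np.repeat([0, 1], 50)
        _, _, p = survstats.logrank_test(obs, event, groups)
        rejections += p < 0.05
    return rejections / reps


@pytest.fixture(scope="session")
def ora_null_pvals():
    """ORA p-values under random gene draws from the universe (2000 reps)."""
    from cuproscore.cohort_io import GeneSetCollection

    rng = np.random.default_rng(44)
    universe = [f"g{i}" for i in range(200)]
    sets = GeneSetCollection(
        {f"set{j}": list(rng.choice(universe, size=25, replace=False)) for j in range(5)}
    )
    pvals = []
    for _ in range(2000):
        draw = list(rng.choice(universe, size=30, replace=False))
        table = degstats.ora_enrich(draw, universe, sets)
        pvals.extend(table["p"].tolist())
    return np.asarray(pvals)


@pytest.fixture(scope="session")
def null_panel_r():
    """Held-out prediction correlation under a null reference panel
    (response independent of expression), 20 seeds."""
    rs = []
    for seed in range(20):
        config = SimConfig(
            n_genes=200, n_ref_samples=80, n_drugs=1, seed=seed + 300
        )
        panel_expr, panel_resp, _ = simulate_reference_panel(config)
        rng = np.random.default_rng(seed)
        null_resp = panel_resp.copy()
        null_resp.iloc[:, 0] = rng.normal(size=len(null_resp))
        train = panel_expr.values.columns[:60]
        test = panel_expr.values.columns[60:]
        model = drugresp.train_ridge(
            ExpressionMatrix(panel_expr.values[list(train)], panel_expr.unit),
            null_resp.loc[list(train)],
            folds=5,
            seed=seed,
        )
        pred = drugresp.predict_ic50(
            model, ExpressionMatrix(panel_expr.values[list(test)], panel_expr.unit)
        )
        rs.append(float(np.corrcoef(pred.iloc[:, 0], null_resp.loc[list(test)].iloc[:, 0])[0, 1]))
    return np.asarray(rs)
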