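"""End-to-end pipeline: merge/correct -> subtype clustering -> immune
landscape -> DEG screen -> Cox screen -> gene-cluster typing -> signature
split + Boruta + PCA -> CUS + cutoff -> survival/immune/drug comparisons.

A single YAML config drives everything. One global seed fans out to fixed
per-stage seed streams (``SeedSequence([seed, stage_index])``), so toggling
one stage never shifts another stage's randomness, and two runs from the
same config produce byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import batchfx, consensus, cuscore, degstats, drugresp, enrich, survstats
from .cohort_io import (
    ClinicalTable,
    ExpressionMatrix,
    read_clinical,
    read_expression,
    read_gmt,
    summarize_clinical,
    write_clinical,
    write_expression,
)
from .syncohort import SimConfig, simulate_cohort, simulate_reference_panel

logger = logging.getLogger(__name__)

# fixed fan-out indices per stage (stable across config changes)
STAGE_SEEDS = {
    "simulate": 0,
    "cluster": 1,
    "cluster2": 2,
    "boruta": 3,
    "ridge": 4,
}

DEFAULT_PARAMS = {
    "kmax": 4,
    "reps": 50,
    "subsample": 0.8,
    "k_policy": "fixed",
    "fixed_k": 2,
    "lfc": 1.0,
    "pval": 0.05,
    "use_adjusted": False,
    "minprop": 0.1,
    "boruta_alpha": 0.01,
    "boruta_max_iter": 60,
    "keep_tentative": True,
    "folds": 10,
    "min_overlap": 100,
    "lambda_grid": list(drugresp.DEFAULT_LAMBDA_GRID),
}

DEFAULT_STAGES = {
    "correct": True,
    "cluster": True,
    "immune": True,
    "deg": True,
    "cox_screen": True,
    "cluster2": True,
    "score": True,
    "survival": True,
    "drugresp": True,
}


@dataclass
class PipelineConfig:
    seed: int
    output_dir: str
    simulate: dict | None = None          # SimConfig fields; None => load inputs
    inputs: dict = field(default_factory=dict)
    stages: dict = field(default_factory=lambda: dict(DEFAULT_STAGES))
    params: dict = field(default_factory=lambda: dict(DEFAULT_PARAMS))

    def __post_init__(self) -> None:
        self.stages = {**DEFAULT_STAGES, **(self.stages or {})}
        self.params = {**DEFAULT_PARAMS, **(self.params or {})}


def load_config(path) -> PipelineConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> PipelineConfig:
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    extra = set(raw) - known
    if extra:
        raise ValueError(f"unknown config fields: {sorted(extra)}")
    return PipelineConfig(**raw)


def validate_config(config: PipelineConfig | dict | str | Path) -> dict:
    """Schema and cross-field validation without executing anything.

    Returns {"valid": bool, "errors": [...]}.
    """
    errors: list[str] = []
    if isinstance(config, (str, Path)):
        try:
            config = load_config(config)
        except Exception as exc:  # unreadable / malformed file
            return {"valid": False, "errors": [str(exc)]}
    elif isinstance(config, dict):
        try:
            config = config_from_dict(config)
        except Exception as exc:
            return {"valid": False, "errors": [str(exc)]}

    if not isinstance(config.seed, int) or config.seed < 0:
        errors.append(f"seed: must be a non-negative integer (got {config.seed!r})")
    p = config.params
    if not 0 < p["subsample"] <= 1:
        errors.append(f"params.subsample: consensus stage requires 0 < subsample <= 1 (got {p['subsample']})")
    if p["reps"] < 1:
        errors.append("params.reps: must be >= 1")
    if p["kmax"] < 2:
        errors.append("params.kmax: must be >= 2")
    if p["k_policy"] not in ("min-PAC", "fixed"):
        errors.append(f"params.k_policy: unknown policy {p['k_policy']!r}")
    if not 0 < p["pval"] < 1:
        errors.append("params.pval: must be in (0, 1)")
    if p["lfc"] <= 0:
        errors.append("params.lfc: must be > 0")
    if not 0 < p["minprop"] < 0.5:
        errors.append("params.minprop: must be in (0, 0.5)")
    if p["boruta_max_iter"] < 10:
        errors.append("params.boruta_max_iter: must be >= 10")
    if not p["lambda_grid"]:
        errors.append("params.lambda_grid: must be non-empty")

    if config.simulate is None:
        need = ["expression", "clinical"]
        if config.stages.get("score") or config.stages.get("cluster"):
            need.append("program_genes")
        for key in need:
            if key not in config.inputs:
                errors.append(f"inputs.{key}: required when simulate is off")
            elif key != "program_genes" and not Path(config.inputs[key]).exists():
                errors.append(f"inputs.{key}: path does not exist: {config.inputs[key]}")
        if config.stages.get("survival") and "clinical" not in config.inputs:
            errors.append("inputs.clinical: survival stages need survival columns (time, event)")
    else:
        try:
            sim = dict(config.simulate)
            if "n_samples_per_batch" in sim:
                sim["n_samples_per_batch"] = tuple(sim["n_samples_per_batch"])
            SimConfig(**sim, seed=0) if "seed" not in sim else SimConfig(**sim)
        except (TypeError, ValueError) as exc:
            errors.append(f"simulate: {exc}")
    return {"valid": not errors, "errors": errors}


def _stage_seed(config: PipelineConfig, stage: str) -> int:
    ss = np.random.SeedSequence([int(config.seed), STAGE_SEEDS[stage]])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _order_clusters_by_prognosis(labels: pd.Series, clinical: ClinicalTable, names):
    """Map the two raw cluster ids onto ``names`` (better prognosis first),
    using the sign of the two-group log-rank O-E statistic."""
    common = labels.index.intersection(clinical.data.index)
    lab = labels.loc[common]
    levels = sorted(pd.unique(lab))
    time = clinical.data.loc[common, "time"].to_numpy(dtype=float)
    event = clinical.data.loc[common, "event"].to_numpy(dtype=int)
    ome, _ = survstats._logrank_two(time, event, (lab == levels[0]).to_numpy())
    # fewer observed than expected events => better prognosis
    better_first = ome <= 0
    mapping = {
        levels[0]: names[0] if better_first else names[1],
        levels[1]: names[1] if better_first else names[0],
    }
    return labels.map(mapping)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order and write all artifacts plus a
    JSON manifest (config, per-stage seeds and wall-clock, file checksums)."""
    report = validate_config(config)
    if not report["valid"]:
        raise ValueError("invalid config: " + "; ".join(report["errors"]))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "stages": {},
        "files": {},
        "warnings": [],
    }
    results: dict = {}

    def record(stage: str, started: float) -> None:
        manifest["stages"][stage] = {"seconds": round(_time.time() - started, 3)}

    def save_df(df: pd.DataFrame, name: str, **kw) -> None:
        path = out / name
        df.to_csv(path, sep="\t", **kw)
        manifest["files"][name] = _sha256(path)

    # ---- inputs ----
    t0 = _time.time()
    truth = None
    panel = None
    if config.simulate is not None:
        sim = dict(config.simulate)
        if "n_samples_per_batch" in sim:
            sim["n_samples_per_batch"] = tuple(sim["n_samples_per_batch"])
        sim.setdefault("seed", _stage_seed(config, "simulate"))
        sim_config = SimConfig(**sim)
        matrix, clinical, truth = simulate_cohort(sim_config)
        if config.stages["drugresp"]:
            panel_expr, panel_resp, _ = simulate_reference_panel(sim_config)
            panel = (panel_expr, panel_resp)
        from .cohort_io import GeneSetCollection

        genesets = GeneSetCollection(dict(sim_config.immune_sets))
        program_genes = sim_config.program_genes
        write_expression(matrix, out / "expression.tsv")
        manifest["files"]["expression.tsv"] = _sha256(out / "expression.tsv")
        write_clinical(clinical, out / "clinical.tsv")
        manifest["files"]["clinical.tsv"] = _sha256(out / "clinical.tsv")
    else:
        matrix = read_expression(config.inputs["expression"])
        clinical = read_clinical(config.inputs["clinical"])
        genesets = read_gmt(config.inputs["genesets"]) if "genesets" in config.inputs else None
        program_genes = config.inputs.get("program_genes", [])
        if "panel_expression" in config.inputs:
            panel = (
                read_expression(config.inputs["panel_expression"]),
                pd.read_csv(config.inputs["panel_ic50"], sep="\t", index_col=0),
            )
        if matrix.batch is None and "batch" in clinical.data.columns:
            matrix.batch = clinical.data["batch"].reindex(matrix.values.columns)
    baseline_covs = [c for c in ("grade", "stage") if c in clinical.data.columns]
    if baseline_covs:
        baseline = summarize_clinical(clinical, baseline_covs)
        save_df(pd.concat(baseline, names=["covariate", "level"]), "baseline.tsv")
        results["baseline"] = baseline
    record("input", t0)

    # ---- batch correction ----
    if config.stages["correct"] and matrix.batch is not None and matrix.batch.nunique() > 1:
        t0 = _time.time()
        pre = batchfx.batch_severity(matrix)
        matrix, batch_model = batchfx.combat_adjust(matrix)
        post = batchfx.batch_severity(matrix)
        results["batch_severity"] = {"before": pre, "after": post}
        with open(out / "batch_severity.json", "w") as fh:
            json.dump(results["batch_severity"], fh, indent=2, sort_keys=True)
        manifest["files"]["batch_severity.json"] = _sha256(out / "batch_severity.json")
        write_expression(matrix, out / "expression_corrected.tsv")
        manifest["files"]["expression_corrected.tsv"] = _sha256(out / "expression_corrected.tsv")
        record("correct", t0)
    results["matrix"] = matrix
    results["clinical"] = clinical
    results["truth"] = truth

    p = config.params

    # ---- first clustering: CPG subtypes ----
    if config.stages["cluster"]:
        t0 = _time.time()
        if not program_genes:
            raise ValueError("cluster stage requires program_genes")
        cons1 = consensus.consensus_cluster(
            matrix, genes=program_genes, kmax=p["kmax"], reps=p["reps"],
            subsample=p["subsample"], seed=_stage_seed(config, "cluster"),
        )
        k1 = consensus.choose_k(cons1, p["k_policy"], p.get("fixed_k"))
        subtype = _order_clusters_by_prognosis(cons1.assignments[k1], clinical, ("A", "B"))
        results["consensus1"] = cons1
        results["subtype"] = subtype
        save_df(subtype.rename("subtype").to_frame(), "subtypes.tsv", index_label="sample")
        if config.stages["survival"]:
            chi2, df, pval = survstats.logrank_test(
                clinical.time, clinical.event, subtype.loc[clinical.samples].to_numpy()
            )
            results["subtype_logrank"] = {"chi2": chi2, "df": df, "p": pval}
        record("cluster", t0)

    # ---- immune landscape ----
    if config.stages["immune"] and genesets is not None and len(genesets) > 0:
        t0 = _time.time()
        immune = enrich.ssgsea_scores(matrix, genesets)
        results["immune_scores"] = immune
        save_df(immune.scores, "immune_ssgsea.tsv", index_label="sample")
        record("immune", t0)

    # ---- DEG screen between subtypes ----
    if config.stages["deg"]:
        t0 = _time.time()
        if "subtype" not in results:
            raise ValueError("deg stage requires the cluster stage")
        deg_table = degstats.moderated_t_table(
            matrix, results["subtype"], group_order=("A", "B")
        )
        degs = degstats.filter_degs(
            deg_table, lfc_thresh=p["lfc"], p_thresh=p["pval"], use_adjusted=p["use_adjusted"]
        )
        results["deg_table"] = deg_table
        results["degs"] = degs
        save_df(deg_table.loc[degs], "degs.tsv", index_label="gene")
        if genesets is not None and len(genesets) > 0:
            results["ora"] = degstats.ora_enrich(degs, list(matrix.values.index), genesets)
            save_df(results["ora"], "ora.tsv")
        record("deg", t0)

    # ---- univariate Cox screen of DEGs -> CSRGs ----
    if config.stages["cox_screen"]:
        t0 = _time.time()
        csrgs, cox_table = survstats.screen_prognostic(
            matrix, clinical, rule="csrg", genes=results["degs"]
        )
        results["csrgs"] = csrgs
        results["cox_table"] = cox_table
        save_df(cox_table, "cox_screen.tsv")
        record("cox_screen", t0)

    # ---- secondary clustering: gene clusters on CSRGs ----
    if config.stages["cluster2"]:
        t0 = _time.time()
        if len(results.get("csrgs", [])) < 2:
            raise ValueError("cluster2 stage needs >= 2 CSRGs")
        cons2 = consensus.consensus_cluster(
            matrix, genes=results["csrgs"], kmax=p["kmax"], reps=p["reps"],
            subsample=p["subsample"], seed=_stage_seed(config, "cluster2"),
        )
        k2 = consensus.choose_k(cons2, p["k_policy"], p.get("fixed_k"))
        # C1 = poorer prognosis, matching the reported gene-cluster ordering
        gene_cluster = _order_clusters_by_prognosis(
            cons2.assignments[k2], clinical, ("C2", "C1")
        )
        results["consensus2"] = cons2
        results["gene_cluster"] = gene_cluster
        save_df(gene_cluster.rename("gene_cluster").to_frame(), "gene_clusters.tsv",
                index_label="sample")
        record("cluster2", t0)

    # ---- signature split + Boruta + PCA -> CUS ----
    if config.stages["score"]:
        t0 = _time.time()
        split = cuscore.split_signature(
            matrix, results["csrgs"], results["gene_cluster"], reference_cluster="C1"
        )
        boruta = cuscore.boruta_select(
            matrix.values.loc[results["csrgs"]].T,
            results["gene_cluster"],
            alpha=p["boruta_alpha"],
            max_iter=p["boruta_max_iter"],
            seed=_stage_seed(config, "boruta"),
        )
        cus = cuscore.compute_cus(matrix, split, boruta, keep_tentative=p["keep_tentative"])
        cut = survstats.optimal_cutpoint(
            cus.cus.loc[clinical.samples].to_numpy(), clinical.time, clinical.event,
            minprop=p["minprop"],
        )
        cus.cutoff = cut.cutoff
        group = cuscore.assign_cus_groups(cus.cus, cut.cutoff)
        cus.table["group"] = group
        results.update(split=split, boruta=boruta, cus=cus, cutpoint=cut, cus_group=group)
        save_df(cus.table, "cus.tsv", index_label="sample")
        with open(out / "boruta.json", "w") as fh:
            json.dump(
                {
                    "status": boruta.status.to_dict(),
                    "hits": boruta.hits.to_dict(),
                    "iterations": boruta.iterations,
                    "alpha": boruta.alpha,
                },
                fh, indent=2, sort_keys=True,
            )
        manifest["files"]["boruta.json"] = _sha256(out / "boruta.json")
        record("score", t0)

    # ---- survival & immune contrasts of the CUS groups ----
    if config.stages["survival"] and "cus_group" in results:
        t0 = _time.time()
        grp = results["cus_group"].loc[clinical.samples]
        chi2, df, pval = survstats.logrank_test(clinical.time, clinical.event, grp.to_numpy())
        cox = survstats.cox_fit_univariate(
            clinical.time, clinical.event, (grp == "high").astype(float).to_numpy(),
            name="CUS high vs low",
        )
        results["cus_logrank"] = {"chi2": chi2, "df": df, "p": pval}
        results["cus_cox"] = cox
        surv = {
            "cus_logrank": results["cus_logrank"],
            "cus_hr": {"HR": cox.hr, "ci_low": cox.ci_low, "ci_high": cox.ci_high, "p": cox.p},
            "cutoff": results["cutpoint"].cutoff,
            "cutpoint_statistic": results["cutpoint"].statistic,
            "cutpoint_p_descriptive": True,
        }
        if "subtype_logrank" in results:
            surv["subtype_logrank"] = results["subtype_logrank"]
        with open(out / "survival.json", "w") as fh:
            json.dump(surv, fh, indent=2, sort_keys=True)
        manifest["files"]["survival.json"] = _sha256(out / "survival.json")
        if "immune_scores" in results:
            corr = enrich.correlate_scores(results["cus"].cus, results["immune_scores"])
            results["cus_immune_corr"] = corr
            save_df(corr, "cus_immune_correlation.tsv")
        record("survival", t0)

    # ---- drug response ----
    if config.stages["drugresp"] and panel is not None:
        t0 = _time.time()
        panel_expr, panel_resp = panel
        ref_c, coh_c = drugresp.homogenize(panel_expr, matrix, min_overlap=p["min_overlap"])
        model = drugresp.train_ridge(
            ref_c, panel_resp, lambda_grid=p["lambda_grid"], folds=p["folds"],
            seed=_stage_seed(config, "ridge"),
        )
        pred = drugresp.predict_ic50(model, coh_c)
        results["ic50_pred"] = pred
        save_df(pred, "ic50_predicted.tsv", index_label="sample")
        if "cus_group" in results:
            grp = results["cus_group"].reindex(pred.index)
            rows = []
            for drug in pred.columns:
                hi = pred.loc[grp == "high", drug]
                lo = pred.loc[grp == "low", drug]
                u, pv = degstats.rank_sum_test(hi, lo)
                rows.append((drug, float(hi.median()), float(lo.median()), u, pv))
            drug_cmp = pd.DataFrame(
                rows, columns=["drug", "median_high", "median_low", "U", "p"]
            ).set_index("drug")
            results["drug_comparison"] = drug_cmp
            save_df(drug_cmp, "drug_comparison.tsv")
        if program_genes:
            gd = drugresp.gene_drug_correlation(matrix, pred, genes=program_genes)
            results["gene_drug"] = gd
            save_df(gd, "gene_drug_correlation.tsv", index=False)
            cpgs, cpg_table = survstats.screen_prognostic(
                matrix, clinical, rule="potential_cpg", genes=program_genes
            )
            results["potential_cpgs"] = cpgs
            save_df(cpg_table, "potential_cpg_screen.tsv")
        record("drugresp", t0)

    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    results["manifest"] = manifest
    return results
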