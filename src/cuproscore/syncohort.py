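"""Synthetic cohorts with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: a two-batch bulk expression cohort on the log2 scale in which a
small "program" of cuproptosis-promoting genes (CPGs) defines two latent
subtypes, ~30 signature genes track the program with known positive or
negative association signs, overall survival follows an exponential
proportional-hazards model driven by the latent program, immune marker sets
shift with a subtype-dependent infiltration fraction, and a cell-line-like
reference panel carries drug log-IC50 values that are linear in a known gene
subset.

Orientation convention: the recorded latent ``activity`` is the risk score
entering the hazard (linear predictor = ``hazard_coef * activity``), i.e. the
*loss* of the protective program. Subtype 2 has the program genes shifted
down by ``subtype_effect`` and therefore high activity and poor prognosis,
mirroring the biology where low CPG expression marks the poor-prognosis
cluster. The centred program expression itself is kept as
``program_level = -activity``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort_io import (
    ClinicalTable,
    ExpressionMatrix,
    GeneSetCollection,
    write_clinical,
    write_expression,
    write_gmt,
)


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults define the standard study conditions used throughout the test
    suite: 2 batches of 200 samples, 1000 genes of which 7 form the CPG
    program and 31 the downstream signature (16 positively / 15 negatively
    associated), a 2.0 log2-unit subtype shift on the program genes, additive
    per-gene batch shifts drawn N(0, 0.5^2), unit residual noise, hazard
    coefficient 0.8 per unit latent activity and a target censoring fraction
    of 0.4.
    """

    n_samples_per_batch: tuple[int, ...] = (200, 200)
    n_genes: int = 1000
    n_program_genes: int = 7
    n_signature_genes: int = 31
    n_signature_positive: int = 16
    subtype_effect: float = 2.0
    batch_shift: float = 0.5       # SD of the additive per-gene batch shift
    batch_scale_sd: float = 0.0    # log-SD of a per-gene batch noise-scale effect
    noise_sd: float = 1.0
    activity_jitter_sd: float = 0.0
    hazard_coef: float = 0.8
    baseline_hazard: float = 1e-3  # events per day
    censor_rate: float = 0.4
    n_immune_sets: int = 5
    immune_set_size: int = 10
    immune_shift: float = 1.5
    n_ref_samples: int = 120
    n_drugs: int = 2
    n_predictor_genes: int = 10
    drug_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_samples_per_batch": min(self.n_samples_per_batch, default=0),
            "n_genes": self.n_genes,
            "n_program_genes": self.n_program_genes,
            "n_signature_genes": self.n_signature_genes,
            "n_immune_sets": self.n_immune_sets,
            "immune_set_size": self.immune_set_size,
            "n_ref_samples": self.n_ref_samples,
        }
        for name, val in counts.items():
            if val <= 0:
                raise ValueError(f"{name} must be positive (got {val})")
        if not 0 <= self.censor_rate < 1:
            raise ValueError(f"censor_rate must be in [0, 1) (got {self.censor_rate})")
        if not 0 <= self.n_signature_positive <= self.n_signature_genes:
            raise ValueError("n_signature_positive must lie in [0, n_signature_genes]")
        reserved = (
            self.n_program_genes
            + self.n_signature_genes
            + self.n_immune_sets * self.immune_set_size
        )
        if reserved > self.n_genes:
            raise ValueError(
                f"program, signature and immune marker genes ({reserved}) "
                f"exceed n_genes ({self.n_genes}); index sets must be disjoint"
            )

    # --- gene universe (disjoint by construction) ---

    @property
    def program_genes(self) -> list[str]:
        return [f"CPG{i + 1:02d}" for i in range(self.n_program_genes)]

    @property
    def signature_genes(self) -> list[str]:
        return [f"SIG{i + 1:02d}" for i in range(self.n_signature_genes)]

    @property
    def immune_sets(self) -> dict[str, list[str]]:
        return {
            f"immune_cell_{s + 1}": [
                f"IMM{s + 1:02d}_{j + 1:02d}" for j in range(self.immune_set_size)
            ]
            for s in range(self.n_immune_sets)
        }

    @property
    def all_genes(self) -> list[str]:
        marker = [g for genes in self.immune_sets.values() for g in genes]
        n_noise = self.n_genes - self.n_program_genes - self.n_signature_genes - len(marker)
        noise = [f"NOISE{i + 1:04d}" for i in range(n_noise)]
        return self.program_genes + self.signature_genes + marker + noise

    @property
    def signature_signs(self) -> pd.Series:
        signs = [1] * self.n_signature_positive + [-1] * (
            self.n_signature_genes - self.n_signature_positive
        )
        return pd.Series(signs, index=self.signature_genes, dtype=int)


@dataclass
class GroundTruth:
    """Latent state of a simulated cohort or reference panel."""

    subtype: pd.Series | None = None          # 1 (high program) / 2 (low program)
    activity: pd.Series | None = None         # risk score entering the hazard
    program_level: pd.Series | None = None    # centred program expression = -activity
    batch: pd.Series | None = None
    infiltration: pd.Series | None = None     # immune fraction in [0, 1]
    signature_signs: pd.Series | None = None  # +1 / -1 per signature gene
    program_genes: list[str] = field(default_factory=list)
    signature_genes: list[str] = field(default_factory=list)
    immune_sets: dict[str, list[str]] = field(default_factory=dict)
    drug_coefficients: pd.DataFrame | None = None  # gene x drug
    drug_intercepts: pd.Series | None = None
    true_log_ic50: pd.DataFrame | None = None      # sample x drug


def _baseline_means(config: SimConfig) -> pd.Series:
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    mu = rng.normal(6.0, 1.5, size=config.n_genes)
    return pd.Series(mu, index=config.all_genes)


def _batch_effects(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene additive shift and multiplicative noise scale per batch."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    n_b = len(config.n_samples_per_batch)
    gamma = rng.normal(0.0, 1.0, size=(config.n_genes, n_b)) * config.batch_shift
    if config.batch_scale_sd > 0:
        delta = np.exp(rng.normal(0.0, config.batch_scale_sd, size=(config.n_genes, n_b)))
    else:
        rng.normal(size=(config.n_genes, n_b))  # keep stream alignment
        delta = np.ones((config.n_genes, n_b))
    idx = config.all_genes
    return (
        pd.DataFrame(gamma, index=idx, columns=range(n_b)),
        pd.DataFrame(delta, index=idx, columns=range(n_b)),
    )


def drug_coefficients(config: SimConfig) -> tuple[pd.DataFrame, pd.Series]:
    """True linear model of each simulated drug's log-IC50.

    Each drug's predictor genes are drawn from the signature, with
    coefficient signs aligned to the genes' program-association signs (times
    a per-drug orientation): sensitivity is driven by the latent program, the
    way pathway-level biology drives response to a targeted agent. This makes
    the response learnable from the correlated signature axis and
    subtype-dependent in the cohort. Shared between :func:`simulate_cohort`
    and :func:`simulate_reference_panel` so cohort-side true responses and
    panel training targets agree.
    """
    if config.n_drugs < 1:
        raise ValueError("at least 1 simulated drug is required")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
    genes = config.all_genes
    signs = config.signature_signs
    coefs = pd.DataFrame(0.0, index=genes, columns=[f"drug_{d + 1}" for d in range(config.n_drugs)])
    n_pick = min(config.n_predictor_genes, config.n_signature_genes)
    for drug in coefs.columns:
        picked = rng.choice(config.signature_genes, size=n_pick, replace=False)
        orient = rng.choice([-1.0, 1.0])
        vals = rng.uniform(0.3, 0.7, size=n_pick)
        coefs.loc[picked, drug] = orient * vals * signs[picked].to_numpy()
    intercepts = pd.Series(rng.normal(1.0, 0.5, size=config.n_drugs), index=coefs.columns)
    return coefs, intercepts


def _censoring_rate(rates: np.ndarray, target: float) -> float:
    """Exponential censoring rate achieving the target expected censoring
    fraction against per-sample exponential event rates, by bisection."""
    if target <= 0:
        return 0.0

    def frac(lam: float) -> float:
        return float(np.mean(lam / (lam + rates)))

    lo, hi = 1e-12, 1.0
    while frac(hi) < target:
        hi *= 10
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if frac(mid) < target:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def simulate_cohort(config: SimConfig) -> tuple[ExpressionMatrix, ClinicalTable, GroundTruth]:
    """Simulate a two-batch log2-scale expression cohort with survival.

    Subtype 2 has the CPG program shifted down by ``subtype_effect``;
    survival times are exponential with linear predictor
    ``hazard_coef * activity`` and independent exponential censoring tuned
    to the target censoring fraction. Fixed seed gives identical output.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 404]))
    mu = _baseline_means(config)
    gamma, delta = _batch_effects(config)

    n = int(sum(config.n_samples_per_batch))
    samples = [f"S{i + 1:04d}" for i in range(n)]
    batch = np.repeat(np.arange(len(config.n_samples_per_batch)), config.n_samples_per_batch)

    subtype = rng.integers(1, 3, size=n)  # 1 or 2
    jitter = rng.normal(0.0, config.activity_jitter_sd, size=n)
    program_level = np.where(subtype == 1, 0.5, -0.5) * config.subtype_effect + jitter
    activity = -program_level

    infiltration = np.clip(
        0.35 + 0.30 * (subtype == 2) + rng.normal(0.0, 0.15, size=n), 0.0, 1.0
    )

    genes = config.all_genes
    signs = config.signature_signs
    # structural means per gene per sample
    expr = np.tile(mu.to_numpy()[:, None], (1, n))
    gene_pos = {g: i for i, g in enumerate(genes)}
    for g in config.program_genes:
        expr[gene_pos[g]] += program_level
    for g in config.signature_genes:
        expr[gene_pos[g]] += signs[g] * program_level
    for markers in config.immune_sets.values():
        for g in markers:
            expr[gene_pos[g]] += config.immune_shift * infiltration
    # batch structure + residual noise
    expr += gamma.to_numpy()[:, batch]
    expr += rng.normal(0.0, config.noise_sd, size=expr.shape) * delta.to_numpy()[:, batch]

    values = pd.DataFrame(expr, index=genes, columns=samples)
    batch_s = pd.Series(batch, index=samples)
    matrix = ExpressionMatrix(values, "log2TPM1", batch_s)

    # survival: exponential PH, exponential independent censoring
    rates = config.baseline_hazard * np.exp(config.hazard_coef * activity)
    event_t = rng.exponential(1.0 / rates)
    lam_c = _censoring_rate(rates, config.censor_rate)
    if lam_c > 0:
        censor_t = rng.exponential(1.0 / lam_c, size=n)
    else:
        censor_t = np.full(n, np.inf)
    time = np.minimum(event_t, censor_t)
    event = (event_t <= censor_t).astype(int)

    grade_probs = {1: [0.05, 0.55, 0.30, 0.10], 2: [0.02, 0.33, 0.45, 0.20]}
    stage_probs = {1: [0.60, 0.15, 0.17, 0.08], 2: [0.40, 0.10, 0.28, 0.22]}
    grade = np.array([
        rng.choice(["G1", "G2", "G3", "G4"], p=grade_probs[s]) for s in subtype
    ])
    stage = np.array([
        rng.choice(["I", "II", "III", "IV"], p=stage_probs[s]) for s in subtype
    ])

    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "time": np.maximum(time, 1e-3),
                "event": event,
                "grade": grade,
                "stage": stage,
                "batch": batch,
            },
            index=pd.Index(samples, name="sample"),
        )
    )

    if config.n_drugs >= 1:
        coefs, intercepts = drug_coefficients(config)
        true_ic50 = values.T @ coefs + intercepts
    else:
        coefs, intercepts, true_ic50 = None, None, None

    truth = GroundTruth(
        subtype=pd.Series(subtype, index=samples),
        activity=pd.Series(activity, index=samples),
        program_level=pd.Series(program_level, index=samples),
        batch=batch_s,
        infiltration=pd.Series(infiltration, index=samples),
        signature_signs=signs,
        program_genes=config.program_genes,
        signature_genes=config.signature_genes,
        immune_sets=config.immune_sets,
        drug_coefficients=coefs,
        drug_intercepts=intercepts,
        true_log_ic50=true_ic50,
    )
    return matrix, clinical, truth


def simulate_reference_panel(
    config: SimConfig,
    stream: int = 0,
) -> tuple[ExpressionMatrix, pd.DataFrame, GroundTruth]:
    """Simulate a cell-line-like reference panel with measured log-IC50.

    Panel expression shares the cohort's gene universe; each line carries a
    continuous latent program activity ~ N(0, 1). Per drug, log-IC50 is a
    linear combination of the drug's predictor genes plus N(0, sigma^2)
    noise; the true coefficients are recorded in the returned GroundTruth.

    ``stream`` selects an independent sampling stream under the same true
    drug model — stream 0 is the reference panel itself; other streams give
    independent panels for held-out evaluation.
    """
    if config.n_drugs < 1:
        raise ValueError("at least 1 simulated drug is required")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 505, stream]))
    mu = _baseline_means(config)
    genes = config.all_genes
    n = config.n_ref_samples
    lines = [f"CL{i + 1:04d}" for i in range(n)]

    program_level = rng.normal(0.0, 1.0, size=n)
    infiltration = np.clip(rng.normal(0.5, 0.15, size=n), 0.0, 1.0)

    expr = np.tile(mu.to_numpy()[:, None], (1, n))
    gene_pos = {g: i for i, g in enumerate(genes)}
    signs = config.signature_signs
    for g in config.program_genes:
        expr[gene_pos[g]] += program_level
    for g in config.signature_genes:
        expr[gene_pos[g]] += signs[g] * program_level
    for markers in config.immune_sets.values():
        for g in markers:
            expr[gene_pos[g]] += config.immune_shift * infiltration
    expr += rng.normal(0.0, config.noise_sd, size=expr.shape)

    values = pd.DataFrame(expr, index=genes, columns=lines)
    coefs, intercepts = drug_coefficients(config)
    if config.drug_noise_sd == 0 and (coefs.to_numpy() == 0).all(axis=0).any():
        bad = coefs.columns[(coefs.to_numpy() == 0).all(axis=0)].tolist()
        raise ValueError(f"degenerate constant response (zero coefficients, zero noise): {bad}")
    signal = values.T @ coefs + intercepts
    response = signal + rng.normal(0.0, config.drug_noise_sd, size=signal.shape)

    truth = GroundTruth(
        activity=pd.Series(-program_level, index=lines),
        program_level=pd.Series(program_level, index=lines),
        signature_signs=signs,
        program_genes=config.program_genes,
        signature_genes=config.signature_genes,
        immune_sets=config.immune_sets,
        drug_coefficients=coefs,
        drug_intercepts=intercepts,
        true_log_ic50=signal,
    )
    return ExpressionMatrix(values, "log2TPM1"), response, truth


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_fixture_bundle(dir_path, config: SimConfig) -> dict:
    """Write a complete synthetic study to ``dir_path``.

    Emits expression, clinical, ground-truth and reference-panel TSVs plus a
    GMT of immune/signature gene sets and a JSON manifest with the config and
    per-file SHA-256 checksums.
    """
    out = Path(dir_path)
    out.mkdir(parents=True, exist_ok=True)
    matrix, clinical, truth = simulate_cohort(config)
    panel_expr, panel_resp, panel_truth = simulate_reference_panel(config)

    write_expression(matrix, out / "expression.tsv")
    write_clinical(clinical, out / "clinical.tsv")
    sets = dict(config.immune_sets)
    signs = config.signature_signs
    sets["signature_pos"] = [g for g in config.signature_genes if signs[g] > 0]
    sets["signature_neg"] = [g for g in config.signature_genes if signs[g] < 0]
    write_gmt(GeneSetCollection(sets), out / "genesets.gmt")
    write_expression(panel_expr, out / "panel_expression.tsv")
    panel_resp.to_csv(out / "panel_ic50.tsv", sep="\t", index_label="sample")
    gt = pd.DataFrame(
        {
            "subtype": truth.subtype,
            "activity": truth.activity,
            "batch": truth.batch,
            "infiltration": truth.infiltration,
        }
    )
    gt.to_csv(out / "ground_truth.tsv", sep="\t", index_label="sample")

    files = [
        "expression.tsv",
        "clinical.tsv",
        "genesets.gmt",
        "panel_expression.tsv",
        "panel_ic50.tsv",
        "ground_truth.tsv",
    ]
    manifest = {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "signature_signs": {g: int(s) for g, s in signs.items()},
        "drug_coefficients": {
            d: {g: float(v) for g, v in col.items() if v != 0.0}
            for d, col in truth.drug_coefficients.items()
        },
        "files": {name: _sha256(out / name) for name in files},
    }
    manifest["config"]["n_samples_per_batch"] = list(config.n_samples_per_batch)
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
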