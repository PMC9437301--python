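# Methods

`cuproscore` re-implements, as a tested library, a two-stage molecular
subtyping and scoring analysis for bulk expression cohorts: resampled
consensus clustering on a small cuproptosis-promoting gene (CPG) program,
a prognostic signature derived from the resulting subtypes, a per-sample
cuproptosis score (CUS) built from the signature, survival stratification at
an optimal cutpoint, and downstream immune and drug-response contrasts. This
note records the models, the defaults and why, the numerical choices, and
what the synthetic validation does and does not demonstrate.

## Preprocessing

Expression input is FPKM, TPM or log2(TPM+1), declared per matrix. FPKM is
converted per sample as TPM_g = FPKM_g / Σ_g FPKM_g × 10⁶ (each column then
sums to 10⁶); all downstream analysis operates on log2(TPM+1). No variance
filtering is applied by default. Cohorts are merged on the intersection of
their gene universes; samples lacking survival time or event are dropped and
counted; gene ids are matched as exact strings (no alias resolution).
Baseline tables report per-covariate category counts with percentages over
non-missing samples only.

## Batch correction

`batchfx.combat_adjust` is the parametric empirical-Bayes location/scale
model: per gene, standardize against the batch-weighted grand mean and
pooled residual variance; estimate per-batch location (γ) and scale (δ²)
effects; shrink γ toward a normal prior and δ² toward an inverse-gamma
prior, with method-of-moments hyperparameters and iterated conditional
updates (fixed point, tolerance 1e-4 on γ*, max 100 iterations); then
back-transform. No covariate design is supported. Genes with zero pooled
variance pass through unchanged; a single batch is a warning no-op so
one-cohort pipelines run.

Two deliberate conventions:

- **Mean anchoring.** After back-transformation each gene is re-centred to
  its pre-correction pooled (batch-weighted) mean, so correction never moves
  a gene's overall level. The EB estimates are unaffected; only a per-gene
  constant is added.
- **Near-idempotence.** A second correction pass is not an exact no-op: the
  method-of-moments inverse-gamma prior treats the chi-square sampling
  spread of the per-gene scale estimates as real between-gene variation, so
  a repeat pass rescales by roughly half that sampling noise (RMS ≈ 3e-3 at
  500 samples/batch; identical in the reference implementation we
  cross-check against). This is a property of the published algorithm, not
  of this implementation.

Batch severity is reported as the mean per-gene one-way F statistic across
batches plus the silhouette of batch labels on the top-2 principal
components.

## Consensus clustering

`consensus.consensus_cluster` follows the resampling protocol: 50
repetitions, 80% of samples drawn without replacement per repetition, genes
z-scored within the subsample, Euclidean distances, and PAM (k-medoids,
BUILD initialisation then SWAP until no single swap reduces cost) as the
inner clusterer for each k in 2..kmax. The consensus matrix entry for a
sample pair is its co-clustering count divided by its co-sampling count;
pairs never co-sampled get 0 (warned when they exceed 1% of pairs — at 50
repetitions and 80% subsampling this is vanishingly rare above ~30 samples).
The final call per k is an average-linkage hierarchical cut of
1 − consensus. PAM is deterministic given input order; it is a 1-swap local
search and is only guaranteed to match exhaustive medoid search on data with
genuine cluster structure.

k is selected by minimum PAC — the proportion of off-diagonal consensus
entries in (0.1, 0.9) — with ties to the smallest k; a `fixed` policy
reproduces an investigator-chosen k (the pipeline default fixes k = 2,
matching the two-cluster typing the analysis is built around). CDFs and
delta-area of the consensus distribution are also reported.

## Immune landscape scoring

`enrich.ssgsea_scores` implements the single-sample rank-weighted
running-sum enrichment statistic: per sample, genes are ranked by expression
descending (ties broken by ascending gene id, making output
platform-independent), in-set steps are weighted by rank^α (α = 0.25) and
out-of-set steps uniformly, and the score is the integrated difference
between the cumulative in-set weight fraction and the cumulative out-of-set
fraction. Optional normalization divides all scores by the global max − min
of the score matrix and preserves ordering. The statistic is invariant under
strictly monotone transforms of a sample's expression. Stromal and immune
composite scores are the unnormalized enrichment scores of user-supplied
stromal/immune signatures, and their sum forms the purity-tracking
composite; marker gene sets are always inputs (the synthetic generator ships
its own), never bundled.

## Differential expression and generic tests

The moderated t borrows strength across genes through an inverse-chi-square
prior on residual variances. The prior degrees of freedom d₀ and variance
s₀² are fitted by matching the mean and variance of log s² with
digamma/trigamma identities (trigamma inverted by Newton iteration);
posterior variances s̃² = (d₀s₀² + d·s²)/(d₀ + d) feed a t statistic with
d₀ + d degrees of freedom. d₀ → 0 reduces to the ordinary pooled t; a
non-positive excess variance of log s² yields complete shrinkage. DEGs are
filtered at |logFC| > 1 and raw p < 0.05 (strict inequalities; an
`use_adjusted` switch applies the BH column instead, since published
analyses are often ambiguous on this point). logFC is second-group minus
first; the pipeline orders groups so it reads poor-prognosis minus
good-prognosis.

Over-representation uses the hypergeometric upper tail against the
expression matrix's gene universe with BH adjustment across sets. Rank-sum
tests are exact by enumeration when n₁+n₂ ≤ 12 without ties, otherwise
normal with tie and continuity correction (the worst-case gap between the
two at 4 vs 4 is ≈ 0.03). Kruskal–Wallis applies the tie correction with a
chi-square reference. The qPCR fold change is 2^−ΔΔCt.

## Survival analysis

The univariate Cox fit maximizes the partial likelihood by Newton–Raphson
(tolerance 1e-8 on the step, damped to ±2 per iteration) with Efron
handling of tied event times; Breslow is a switch. Monotone likelihoods
(perfect separation) cap |β| at 15 and flag the result instead of failing,
so genome-wide screens complete. Wald intervals and p-values are reported.
Screening rules: `csrg` keeps p < 0.05; `potential_cpg` keeps protective
genes with p < 0.001 and 1 − HR > 0.4.

Kaplan–Meier curves are product-limit estimates with Greenwood variance;
the log-rank test accumulates observed-minus-expected with hypergeometric
variance at each distinct event time (general g groups via the covariance
matrix of the first g − 1). The asymptotic chi-square reference is slightly
anti-conservative in very small groups (empirical size ≈ 0.055 at 20 per
group with ~40% censoring; ≈ 0.051 at 50 per group, the regime used for the
calibration checks).

The optimal cutpoint is the maximally selected standardized log-rank
statistic over all midpoints between consecutive unique score values whose
split leaves both groups with at least ⌈minprop·n⌉ samples (minprop = 0.1;
ties to the lower cutoff). Because the statistic is maximized over
candidate splits, its nominal p-value is anti-conservative — under the null
the selected statistic exceeds the chi-square(1) 95% quantile far more than
5% of the time — so cutpoint p-values are labelled descriptive throughout.

## The cuproptosis score

Prognostic signature genes are split by the sign of their point-biserial
correlation with the indicator of a reference gene-cluster: positive →
sigC1, negative → sigC2 (zero correlations are excluded with a warning).
Each set is reduced to its first principal-component score per sample:
genes are centred and unit-scaled, an SVD taken, and the sample projection
on the first right singular direction used, with the sign fixed so the
score correlates non-negatively with the set's mean scaled expression
(PC sign is otherwise arbitrary). Then

    CUS = PsigC1 − PsigC2,

one PC1 score per signature set per sample; a configuration option adds PC2
to each term. CUS is invariant to gene-wise affine rescaling and exactly
negates when the two sets are swapped. Whether high CUS marks poor
prognosis is asserted empirically downstream, never assumed; the pipeline
passes the poorer-prognosis gene-cluster as the reference so that, given
the orientation rule, high CUS tracks risk.

Boruta feature selection runs against the gene-cluster label before the PCA
(both the target choice and keeping max-iteration "tentative" features are
flags; defaults: target = gene cluster, tentative kept so small signatures
survive). Each iteration appends an independently shuffled shadow copy of
every active feature, scores a hit for undecided features beating the
maximum shadow importance, and applies a two-sided binomial test at α = 0.01
Bonferroni-adjusted across the features under test; rejected features leave
the design. The default importance is per-tree out-of-bag permutation
importance from a 50-tree random forest (depth ≤ 7): the accuracy drop on a
tree's out-of-bag samples when one column is permuted, averaged over trees.
This choice matters. Impurity importances credit every in-sample split, so
noise features that are spuriously correlated with the target in the
realized dataset repeatedly beat the shadows; ensemble-level permutation
importance masks strongly redundant informative features, because other
trees compensate. Per-tree out-of-bag evaluation handles both regimes. Even
so, a noise feature whose sample correlation is family-wise extreme (|r| ≈
0.24 among 50 features at n = 200) is genuinely relevant *to that dataset*
and may be confirmed; this is a property of all shadow-comparison selectors.

## Drug-response imputation

A reference expression panel with measured log-IC50 is homogenized with the
cohort by treating the two as batches on their shared gene space (≥ 100
genes required by default) and applying the batch correction above. Per
drug, a ridge regression is fitted on gene-standardized reference
expression; the penalty λ is chosen by k-fold (default 10) cross-validated
mean squared error over a log-spaced grid 10⁻²..10⁴, ties to the larger λ
(an explicit, testable alternative to the automatic analytic rule of the
original transfer tool). Cohort predictions use the training
standardization. Group contrasts of predictions use the rank-sum test;
gene–response mining reports Pearson r with BH-adjusted p across all
(gene, drug) pairs.

## The synthetic study

`syncohort` generates cohorts with known ground truth under the structure
the analysis assumes. Defaults (the standard study conditions used by the
tests and the acceptance script):

| parameter | default | meaning |
|---|---|---|
| samples | 2 × 200 | two batches |
| genes | 1000 | 7 CPG program + 31 signature (16+/15−) + 5×10 immune markers + noise |
| subtype_effect | 2.0 | log2 shift of program genes (down in subtype 2) |
| noise_sd | 1.0 | residual log2 SD |
| batch_shift | 0.5 | SD of per-gene additive batch shift, N(0, 0.5²) |
| hazard_coef | 0.8 | log-hazard per unit latent activity |
| baseline_hazard | 1e-3/day | exponential baseline |
| censor_rate | 0.4 | target censoring fraction |
| immune_shift | 1.5 | marker shift per unit infiltration fraction |
| panel | 120 lines, 2 drugs | 10 signature-gene predictors each, response noise SD 0.5 |

Latent structure: each sample has a two-valued centred program level
(±subtype_effect/2; an optional within-subtype jitter defaults to 0).
The recorded latent *activity* is the risk orientation — the negative
program level — and enters an exponential proportional-hazards model as
hazard_coef × activity, so subtype 2 (low program expression) has high
activity and poor prognosis, consistent with a protective program.
Signature genes move with the program level according to their recorded
±1 association sign. Censoring is independent exponential with its rate
solved by bisection so the expected censoring fraction equals the target.
Immune marker genes shift with a per-sample infiltration fraction that is
higher in subtype 2. Drug log-IC50 is a linear combination of signature
genes whose coefficient signs align with the genes' association signs
(sensitivity driven by the latent program, as for a pathway-targeted
agent) plus Gaussian noise; the reference panel draws a continuous program
activity ~ N(0,1), and independent evaluation panels can be drawn under the
same true drug model via a stream argument. Batch effects are additive
per-gene shifts (a scale-effect toggle stresses the variance adjustment).

What the generator does **not** emulate: count-level noise (negative
binomial over-dispersion), library-size and GC artifacts, gene–gene
correlation beyond the single latent program, probe-level platform effects,
informative censoring, and any copy-number/methylation structure. Passing
recovery tests therefore demonstrates that the pipeline's inference is
correct *under its own model assumptions* at realistic effect sizes — not
that those assumptions hold for any particular real cohort.

## Problem sizes and reproducibility

The validation studies use 10 simulation seeds for end-to-end recovery
(n = 400 each), 10 seeds for the Boruta null/recovery experiments, 5000
replicates for rank-sum/log-rank calibration, and 2000 for the ORA and
cutpoint-inflation nulls — sizes at which every asserted margin is stable
across reruns on a single CPU. The pipeline fans a single global seed into
fixed per-stage streams (`SeedSequence([seed, stage_index])`), so toggling
one stage never shifts another stage's randomness and two runs from one
config are byte-identical; the run manifest records config, per-stage
wall-clock, and SHA-256 checksums of every artifact.

## Known limitations

- PAM can return a 1-swap local optimum on unstructured data.
- The cutpoint p-value is selection-inflated by construction and is
  reported as descriptive; no selection-adjusted p-value is computed.
- The batch model assumes additive/multiplicative effects on a log scale
  with exchangeable genes; it cannot remove batch-by-subtype confounding.
- Only two-cluster typings are supported by the signature split; the
  consensus machinery itself handles any k.
- The ridge transfer assumes the reference panel and cohort share the
  response-relevant expression axes after homogenization; signal carried by
  genes absent from the shared universe is lost.
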