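# Methods

This note documents the models and procedures `ucscore` implements, the
parameters that matter, what the synthetic cohort generator does and does
not emulate, and the numerical and design choices made where the design was
genuinely open.

## The analysis problem

A cohort of colon biopsies from ulcerative colitis (UC) and IBD-unclassified
(IBDU) patients, plus normal-colon controls, is profiled on a probe-set
expression array (log2 intensities after upstream normalization, which is
out of scope here). Each biopsy carries clinical covariates: the endoscopic
Mayo subscore (0–3) at the biopsy location, partial (0–9) and total (0–12)
Mayo composites, physician's global assessment (0–3), fecal calprotectin
(µg/g, often missing), labeling kit, center, and — for the followed-up
subset — a 3–6-month status code (0–3; > 1 = poor outcome). The package
asks three questions of such data: which transcripts track endoscopic
activity, how well a cross-validated molecular score reproduces the
activity dichotomy, and whether molecular scores carry prognostic
information beyond the standard-of-care variables.

## Labeling-kit harmonization

Two labeling kits introduce a per-probe batch shift. The correction is
per-probe additive mean-matching on the log2 scale: the non-reference kit's
samples receive, probe by probe, the offset that equalizes the two per-kit
means (equivalently a multiplicative linear-scale correction factor). The
reference kit is the one with more samples (ties favour kit_A). The
operation is idempotent and preserves within-kit contrasts exactly. Two
caveats are deliberate: a kit with fewer than two samples is refused (the
offset would be one sample's noise), and kit–class confounding is *not*
adjusted — mean-matching removes the marginal batch shift only. Whether a
per-probe or single global factor is more appropriate is an open design
point; per-probe was chosen because batch effects on arrays are strongly
probe-dependent, and the generator plants them per probe.

## Moderated t landscape

Activity classes are fixed by the endoscopic Mayo subscore: active ⇔
subscore > 1. Per probe g, a two-group comparison on log2 values gives the
mean difference Δg and residual variance s²_g with d_g = n₁ + n₂ − 2 df.
The variances are shrunk toward a scaled inverse-χ² prior with
hyperparameters (d₀, s₀²) estimated by moment matching on log variances:
e_g = log s²_g − ψ(d_g/2) + log(d_g/2) estimates log σ²_g without bias, the
excess of var(e) over the sampling term ψ′(d_g/2) identifies ψ′(d₀/2)
(inverted by Newton iteration), and s₀² follows from the mean of e. The
posterior variance is s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g) and
t_g = Δg/(s̃_g √(1/n₁+1/n₂)) is referred to a t distribution with d₀ + d_g
df (normal when d₀ = ∞). This estimator is cross-checked against R/limma's
`lmFit`/`eBayes` in the test suite and agrees to ~1e-8 on t, p, d₀ and s₀².

Degenerate branch: when the observed variances show no excess dispersion
(var(e) ≤ ψ′(d/2)), the prior is a point mass (d₀ = ∞) located at the
*geometric mean of the observed s²_g* rather than the bias-corrected
exp(mean e). This makes the equal-variance case collapse exactly onto the
ordinary pooled t — the behaviour a user forcing s₀² = s² would expect —
at the cost of a small bias that only matters in the regime where
moderation is pointless anyway. Probes constant across every sample are
flagged and assigned t = 0, p = 1 rather than erroring.

Reported per probe: linear-scale geometric group means (2^mean-log2,
including a display-only control mean — controls never enter the test),
log2 fold change, moderated t, two-sided p, and Benjamini–Hochberg FDR
(step-up, capped at 1). Ranked top lists filter by fold-change sign, sort
by unadjusted p, break ties by larger |log2 FC| then probe id, and can
collapse to one best probe per gene symbol. The volcano table carries
−log10 p, interest-set flags from the annotation, and a marker on the probe
with the largest p still satisfying FDR < 0.05.

## Median-ensemble activity classifiers

Two cohorts are scored: Mayo_Prob_1 (UC biopsies only) and Mayo_Prob_2
(UC + IBDU). Cross-validation is stratified 10-fold (fold sizes within one
sample, class proportions preserved; k = n degenerates to leave-one-out).
Inside each fold, the top 20 probe sets by *ordinary* two-sample t-test —
not the moderated test, which is reserved for the landscape — are selected
on the training split alone and fed to every learner; the held-out 10% is
scored and never touched before the panel is fit (the suite verifies this
with a NaN-poisoning probe). Out-of-fold ensemble scores are pooled into a
single Mann–Whitney AUC rather than averaged per fold.

The 12-learner panel maps the classical roster onto scikit-learn
analogues: LDA; shrinkage LDA (for regularized DA); regularized QDA (for
mixture DA); logistic regression on pairwise interaction expansions (for
flexible DA); gradient boosting; RBF and linear SVMs with Platt-calibrated
probabilities; random forest; a pruned decision tree (for C5.0); a small
MLP; ridge logistic (for Bayesian GLM); and elastic-net logistic (for
glmnet). Hyperparameters are fixed, untuned defaults recorded in the
roster; the roster is a plain list of named factories and can be swapped
wholesale. Every learner must emit P(active) ∈ [0, 1]; the ensemble score
is the per-sample median (mean of the central pair for an even count),
which makes the aggregate robust to any single misbehaving learner. A
learner that fails to fit is retried once and then dropped with a warning;
a fold aborts if more than half the roster fails. Feature selection is
deterministic (seed-free), so refits with different seeds keep the same
feature list; the final deployment model refits the panel on all included
samples and round-trips through save/load with identical scores.

## Transcript-set scores and MCalpro

"Standardized against a control population" is implemented as the linear
fold over the control geometric mean: per probe and sample,
2^(x_gs − mean over controls of x_g·). A transcript-set score is the
geometric mean of these standardized values across the set's probes, so
scores live on a positive fold-vs-control scale and the control population
itself has geometric mean 1 per probe and per set (identity checked to
1e-12). The z-score alternative is available behind a flag for sensitivity
analysis but is not the default: group means of a calprotectin score
reported on a positive fold-like scale, and the geometric mean of z-scores
(which can be ≤ 0), both argue for the fold convention. The control
reference pools both centers. MCalpro is the set score over every probe
annotated to S100A8 or S100A9.

## Overrepresentation analysis

Gene-set collections are supplied as GMT files — term databases are
versioned external inputs, so no specific GO/KEGG release is bundled, and
the synthetic generator writes a small GMT (one planted-up set plus random
sets) for testing. The query is the top 150 activity-increased genes (best
probe per gene; a warning fires if any selected transcript misses
FDR < 0.05, or if fewer than 150 increased transcripts exist). The
background universe is the set of genes represented on the array —
enrichment conditioned on measurability — unless an explicit universe is
given. Per set, p = P(X ≥ k) under Hypergeometric(N, K, n), equal to the
one-sided Fisher exact p of the 2×2 table (verified to 1e-10 against
scipy's Fisher implementation on 500 random configurations), with BH
adjustment across the collection.

## Outcome association battery

All statistics run on complete cases for the variables they use and report
the n consumed. Spearman correlations use midranks with the t-approximation
for p (n − 2 df); constant inputs yield an explicit "undefined" marker, not
a silent zero. Group comparisons against the status-code dichotomy use
Welch's t with Satterthwaite df. The univariate screen fits a
maximum-likelihood logistic model per predictor and reports the Wald p of
the slope plus the AUC of the fitted probabilities; perfect separation
falls back to a ridge-penalized fit with Wald SEs from the penalized
Hessian and is flagged. Nested model comparisons use the likelihood-ratio
test with df equal to the *rank* difference of the two designs — added
covariates exactly collinear with the reduced design are dropped, so adding
a copy gives LRT = 0, p = 1 instead of a singular fit. The default clinical
model is endoscopic Mayo + total Mayo + fecal calprotectin, with the
partial-Mayo variant available via config; the molecular block is
Mayo_Prob_1 + Mayo_Prob_2 + MCalpro.

Permutation importance grows a bagged forest of 500 decision trees
(√p features per split) and scores each variable by the mean decrease in
*out-of-bag* AUC over 50 permutations of its column. AUC-decrease was
chosen over impurity importance because the predictor battery mixes
ordinal clinical grades, a heavy-tailed stool assay, and bounded
probability scores. The forest is built by an explicit bagging loop over
scikit-learn trees because per-tree out-of-bag predictions (needed for the
permuted re-scoring) are not publicly exposed by the stock random-forest
class. Random streams are keyed per variable by sorted name, so the
caller's column order cannot change any result. Fewer than 20 complete
cases are refused. One caveat documented deliberately: permutation
importance splits signal shared by correlated predictors, so with three
inter-correlated molecular scores the stable qualitative statement is that
the *top-ranked* variable is molecular, not that every molecular score
element-wise dominates every clinical covariate.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, at
the emulated study's sample scale (128 UC + 13 IBDU biopsies, 17 controls,
Mayo subscore weights 25/33/49/34) and a default 5,000-probe array — a
scaled-down array with ~40% as many genes as probes, several probes per
gene.

* **Baseline and noise.** Per-probe baseline means U(4, 12) log2-units;
  per-probe residual SDs from a scaled inverse-χ² law (prior df 4, scale
  `noise_sd`² = 1) — the standard empirical-Bayes array variance model, so
  the moderated-t hierarchical model is correctly specified and calibration
  tests probe the estimator, not a generator artefact.
* **Severity.** Latent severity = Mayo subscore + Normal(0, 0.5); controls
  are exactly 0. The within-subscore spread is deliberately substantial:
  the premise of molecular scoring is that continuous scores capture
  heterogeneity the 0–3 grade misses, and with near-noiseless severity the
  recorded subscore would dominate every molecular readout by construction.
* **Planted signal.** `n_signal_probesets` (200) probes shift by
  effect × severity with per-probe magnitudes U(0.5, 1.5) × `effect_size`
  (1 log2-unit) and random signs. The S100A8/A9 pair is always planted,
  always increased, at 2× the base effect — calprotectin subunits are
  canonically among the most strongly induced transcripts in inflamed
  mucosa.
* **Clinical covariates.** Partial Mayo, PGA and total Mayo are noisy
  rounded functions of severity; fecal calprotectin is lognormal around a
  curve in the biopsy's own (pre-batch) S100A8/A9 expression, with heavy
  noise (`calprotectin_noise_sd` = 0.6 on the log scale) — stool and
  tissue measurements agree only loosely.
* **Outcome.** Pr(status code > 1) = logistic(1.8 × (severity − 1.8)),
  then a uniform split within {0,1} / {2,3}. About 57% of biopsies carry a
  status code (the followed-up fraction); stool calprotectin availability
  is nested in follow-up — followed-up biopsies always carry the stool
  measurement, plus half of the rest — mirroring outcome tables that report
  calprotectin group means within the follow-up cohort.
* **Batches.** Half the samples are assigned to kit_B (independently of
  severity by default; a confounded variant exists behind a flag so the
  correction's limits can be probed), with per-probe offsets N(0, 0.3).
* **Ground truth.** The planted probe set, per-probe effects, per-sample
  severities and kit offsets are returned and serialized to a JSON sidecar.

What the generator does **not** emulate, hence what passing tests do not
show about real data: probe-level (pre-summarization) intensities and
upstream normalization; correlation between repeat biopsies of one patient
(every biopsy is independent); center effects beyond the label; dropout or
informative missingness beyond the simple mechanisms above; and any
specific real gene's behaviour — gene symbols are synthetic apart from
S100A8/S100A9. Real-data effect sizes, correlations and AUCs are therefore
benchmarks of structure, not values this package claims to reproduce.

## Validation experiments and problem sizes

`ucscore.evaluation` (exercised by the test suite and by
`scripts/acceptance.py`) runs the whole-workflow checks at fixed sizes
chosen to keep each experiment in the seconds-to-a-minute range: the
leakage guard runs the full 10-fold ensemble on ten signal-free cohorts of
140 biopsies × 5,000 probes (mean pooled AUC expected in [0.40, 0.60]); the
power check runs one planted cohort at the same scale (AUC ≥ 0.85,
per-fold selection precision ≥ 0.9); moderated-t calibration uses the
5,000-probe null cohort (p < 0.05 fraction 0.05 ± 0.01) and a 2,000-probe
equal-variance construction (relative gap to the pooled t ≤ 1e-6); BH and
hypergeometric tests are compared with independent oracles on 1,000 and
500 random configurations; LRT type-I error uses 1,000 null logistic
simulations at n = 140 (0.05 ± 0.02); determinism reruns the full pipeline
twice on a 400-probe cohort and compares bytes; and the importance
structure check runs the default generator end to end.

## Known limitations

* The kit correction assumes the batch effect is additive on log2 and
  unconfounded with class; a confounded design will fold real signal into
  the correction.
* Ensemble probabilities are calibrated only as well as their learners;
  the median is a rank-stable but not calibration-optimal aggregate.
* The LRT and Wald p-values are asymptotic; at n ≈ 80 complete cases with
  ~30% events they are mildly liberal, as the calibration experiment
  quantifies.
* Permutation importance of correlated predictors divides shared credit;
  rankings below the top are not individually meaningful.
* Complete-case analysis throughout; no imputation, no patient-level
  random effects for repeat biopsies, no survival modeling.
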