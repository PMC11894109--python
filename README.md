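# ucscore

Molecular scoring of ulcerative colitis (UC) biopsies from probe-set
microarray expression: a reusable, tested implementation of the workflow
that relates the mucosal transcriptome to endoscopic disease activity and
to short-term clinical outcome.

## Who this is for and what it does

Conventional UC assessment relies on ordinal scores (the 0–3 endoscopic
Mayo subscore, the partial/total Mayo composites, physician's global
assessment) and on fecal calprotectin. These are coarse, observer-dependent
and only weakly predictive of the patient's course. `ucscore` implements a
molecular alternative for bulk expression profiles of colon biopsies:

1. **Molecular landscape** (`ucscore.de`) — per probe set, an
   empirical-Bayes moderated t-test of active (endoscopic Mayo subscore
   > 1) vs inactive (≤ 1) biopsies. Residual variances s²_g with d_g df
   are shrunk toward a scaled inverse-χ² prior fitted by moment matching
   on log variances, giving

       s̃²_g = (d₀·s₀² + d_g·s²_g) / (d₀ + d_g),
       t_g  = Δx̄_g / (s̃_g·√(1/n₁ + 1/n₂)),  df = d₀ + d_g,

   with Benjamini–Hochberg FDR, linear-scale group geometric means,
   ranked top lists, and a volcano table.
2. **Activity classifiers** (`ucscore.classify`) — the Mayo_Prob ensemble:
   stratified 10-fold cross-validation, fold-internal selection of the top
   20 probe sets by two-sample t-test, a panel of 12 commodity learners
   each emitting P(active) ∈ [0, 1], the per-sample **median** of the panel
   as the ensemble score, and a pooled out-of-fold Mann–Whitney AUC.
   Mayo_Prob_1 trains on UC biopsies only; Mayo_Prob_2 adds IBD-unclassified
   (IBDU) biopsies.
3. **Transcript-set scores** (`ucscore.setscores`) — expression standardized
   per probe as the linear fold over the control-population geometric mean,
   2^(x_gs − mean_ctrl(x_g)); a set score is the geometric mean across the
   set's probes. MCalpro, the molecular calprotectin score, uses all probes
   of S100A8 and S100A9 (the calprotectin heterodimer subunits).
4. **Overrepresentation analysis** (`ucscore.enrichment`) — one-sided
   hypergeometric tests of the top-150 activity-increased genes against
   GMT gene-set collections, with the array's gene universe as background.
5. **Outcome statistics** (`ucscore.outcomes`) — Spearman correlation
   tables, Welch tests against the 3–6-month status-code dichotomy (poor
   outcome = status code > 1), univariate logistic screens, nested-model
   likelihood-ratio tests, and random-forest permutation importance by
   out-of-bag AUC decrease.

Because the emulated study's raw data are not publicly deposited, the
package ships a first-class synthetic cohort generator
(`ucscore.synthetic`) that reproduces the statistical structure the
analysis assumes — ~141 UC/IBDU biopsies plus 17 normal controls, a latent
continuous disease severity driving a planted probe-set subset, S100A8/A9
coupled to noisy fecal calprotectin, two labeling-kit batches, and outcome
status codes driven by severity — together with the ground truth needed to
test every stage.

## Worked example

```python
from ucscore import (CohortConfig, generate_cohort, apply_kit_correction,
                     define_activity_classes, ModeratedTTest,
                     ActivityClassifier, mcalpro, spearman)

config = CohortConfig(n_probesets=5000, n_signal_probesets=200, seed=42)
bundle, truth = generate_cohort(config)
matrix = apply_kit_correction(bundle.matrix, bundle.samples)

classes = define_activity_classes(bundle.samples, include_ibdu=False)
de = ModeratedTTest(matrix, classes, control_ids=bundle.control_ids,
                    annotation=bundle.annotation).fit()
print(de.summary())

cv = ActivityClassifier(matrix, classes).cross_validate(k=10, seed=42)
print(cv.summary())

scores = mcalpro(matrix, bundle.control_ids, bundle.annotation)
biopsies = bundle.samples[bundle.samples.diagnosis != "control"]
rho = spearman(scores.loc[biopsies.index], biopsies["fecal_calprotectin"])
print(f"MCalpro vs fecal calprotectin: rho = {rho.rho:.2f} "
      f"(p = {rho.p:.2g}, n = {rho.n})")
```

prints

```
Moderated t-test: active vs inactive endoscopic Mayo subscore
  probes tested:        5000
  active / inactive n:  84 / 44
  residual df per probe: 126
  prior df d0:          4.044
  prior variance s0^2:  1.01
  probes at FDR < 0.05: 200
  probes at p < 0.05:   449

Mayo_Prob_1: 10-fold cross-validated median ensemble (12 learners)
  samples: 128 {'active': 84, 'inactive': 44}
  pooled out-of-fold AUC: 0.967
  mean ensemble score (active / inactive): 0.916 / 0.146

MCalpro vs fecal calprotectin: rho = 0.91 (p = 4.7e-42, n = 108)
```

The moderated-t fit recovers the generator's variance prior (d₀ ≈ 4,
s₀² ≈ 1), FDR < 0.05 picks out essentially the 200 planted probe sets, the
cross-validated ensemble separates active from inactive mucosa (AUC 0.97 on
this synthetic cohort), and the tissue calprotectin score tracks the
simulated stool measurement.

The same workflow runs from the shell:

```bash
ucscore run-all --outdir out --seed 42          # simulate + all stages
ucscore de --config my_config.json              # one stage, cached inputs
```

writing `de_table.csv`, `volcano.csv`, `cv_scores_Mayo_Prob_{1,2}.csv`,
`set_scores.csv`, `enrichment.csv`, the outcome tables, and `report.json`.

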