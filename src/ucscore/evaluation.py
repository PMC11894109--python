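"""Simulation-based validation experiments for the whole workflow.

Each function regenerates its inputs from a seed, runs the relevant part of
the package, and returns the measured quantity: leakage guards (null-cohort
ensemble AUC), power at the planted operating point, estimator calibration
(moderated-t null p fraction, LRT type-I error), agreement gaps against
independent oracles (BH vs statsmodels, hypergeometric vs Fisher exact),
set-score calibration, end-to-end determinism, and the qualitative
importance structure.  Problem sizes are scaled to a 5,000-probe array with
the emulated cohort's sample counts.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from . import outcomes
from .classify import ActivityClassifier
from .data import ClassLabels, apply_kit_correction, define_activity_classes
from .de import benjamini_hochberg, fit_moderated_t
from .enrichment import GeneSetCollection, ora_test
from .pipeline import PipelineConfig, run_pipeline
from .setscores import TranscriptSet, mcalpro, standardize_to_controls, transcript_set_score
from .synthetic import CohortConfig, generate_cohort

#: cohort scale used throughout: 140 biopsies (127 UC + 13 IBDU), 5,000 probes
N_UC, N_IBDU, N_PROBES, N_SIGNAL = 127, 13, 5000, 200


def _cohort(seed: int, effect_size: float) -> CohortConfig:
    return CohortConfig(n_uc_biopsies=N_UC, n_ibdu_biopsies=N_IBDU,
                        n_probesets=N_PROBES, n_signal_probesets=N_SIGNAL,
                        effect_size=effect_size, seed=seed)


def _cv_on_cohort(config: CohortConfig, k: int = 10):
    bundle, truth = generate_cohort(config)
    matrix = apply_kit_correction(bundle.matrix, bundle.samples)
    classes = define_activity_classes(bundle.samples, include_ibdu=True)
    cv = ActivityClassifier(matrix, classes).cross_validate(k=k, seed=config.seed)
    return cv, truth


def null_ensemble_auc(seed: int, n_seeds: int = 10) -> dict:
    """Full 10-fold ensemble pipeline on signal-free cohorts.

    With fold-internal feature selection and no planted signal the pooled
    out-of-fold AUC should hover around 0.5; systematic departure indicates
    selection-bias leakage.
    """
    aucs = []
    for i in range(n_seeds):
        cv, _ = _cv_on_cohort(_cohort(seed + i, effect_size=0.0))
        aucs.append(cv.auc)
    return {"mean_auc": float(np.mean(aucs)), "aucs": aucs,
            "n": n_seeds * (N_UC + N_IBDU)}


def power_ensemble_auc(seed: int) -> dict:
    """Planted operating point: 200/5,000 probes at 1 log2-unit per unit
    severity, 140 biopsies; returns the pooled out-of-fold AUC and the
    per-fold precision of the selected top-20 lists against the truth."""
    cv, truth = _cv_on_cohort(_cohort(seed, effect_size=1.0))
    planted = set(truth.signal_probesets)
    precisions = [float(np.mean([f in planted for f in feats]))
                  for feats in cv.fold_features.values()]
    return {"auc": cv.auc, "fold_precisions": precisions,
            "min_precision": float(min(precisions)),
            "mean_precision": float(np.mean(precisions)),
            "n": N_UC + N_IBDU}


def moderated_t_equal_variance_gap(seed: int, n_probes: int = 2000) -> dict:
    """Max relative gap between the moderated t and the ordinary pooled t
    when every probe shares the same sample variance."""
    rng = np.random.default_rng(seed)
    n1 = n2 = 10
    pattern = rng.normal(0, 1, size=n1 + n2)
    means = rng.uniform(4, 12, size=n_probes)
    shifts = rng.uniform(-2, 2, size=n_probes)
    values = means[:, None] + pattern[None, :]
    values[:, :n1] += shifts[:, None]
    ids = [f"A{i}" for i in range(n1)] + [f"I{i}" for i in range(n2)]
    matrix = pd.DataFrame(values, index=[f"P{i}" for i in range(n_probes)], columns=ids)
    labels = pd.Series(["active"] * n1 + ["inactive"] * n2, index=ids)
    res = fit_moderated_t(matrix, ClassLabels(labels=labels))
    t_ref = stats.ttest_ind(values[:, :n1], values[:, n1:], axis=1, equal_var=True).statistic
    gap = np.abs(res.table["t_moderated"].to_numpy() - t_ref) / np.abs(t_ref)
    return {"max_rel_gap": float(np.max(gap)), "n": n_probes}


def null_p_calibration(seed: int) -> dict:
    """Fraction of moderated-t p-values below 0.05 on a signal-free cohort."""
    config = _cohort(seed, effect_size=0.0)
    bundle, _ = generate_cohort(config)
    matrix = apply_kit_correction(bundle.matrix, bundle.samples)
    classes = define_activity_classes(bundle.samples, include_ibdu=True)
    res = fit_moderated_t(matrix, classes)
    return {"fraction_p_lt_05": float((res.table["p_unadjusted"] < 0.05).mean()),
            "n": N_PROBES}


def bh_oracle_gap(seed: int, n_vectors: int = 1000) -> dict:
    """Max absolute disagreement with statsmodels' BH on random p-vectors."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_vectors):
        p = rng.random(int(rng.integers(1, 80)))
        gap = np.max(np.abs(benjamini_hochberg(p) - multipletests(p, method="fdr_bh")[1]))
        worst = max(worst, float(gap))
    return {"max_abs_gap": worst, "n": n_vectors}


def ora_fisher_gap(seed: int, n_configs: int = 500) -> dict:
    """Max absolute gap between the hypergeometric tail and one-sided Fisher
    exact p over random (N, K, n, k) configurations."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_configs):
        N = int(rng.integers(10, 300))
        K = int(rng.integers(1, N))
        n = int(rng.integers(1, N))
        k = int(rng.integers(max(0, K + n - N), min(K, n) + 1))
        universe = [f"g{i}" for i in range(N)]
        coll = GeneSetCollection(sets={"S": set(universe[:K])}, universe=set(universe))
        query = universe[:k] + universe[K:K + (n - k)]
        p_mine = ora_test(query, coll).at[0, "p"]
        _, p_fisher = fisher_exact([[k, n - k], [K - k, N - K - (n - k)]],
                                   alternative="greater")
        worst = max(worst, abs(float(p_mine) - float(p_fisher)))
    return {"max_abs_gap": worst, "n": n_configs}


def ora_worked_example() -> dict:
    """The enumerable case N=10, K=5, n=4, k=4: p = 5/210."""
    universe = {f"g{i}" for i in range(10)}
    coll = GeneSetCollection(sets={"S": {f"g{i}" for i in range(5)}}, universe=universe)
    p = ora_test([f"g{i}" for i in range(4)], coll).at[0, "p"]
    return {"p": float(p), "expected": 5 / 210, "n": 10}


def mcalpro_calibration(seed: int) -> dict:
    """Set-score calibration: control geometric mean of MCalpro, the
    single-probe identity, and the 4x/9x composition example."""
    config = CohortConfig(n_uc_biopsies=40, n_ibdu_biopsies=0, n_controls=17,
                          n_probesets=200, n_signal_probesets=20, seed=seed)
    bundle, truth = generate_cohort(config)
    scores = mcalpro(bundle.matrix, bundle.control_ids, bundle.annotation)
    control_geomean = float(np.exp(np.log(scores.loc[bundle.control_ids]).mean()))

    std = standardize_to_controls(bundle.matrix, bundle.control_ids)
    solo = transcript_set_score(std, TranscriptSet("solo", [truth.s100a8_probe]))
    identity_gap = float(np.max(np.abs(solo - std.loc[truth.s100a8_probe])))

    pair = pd.DataFrame([[4.0], [9.0]], index=["a", "b"], columns=["s"])
    composed = float(transcript_set_score(pair, TranscriptSet("pair", ["a", "b"]))["s"])
    return {"control_geomean": control_geomean, "identity_gap": identity_gap,
            "composition_example": composed, "n": config.n_controls}


def lrt_type1_error(seed: int, n_sims: int = 1000, n: int = 140) -> dict:
    """Type-I error of the LRT when the full model adds 3 noise covariates."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_sims):
        x = rng.normal(size=n)
        y = (rng.random(n) < expit(-0.5 + 0.8 * x)).astype(float)
        noise = rng.normal(size=(n, 3))
        table = pd.DataFrame({"x": x, "z1": noise[:, 0], "z2": noise[:, 1],
                              "z3": noise[:, 2], "outcome": y})
        comp = outcomes.likelihood_ratio_compare(table, ["x"], ["x", "z1", "z2", "z3"])
        rejections += comp.p < 0.05
    return {"type1_error": rejections / n_sims, "n": n_sims}


def determinism_check(seed: int, workdir) -> dict:
    """Two pipeline runs with one config: are all CSV artifacts identical?"""
    workdir = Path(workdir)
    sim = CohortConfig(n_uc_biopsies=60, n_ibdu_biopsies=8, n_controls=10,
                       n_probesets=400, n_signal_probesets=40, seed=seed)
    dirs = []
    for name in ("run_a", "run_b"):
        outdir = workdir / name
        config = PipelineConfig(outdir=str(outdir), simulate=sim, k_folds=5, seed=seed,
                                importance_trees=80, importance_permutations=8)
        run_pipeline(config)
        dirs.append(outdir)
    csvs = sorted(p.name for p in dirs[0].glob("*.csv"))
    identical = all(
        (dirs[0] / name).read_bytes() == (dirs[1] / name).read_bytes() for name in csvs
    )
    return {"identical": bool(identical), "n": len(csvs)}


def importance_structure(seed: int) -> dict:
    """Default-generator outcome prediction: is the top permutation-importance
    variable a molecular feature (MCalpro or an ensemble score)?"""
    config = CohortConfig(seed=seed)
    bundle, _ = generate_cohort(config)
    matrix = apply_kit_correction(bundle.matrix, bundle.samples)
    cvs = {}
    for include_ibdu in (False, True):
        classes = define_activity_classes(bundle.samples, include_ibdu=include_ibdu)
        cvs[classes.cohort_tag] = ActivityClassifier(matrix, classes).cross_validate(
            k=10, seed=seed)
    mc = mcalpro(matrix, bundle.control_ids, bundle.annotation)
    predictors = outcomes.build_predictor_table(
        bundle.samples,
        mayo_prob_1=cvs["Mayo_Prob_1"].scores["ensemble"],
        mayo_prob_2=cvs["Mayo_Prob_2"].scores["ensemble"],
        mcalpro=mc,
    )
    table = outcomes.permutation_importance(
        predictors,
        variables=["MCalpro", "Mayo_Prob_1", "Mayo_Prob_2", "endoscopic_mayo",
                   "partial_mayo", "total_mayo", "fecal_calprotectin"],
        n_trees=500, n_permutations=50, seed=seed,
    )
    molecular = set(outcomes.MOLECULAR_PREDICTORS)
    top_is_molecular = table.iloc[0]["variable"] in molecular
    max_molecular = float(table[table["variable"].isin(molecular)]["importance"].max())
    max_clinical = float(table[~table["variable"].isin(molecular)]["importance"].max())
    return {
        "top_is_molecular": bool(top_is_molecular),
        "max_molecular_importance": max_molecular,
        "max_clinical_importance": max_clinical,
        "ranking": table["variable"].tolist(),
        "auc": {tag: cv.auc for tag, cv in cvs.items()},
        "auc_n": {tag: len(cv.scores) for tag, cv in cvs.items()},
        "n": int(table["n"].iloc[0]),
    }
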