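"""Outcome battery: correlations, Welch, AUC, logistic screens, LRT, forest."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit
from sklearn.metrics import roc_auc_score

from ucscore.outcomes import (
    auc_mann_whitney,
    build_predictor_table,
    correlation_table,
    group_test_table,
    likelihood_ratio_compare,
    permutation_importance,
    single_predictor_screen,
    spearman,
    welch_test,
)


# --- spearman ----------------------------------------------------------------

def test_spearman_perfect_monotone():
    x = np.array([1.0, 2, 3, 7, 9])
    assert spearman(x, np.exp(x)).rho == pytest.approx(1.0)
    assert spearman(x, -(x**3)).rho == pytest.approx(-1.0)


def test_spearman_ties_match_midrank_pearson_oracle():
    x = np.array([1.0, 2, 3, 4])
    y = np.array([1.0, 1, 3, 4])
    res = spearman(x, y)
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    expected = np.corrcoef(rx, ry)[0, 1]
    assert res.rho == pytest.approx(expected, rel=1e-12)
    # p from the t-approximation with n - 2 df
    t = expected * np.sqrt((4 - 2) / (1 - expected**2))
    assert res.p == pytest.approx(2 * stats.t.sf(abs(t), df=2), rel=1e-9)


def test_spearman_constant_vector_is_undefined_not_zero():
    res = spearman([1.0, 1, 1, 1], [1.0, 2, 3, 4])
    assert res.undefined and np.isnan(res.rho)


def test_spearman_self_correlation_is_one():
    rng = np.random.default_rng(0)
    x = rng.normal(size=30)
    assert spearman(x, x).rho == pytest.approx(1.0)


def test_spearman_needs_four_complete_pairs():
    with pytest.raises(ValueError):
        spearman([1, 2, np.nan, np.nan], [1, 2, 3, 4])


# --- welch -------------------------------------------------------------------

def test_welch_closed_form_equal_variances():
    t, df, p = welch_test([1, 2, 3], [4, 5, 6])
    assert t == pytest.approx(-3.0 / np.sqrt(2.0 / 3.0), rel=1e-12)
    assert df == pytest.approx(4.0)
    assert p == pytest.approx(2 * stats.t.sf(3.0 / np.sqrt(2 / 3), 4), rel=1e-9)


def test_welch_identical_groups():
    t, _, p = welch_test([2.0, 3, 4], [2.0, 3, 4])
    assert t == 0.0 and p == 1.0


def test_welch_antisymmetric_in_group_order():
    rng = np.random.default_rng(1)
    a, b = rng.normal(0, 1, 10), rng.normal(1, 2, 12)
    t1, df1, p1 = welch_test(a, b)
    t2, df2, p2 = welch_test(b, a)
    assert t1 == pytest.approx(-t2) and df1 == pytest.approx(df2) and p1 == pytest.approx(p2)


def test_welch_matches_scipy():
    rng = np.random.default_rng(2)
    a, b = rng.normal(0, 1, 9), rng.normal(0.5, 3, 14)
    t, df, p = welch_test(a, b)
    ref = stats.ttest_ind(a, b, equal_var=False)
    assert t == pytest.approx(ref.statistic, rel=1e-12)
    assert p == pytest.approx(ref.pvalue, rel=1e-12)


# --- AUC -----------------------------------------------------------------------

def test_auc_trivial_cases():
    assert auc_mann_whitney([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0
    assert auc_mann_whitney([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5
    with pytest.raises(ValueError):
        auc_mann_whitney([0.1, 0.2], [1, 1])


def test_auc_invariant_under_monotone_transform_and_matches_sklearn():
    rng = np.random.default_rng(3)
    scores = rng.normal(size=200)
    y = (rng.random(200) < expit(scores)).astype(int)
    direct = auc_mann_whitney(scores, y)
    assert auc_mann_whitney(np.exp(scores), y) == pytest.approx(direct, rel=1e-14)
    assert direct == pytest.approx(roc_auc_score(y, scores), rel=1e-12)


def test_auc_null_mean_is_half():
    rng = np.random.default_rng(4)
    y = np.array([1] * 15 + [0] * 15)
    aucs = [auc_mann_whitney(rng.normal(size=30), y) for _ in range(2000)]
    assert np.mean(aucs) == pytest.approx(0.5, abs=0.02)


# --- predictor table and screens -----------------------------------------------

def _predictors(n=200, signal=1.5, seed=0):
    rng = np.random.default_rng(seed)
    sev = rng.normal(size=n)
    y = (rng.random(n) < expit(signal * sev)).astype(float)
    return pd.DataFrame({
        "good": sev + rng.normal(0, 0.3, n),
        "noise": rng.normal(size=n),
        "outcome": y,
    })


def test_screen_signal_and_null_predictors():
    table = single_predictor_screen(_predictors())
    rows = table.set_index("predictor")
    assert rows.at["good", "auc"] > 0.75
    assert rows.at["good", "p"] < 1e-6
    assert 0.35 < rows.at["noise", "auc"] < 0.65
    assert rows.at["noise", "p"] > 0.01


def test_screen_near_copy_of_outcome_flags_separation():
    df = _predictors(n=100)
    df["copy"] = df["outcome"] + np.random.default_rng(1).normal(0, 1e-4, 100)
    table = single_predictor_screen(df, variables=["copy"]).iloc[0]
    assert table["auc"] >= 0.95
    assert table["separation"] or table["p"] < 1e-6


def test_screen_constant_predictor_is_undefined():
    df = _predictors(n=60)
    df["flat"] = 3.0
    row = single_predictor_screen(df, variables=["flat"]).iloc[0]
    assert row["undefined"] and np.isnan(row["p"])


def test_null_screen_p_values_are_roughly_uniform():
    rng = np.random.default_rng(7)
    ps = []
    for i in range(200):
        df = pd.DataFrame({"x": rng.normal(size=150),
                           "outcome": rng.integers(0, 2, 150).astype(float)})
        ps.append(single_predictor_screen(df).at[0, "p"])
    assert np.mean(ps) == pytest.approx(0.5, abs=0.08)
    assert np.mean(np.array(ps) < 0.05) == pytest.approx(0.05, abs=0.05)


def test_build_predictor_table_outcome_dichotomy():
    samples = pd.DataFrame({
        "diagnosis": ["UC", "UC", "UC", "control"],
        "endoscopic_mayo": [0, 2, 3, np.nan],
        "partial_mayo": [1, 5, 8, np.nan],
        "total_mayo": [1, 7, 11, np.nan],
        "pga": [0, 2, 3, np.nan],
        "fecal_calprotectin": [50, 800, np.nan, np.nan],
        "status_code": [0, 2, np.nan, np.nan],
    }, index=["s1", "s2", "s3", "c1"])
    table = build_predictor_table(samples)
    assert list(table.index) == ["s1", "s2", "s3"]
    assert table["outcome"].tolist()[:2] == [0.0, 1.0]
    assert np.isnan(table.at["s3", "outcome"])


# --- LRT -----------------------------------------------------------------------

def test_lrt_exact_copy_adds_nothing():
    df = _predictors(n=150)
    df["copy_of_good"] = df["good"]
    comp = likelihood_ratio_compare(df, ["good"], ["good", "copy_of_good"])
    assert comp.df == 0 and comp.lrt == pytest.approx(0.0, abs=1e-6) and comp.p == 1.0


def test_lrt_true_signal_detected():
    df = _predictors(n=300, signal=1.5, seed=5)
    comp = likelihood_ratio_compare(df, ["noise"], ["noise", "good"])
    assert comp.df == 1 and comp.p < 1e-6
    assert comp.auc_full > comp.auc_reduced
    assert comp.lrt >= 0


def test_lrt_requires_nesting():
    df = _predictors(n=100)
    with pytest.raises(ValueError, match="subset"):
        likelihood_ratio_compare(df, ["good"], ["noise"])


# --- permutation importance ------------------------------------------------------

def test_importance_outcome_duplicate_dominates_and_noise_is_null():
    rng = np.random.default_rng(11)
    n = 120
    y = rng.integers(0, 2, n).astype(float)
    df = pd.DataFrame({
        "oracle": y + rng.normal(0, 0.01, n),
        "noise_a": rng.normal(size=n),
        "noise_b": rng.normal(size=n),
        "outcome": y,
    })
    imp = permutation_importance(df, n_trees=150, n_permutations=20, seed=0)
    assert imp.iloc[0]["variable"] == "oracle"
    for _, row in imp[imp["variable"] != "oracle"].iterrows():
        assert abs(row["importance"]) < 2 * row["importance_sd"] + 1e-9


def test_importance_invariant_to_column_order():
    df = _predictors(n=80, seed=3)
    df["extra"] = np.random.default_rng(4).normal(size=80)
    a = permutation_importance(df[["good", "noise", "extra", "outcome"]],
                               n_trees=60, n_permutations=10, seed=5)
    b = permutation_importance(df[["extra", "outcome", "noise", "good"]],
                               n_trees=60, n_permutations=10, seed=5)
    pd.testing.assert_frame_equal(a, b)


def test_importance_refuses_sparse_complete_cases():
    df = _predictors(n=15)
    with pytest.raises(ValueError, match="complete cases"):
        permutation_importance(df, n_trees=10, n_permutations=5, seed=0)


# --- table builders -----------------------------------------------------------

def test_correlation_and_group_tables_shapes():
    rng = np.random.default_rng(9)
    n = 80
    sev = rng.normal(1.5, 1, n)
    samples = pd.DataFrame({
        "diagnosis": ["UC"] * n,
        "endoscopic_mayo": np.clip(np.round(sev), 0, 3),
        "partial_mayo": np.clip(np.round(2 * sev + rng.normal(0, 1, n)), 0, 9),
        "total_mayo": np.clip(np.round(3 * sev + rng.normal(0, 1, n)), 0, 12),
        "pga": np.clip(np.round(sev), 0, 3),
        "fecal_calprotectin": np.exp(5 + 0.5 * sev + rng.normal(0, 0.4, n)),
        "status_code": rng.integers(0, 4, n).astype(float),
    }, index=[f"s{i}" for i in range(n)])
    scores = pd.Series(expit(sev + rng.normal(0, 0.3, n)), index=samples.index)
    mc = pd.Series(np.exp(0.5 * sev), index=samples.index)
    pred = build_predictor_table(samples, scores, scores, mc)

    corr = correlation_table(pred)
    assert set(corr["score"]) == {"Mayo_Prob_1", "Mayo_Prob_2", "MCalpro"}
    assert len(corr) == 15
    strong = corr[(corr.score == "MCalpro") & (corr.clinical_feature == "endoscopic_mayo")]
    assert strong["rho"].iloc[0] > 0.5

    groups = group_test_table(pred)
    assert {"variable", "mean_good", "mean_poor", "t", "p", "n"} <= set(groups.columns)
    assert len(groups) == len(pred.columns) - 1
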