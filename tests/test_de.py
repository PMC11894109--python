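"""Moderated-t oracle checks, BH step-up, ranking and volcano rules."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from conftest import make_class_labels, make_matrix
from ucscore.data import define_activity_classes
from ucscore.de import (
    benjamini_hochberg,
    fit_moderated_t,
    rank_transcripts,
    trigamma_inverse,
    volcano_table,
)


def test_closed_form_pooled_t_with_zero_prior_df():
    """One probe, active {4,5,6} vs inactive {1,2,3}, d0 forced to 0:
    t = 3 / sqrt(1 * (1/3 + 1/3)) = 3.674, df = 4."""
    m = make_matrix([[4, 5, 6, 1, 2, 3]], probe_ids=["p"],
                    sample_ids=["A0", "A1", "A2", "I0", "I1", "I2"])
    classes = make_class_labels(3, 3)
    res = fit_moderated_t(m, classes, prior_df=0.0)
    expected_t = 3.0 / np.sqrt(2.0 / 3.0)
    assert res.table.at["p", "t_moderated"] == pytest.approx(expected_t, rel=1e-9)
    expected_p = 2 * stats.t.sf(expected_t, df=4)
    assert res.table.at["p", "p_unadjusted"] == pytest.approx(expected_p, rel=1e-9)


def test_equal_variances_collapse_to_ordinary_pooled_t():
    """When every probe has the same sample variance the estimated prior is a
    point mass at that variance and t_moderated equals the ordinary pooled t."""
    rng = np.random.default_rng(0)
    pattern = rng.normal(0, 1, size=10)  # identical within-probe pattern
    means = rng.uniform(4, 12, size=50)
    values = means[:, None] + pattern[None, :]
    values[:25, :5] += rng.uniform(0.5, 2.0, size=(25, 1))  # shift means only
    m = make_matrix(values, sample_ids=[f"A{i}" for i in range(5)] + [f"I{i}" for i in range(5)])
    classes = make_class_labels(5, 5)
    res = fit_moderated_t(m, classes)
    a, i = values[:, :5], values[:, 5:]
    t_ref = stats.ttest_ind(a, i, axis=1, equal_var=True).statistic
    np.testing.assert_allclose(res.table["t_moderated"].to_numpy(), t_ref, rtol=1e-6)


def test_forced_prior_at_sample_variance_collapses_posterior():
    """With s0^2 = s^2 the posterior variance is s^2 for any prior df."""
    m = make_matrix([[4.0, 5, 6, 1, 2, 3]], probe_ids=["p"],
                    sample_ids=["A0", "A1", "A2", "I0", "I1", "I2"])
    classes = make_class_labels(3, 3)
    t_vals = [fit_moderated_t(m, classes, prior_df=d0, prior_var=1.0).table.at["p", "t_moderated"]
              for d0 in (0.0, 2.0, 10.0, 1000.0)]
    np.testing.assert_allclose(t_vals, 3.0 / np.sqrt(2.0 / 3.0), rtol=1e-9)


def test_flat_probe_flagged_with_unit_p():
    m = make_matrix([[5.0] * 6, [4, 5, 6, 1, 2, 3]], probe_ids=["flat", "sig"],
                    sample_ids=["A0", "A1", "A2", "I0", "I1", "I2"])
    classes = make_class_labels(3, 3)
    res = fit_moderated_t(m, classes)
    assert res.table.at["flat", "t_moderated"] == 0.0
    assert res.table.at["flat", "p_unadjusted"] == 1.0
    assert res.table.at["flat", "log2_fold_change"] == 0.0
    assert bool(res.table.at["flat", "zero_variance"])


def test_moderation_shrinks_t_variance_on_null_data():
    rng = np.random.default_rng(5)
    sd = np.sqrt(4 / rng.chisquare(4, size=3000))
    values = 8 + rng.normal(0, 1, size=(3000, 16)) * sd[:, None]
    m = make_matrix(values, sample_ids=[f"A{i}" for i in range(8)] + [f"I{i}" for i in range(8)])
    classes = make_class_labels(8, 8)
    res = fit_moderated_t(m, classes)
    assert res.params.prior_df > 0
    t_ord = stats.ttest_ind(values[:, :8], values[:, 8:], axis=1, equal_var=True).statistic
    assert np.var(res.table["t_moderated"]) < np.var(t_ord)


def test_group_means_are_linear_scale_geometric_means(small_cohort):
    _, bundle, _ = small_cohort
    classes = define_activity_classes(bundle.samples, include_ibdu=True)
    res = fit_moderated_t(bundle.matrix, classes, control_ids=bundle.control_ids)
    expected = 2.0 ** bundle.matrix[classes.active_ids].mean(axis=1)
    np.testing.assert_allclose(res.table["mean_active"], expected, rtol=1e-12)
    ctrl = 2.0 ** bundle.matrix[bundle.control_ids].mean(axis=1)
    np.testing.assert_allclose(res.table["mean_control"], ctrl, rtol=1e-12)
    np.testing.assert_allclose(
        res.table["log2_fold_change"],
        np.log2(res.table["mean_active"]) - np.log2(res.table["mean_inactive"]),
        atol=1e-9,
    )


def test_fdr_never_below_unadjusted_p(small_cohort):
    _, bundle, _ = small_cohort
    classes = define_activity_classes(bundle.samples, include_ibdu=True)
    res = fit_moderated_t(bundle.matrix, classes)
    assert (res.table["p_fdr"] >= res.table["p_unadjusted"] - 1e-15).all()


def test_moderated_t_matches_limma(tmp_path):
    """Independent oracle: R/limma lmFit + eBayes on a small fixture must
    agree with our estimator on t, p, and both hyperparameters."""
    rng = np.random.default_rng(42)
    p, n1, n2 = 60, 7, 9
    sd = np.sqrt(4 / rng.chisquare(4, p))
    values = rng.normal(8, 1, size=(p, 1)) + rng.normal(0, 1, size=(p, n1 + n2)) * sd[:, None]
    values[:10, :n1] += 1.5
    sample_ids = [f"A{i}" for i in range(n1)] + [f"I{i}" for i in range(n2)]
    m = make_matrix(values, sample_ids=sample_ids)
    m.rename_axis("probe_id").to_csv(tmp_path / "mat.tsv", sep="\t")
    script = textwrap.dedent(f"""
        suppressMessages(library(limma))
        x <- as.matrix(read.delim("{tmp_path}/mat.tsv", row.names=1))
        design <- cbind(Intercept=1, Active=c(rep(1,{n1}), rep(0,{n2})))
        fit <- eBayes(lmFit(x, design))
        out <- data.frame(t=fit$t[,"Active"], p=fit$p.value[,"Active"])
        write.csv(out, "{tmp_path}/limma_out.csv")
        cat(fit$df.prior, fit$s2.prior, sep="\\n")
    """)
    (tmp_path / "oracle.R").write_text(script)
    proc = subprocess.run(["Rscript", str(tmp_path / "oracle.R")],
                          capture_output=True, text=True, check=True)
    d0_ref, s20_ref = map(float, proc.stdout.split())

    res = fit_moderated_t(m, make_class_labels(n1, n2))
    ref = pd.read_csv(tmp_path / "limma_out.csv", index_col=0)
    assert res.params.prior_df == pytest.approx(d0_ref, rel=1e-6)
    assert res.params.prior_var == pytest.approx(s20_ref, rel=1e-6)
    np.testing.assert_allclose(res.table["t_moderated"], ref["t"], rtol=1e-8)
    np.testing.assert_allclose(res.table["p_unadjusted"], ref["p"], rtol=1e-8)


def test_trigamma_inverse_round_trip():
    from scipy.special import polygamma
    for x in (0.01, 0.5, 2.0, 50.0, 1e4):
        y = float(polygamma(1, x))
        assert trigamma_inverse(y) == pytest.approx(x, rel=1e-6)


# --- Benjamini-Hochberg -----------------------------------------------------

def _bh_oracle(p):
    """Brute-force step-up: for each i, min over j with p_(j) >= p_(i) of
    min(1, m p_(j) / j)."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj_sorted = np.empty(m)
    running = np.inf
    for pos in range(m - 1, -1, -1):
        running = min(running, p[order[pos]] * m / (pos + 1))
        adj_sorted[pos] = min(1.0, running)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def test_bh_hand_examples():
    np.testing.assert_allclose(benjamini_hochberg([0.01, 0.02, 0.03, 0.04]),
                               [0.04, 0.04, 0.04, 0.04])
    np.testing.assert_allclose(benjamini_hochberg([0.2]), [0.2])


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        benjamini_hochberg([0.5, 1.2])
    with pytest.raises(ValueError):
        benjamini_hochberg([-0.1])


def test_bh_matches_independent_oracles_on_random_vectors():
    rng = np.random.default_rng(123)
    for _ in range(200):
        p = rng.random(int(rng.integers(1, 60)))
        mine = benjamini_hochberg(p)
        np.testing.assert_array_equal(mine, _bh_oracle(p))
        sm_ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(mine, sm_ref, atol=1e-12)


@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
def test_bh_is_monotone_and_bounded(p):
    adj = benjamini_hochberg(p)
    assert np.all(adj <= 1.0) and np.all(adj >= np.asarray(p) - 1e-12)
    order = np.argsort(p, kind="mergesort")
    assert np.all(np.diff(adj[order]) >= -1e-15)


# --- ranking and volcano ----------------------------------------------------

def _de_table(rows):
    table = pd.DataFrame(rows).set_index("probe_id")
    table["p_fdr"] = benjamini_hochberg(table["p_unadjusted"].to_numpy())
    return table


def test_rank_collapse_keeps_best_probe_per_gene():
    table = _de_table([
        dict(probe_id="a", log2_fold_change=1.0, p_unadjusted=1e-8, gene_symbol="G1"),
        dict(probe_id="b", log2_fold_change=0.8, p_unadjusted=1e-5, gene_symbol="G1"),
        dict(probe_id="c", log2_fold_change=0.5, p_unadjusted=1e-3, gene_symbol="G2"),
    ])
    top = rank_transcripts(table, "increased", k=5, collapse_to_genes=True)
    assert list(top.index) == ["a", "c"]


def test_rank_ties_break_on_fold_change_then_probe_id():
    table = _de_table([
        dict(probe_id="b", log2_fold_change=1.5, p_unadjusted=0.01, gene_symbol=""),
        dict(probe_id="a", log2_fold_change=2.0, p_unadjusted=0.01, gene_symbol=""),
        dict(probe_id="c", log2_fold_change=2.0, p_unadjusted=0.01, gene_symbol=""),
    ])
    top = rank_transcripts(table, "increased", k=3)
    assert list(top.index) == ["a", "c", "b"]


def test_rank_direction_filters_by_sign():
    table = _de_table([
        dict(probe_id="up", log2_fold_change=1.0, p_unadjusted=0.001, gene_symbol=""),
        dict(probe_id="dn", log2_fold_change=-1.0, p_unadjusted=0.0001, gene_symbol=""),
    ])
    assert list(rank_transcripts(table, "increased", 5).index) == ["up"]
    assert list(rank_transcripts(table, "decreased", 5).index) == ["dn"]
    with pytest.raises(ValueError):
        rank_transcripts(table, "increased", 0)


def test_volcano_coordinates_flags_and_fdr_line():
    table = _de_table([
        dict(probe_id="a", log2_fold_change=2.0, p_unadjusted=0.01, gene_symbol="G"),
        dict(probe_id="b", log2_fold_change=-1.0, p_unadjusted=0.5, gene_symbol="H"),
    ])
    table["p_fdr"] = [0.02, 0.5]
    annotation = pd.DataFrame({"gene_symbol": ["G", "H"], "flags": ["calprotectin", ""]},
                              index=pd.Index(["a", "b"], name="probe_id"))
    v = volcano_table(table, annotation)
    assert v.at["a", "neg_log10_p"] == pytest.approx(2.0)
    assert v.at["a", "flags"] == "calprotectin"
    assert bool(v.at["a", "fdr_line"]) and not bool(v.at["b", "fdr_line"])


def test_volcano_fdr_line_absent_when_nothing_significant():
    table = _de_table([
        dict(probe_id="a", log2_fold_change=1.0, p_unadjusted=0.4, gene_symbol=""),
        dict(probe_id="b", log2_fold_change=-2.0, p_unadjusted=0.6, gene_symbol=""),
    ])
    v = volcano_table(table)
    assert not v["fdr_line"].any()


def test_top_list_precision_against_planted_truth(corrected_planted):
    matrix, bundle, truth = corrected_planted
    classes = define_activity_classes(bundle.samples, include_ibdu=False)
    res = fit_moderated_t(matrix, classes, annotation=bundle.annotation)
    top = res.top("increased", k=30)
    planted = set(truth.signal_probesets)
    precision = np.mean([p in planted for p in top.index])
    assert precision >= 0.9
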