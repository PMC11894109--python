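"""Clinical outcome association battery.

Spearman correlations of molecular scores against clinical features, Welch
tests against the 3-6-month status code dichotomy (poor outcome = status
code > 1), rank-based AUC, univariate logistic screens, nested-model
likelihood-ratio comparisons, and random-forest permutation importance with
out-of-bag AUC decrease.

Every statistic runs on complete cases for the variables it uses and
reports the n it actually consumed (fecal calprotectin and the status code
are available only for subsets of biopsies).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.tree import DecisionTreeClassifier
import statsmodels.api as sm

MOLECULAR_PREDICTORS = ["Mayo_Prob_1", "Mayo_Prob_2", "MCalpro"]
CLINICAL_PREDICTORS = [
    "endoscopic_mayo",
    "partial_mayo",
    "total_mayo",
    "pga",
    "fecal_calprotectin",
]


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------

@dataclass
class SpearmanResult:
    rho: float
    p: float
    n: int
    undefined: bool = False


def spearman(x, y) -> SpearmanResult:
    """Spearman rank correlation with midranks; p via the t-approximation.

    Constant inputs make the correlation undefined; the result carries an
    explicit marker rather than a silent zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = x.size
    if n < 4:
        raise ValueError(f"need >= 4 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return SpearmanResult(rho=np.nan, p=np.nan, n=n, undefined=True)
    rho, p = stats.spearmanr(x, y)
    return SpearmanResult(rho=float(rho), p=float(p), n=n)


def welch_test(group_a, group_b) -> tuple[float, float, float]:
    """Welch two-sample t: statistic, Satterthwaite df, two-sided p."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        raise ValueError("degenerate variance in both groups")
    sa, sb = va / a.size, vb / b.size
    t = (a.mean() - b.mean()) / np.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa**2 / (a.size - 1) + sb**2 / (b.size - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def auc_mann_whitney(scores, labels) -> float:
    """Rank-based AUC: P(score_pos > score_neg) + 0.5 P(tie), via midranks."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if scores.shape != y.shape:
        raise ValueError("scores and labels must align")
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute an AUC")
    ranks = stats.rankdata(scores)
    rank_sum_pos = ranks[y == 1].sum()
    return float((rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# predictor table assembly
# ---------------------------------------------------------------------------

def build_predictor_table(samples: pd.DataFrame,
                          mayo_prob_1: pd.Series | None = None,
                          mayo_prob_2: pd.Series | None = None,
                          mcalpro: pd.Series | None = None,
                          status_threshold: float = 1.0) -> pd.DataFrame:
    """Join molecular scores onto the clinical covariates per biopsy.

    The binary ``outcome`` column is 1 where status code > threshold and NaN
    where no follow-up status exists; controls are excluded.
    """
    biopsies = samples[samples["diagnosis"] != "control"]
    table = biopsies[CLINICAL_PREDICTORS + ["status_code"]].astype(float).copy()
    for name, series in (("Mayo_Prob_1", mayo_prob_1), ("Mayo_Prob_2", mayo_prob_2),
                         ("MCalpro", mcalpro)):
        if series is not None:
            table[name] = series.reindex(table.index)
    table["outcome"] = np.where(
        table["status_code"].isna(), np.nan,
        (table["status_code"] > status_threshold).astype(float),
    )
    return table.drop(columns="status_code")


def correlation_table(predictors: pd.DataFrame,
                      score_cols=MOLECULAR_PREDICTORS,
                      clinical_cols=CLINICAL_PREDICTORS) -> pd.DataFrame:
    """Spearman rho/p of each molecular score against each clinical feature."""
    rows = []
    for score in score_cols:
        if score not in predictors.columns:
            continue
        for feature in clinical_cols:
            res = spearman(predictors[score], predictors[feature])
            rows.append({"score": score, "clinical_feature": feature,
                         "rho": res.rho, "p": res.p, "n": res.n,
                         "undefined": res.undefined})
    return pd.DataFrame(rows)


def group_test_table(predictors: pd.DataFrame, variables=None) -> pd.DataFrame:
    """Welch tests of each variable between poor and good future status."""
    if variables is None:
        variables = [c for c in predictors.columns if c != "outcome"]
    out = predictors["outcome"]
    rows = []
    for var in variables:
        x = predictors[var]
        mask = x.notna() & out.notna()
        good = x[mask & (out == 0)]
        poor = x[mask & (out == 1)]
        t, df, p = welch_test(good, poor)
        rows.append({"variable": var, "mean_good": good.mean(), "mean_poor": poor.mean(),
                     "t": t, "df": df, "p": p, "n": int(mask.sum())})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# logistic models
# ---------------------------------------------------------------------------

def _fit_logit(y: np.ndarray, X: np.ndarray):
    """ML logistic fit; returns (params, bse, llf, fitted, converged)."""
    design = sm.add_constant(X, has_constant="add")
    model = sm.Logit(y, design)
    with np.errstate(all="ignore"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = model.fit(disp=0, maxiter=200)
    return fit


def single_predictor_screen(predictors: pd.DataFrame, variables=None) -> pd.DataFrame:
    """Univariate logistic screen of each predictor against the outcome.

    Reports the Wald p of the slope and the AUC of the fitted probabilities
    (identical to the raw predictor's AUC up to monotone transform).
    Perfect separation falls back to a ridge-penalized fit and is flagged;
    constant predictors yield an explicit undefined marker.
    """
    if "outcome" not in predictors.columns:
        raise ValueError("predictor table has no outcome column")
    if variables is None:
        variables = [c for c in predictors.columns if c != "outcome"]
    rows = []
    for var in variables:
        sub = predictors[[var, "outcome"]].dropna()
        y = sub["outcome"].to_numpy()
        x = sub[var].to_numpy()
        row = {"predictor": var, "n": len(sub), "p": np.nan, "auc": np.nan,
               "separation": False, "undefined": False}
        if len(sub) == 0 or np.ptp(x) == 0 or len(np.unique(y)) < 2:
            row["undefined"] = True
            rows.append(row)
            continue
        try:
            fit = _fit_logit(y, x[:, None])
            separated = (not fit.mle_retvals.get("converged", True)) or np.abs(
                fit.params[1]
            ) * np.ptp(x) > 50
        except Exception:
            separated = True
            fit = None
        if separated or fit is None or not np.all(np.isfinite(fit.bse)):
            beta, se, probs = _penalized_logit(y, x[:, None])
            row["separation"] = True
            row["p"] = float(2 * stats.norm.sf(abs(beta[1] / se[1])))
            row["auc"] = auc_mann_whitney(probs, y)
        else:
            row["p"] = float(fit.pvalues[1])
            row["auc"] = auc_mann_whitney(fit.predict(), y)
        rows.append(row)
    return pd.DataFrame(rows)


def _penalized_logit(y, X, c: float = 1.0):
    """Ridge-logistic fallback with Wald SEs from the penalized Hessian."""
    clf = LogisticRegression(C=c, max_iter=5000)
    clf.fit(X, y)
    beta = np.concatenate([clf.intercept_, clf.coef_.ravel()])
    design = np.column_stack([np.ones(len(y)), X])
    probs = clf.predict_proba(X)[:, 1]
    w = probs * (1 - probs)
    hessian = design.T @ (design * w[:, None])
    hessian[1:, 1:] += np.eye(X.shape[1]) / c
    cov = np.linalg.inv(hessian)
    return beta, np.sqrt(np.diag(cov)), probs


@dataclass
class ModelComparison:
    """Nested logistic comparison: LRT statistic, chi-square p, AUCs."""

    reduced: list[str]
    full: list[str]
    llf_reduced: float
    llf_full: float
    lrt: float
    df: int
    p: float
    auc_reduced: float
    auc_full: float
    n: int

    def summary(self) -> str:
        return (
            f"LRT({self.df} df) = {self.lrt:.3f}, p = {self.p:.4g}, n = {self.n}\n"
            f"  reduced [{', '.join(self.reduced)}]: "
            f"logLik {self.llf_reduced:.3f}, AUC {self.auc_reduced:.3f}\n"
            f"  full    [{', '.join(self.full)}]: "
            f"logLik {self.llf_full:.3f}, AUC {self.auc_full:.3f}"
        )


def _independent_columns(X: np.ndarray) -> list[int]:
    """Greedy rank-preserving column subset (constant column implied)."""
    cols: list[int] = []
    base = np.ones((X.shape[0], 1))
    for j in range(X.shape[1]):
        candidate = np.column_stack([base] + [X[:, c][:, None] for c in cols] + [X[:, j][:, None]])
        if np.linalg.matrix_rank(candidate) > 1 + len(cols):
            cols.append(j)
    return cols


def likelihood_ratio_compare(predictors: pd.DataFrame, reduced: list[str],
                             full: list[str]) -> ModelComparison:
    """Compare nested logistic models on shared complete cases.

    Added covariates that are exactly collinear with the reduced design are
    dropped before fitting; the LRT df is the rank difference between the
    two designs, so an added exact copy gives LRT = 0 with p = 1.
    """
    if not set(reduced).issubset(full):
        raise ValueError("reduced covariates must be a subset of the full covariates")
    sub = predictors[sorted(set(full)) + ["outcome"]].dropna()
    y = sub["outcome"].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class on the shared complete cases")

    X_red = sub[reduced].to_numpy(dtype=float)
    X_full = sub[full].to_numpy(dtype=float)
    keep_red = _independent_columns(X_red)
    keep_full = _independent_columns(X_full)
    df = len(keep_full) - len(keep_red)

    fit_red = _fit_logit(y, X_red[:, keep_red])
    fit_full = _fit_logit(y, X_full[:, keep_full])
    for name, fit in (("reduced", fit_red), ("full", fit_full)):
        if not fit.mle_retvals.get("converged", True):
            raise RuntimeError(f"{name} logistic model did not converge: {fit.mle_retvals}")

    lrt = max(0.0, 2.0 * (fit_full.llf - fit_red.llf))
    p = 1.0 if df == 0 else float(stats.chi2.sf(lrt, df))
    return ModelComparison(
        reduced=list(reduced), full=list(full),
        llf_reduced=float(fit_red.llf), llf_full=float(fit_full.llf),
        lrt=float(lrt), df=int(df), p=p,
        auc_reduced=auc_mann_whitney(fit_red.predict(), y),
        auc_full=auc_mann_whitney(fit_full.predict(), y),
        n=len(y),
    )


# ---------------------------------------------------------------------------
# permutation importance
# ---------------------------------------------------------------------------

def permutation_importance(predictors: pd.DataFrame, variables=None,
                           n_trees: int = 500, n_permutations: int = 50,
                           max_features: str = "sqrt", seed: int = 0) -> pd.DataFrame:
    """Random-forest permutation importance by out-of-bag AUC decrease.

    A bagged forest of decision trees is grown on bootstrap resamples; each
    sample's out-of-bag probability is the mean vote of the trees that never
    saw it.  A variable's importance is the mean drop in out-of-bag AUC over
    ``n_permutations`` random permutations of that variable's column.
    AUC-decrease (rather than impurity) keeps mixed-scale clinical and
    molecular predictors comparable.
    """
    if variables is None:
        variables = [c for c in predictors.columns if c != "outcome"]
    if len(variables) < 2:
        raise ValueError("need >= 2 predictors")
    # canonical (sorted) variable order internally, so the caller's column
    # order cannot influence tree construction or the reported ranking
    variables = sorted(map(str, variables))
    sub = predictors[variables + ["outcome"]].dropna()
    if len(sub) < 20:
        raise ValueError(f"need >= 20 complete cases, got {len(sub)}")
    X = sub[variables].to_numpy(dtype=float)
    y = sub["outcome"].to_numpy().astype(int)
    n = len(y)

    # independent, order-invariant streams: one for the forest, one per
    # variable (keyed by sorted position), so permuting the column order of
    # the predictor table cannot change any result
    rng = np.random.default_rng([seed, 0])
    var_order = {v: i for i, v in enumerate(sorted(map(str, variables)))}
    trees, oob_masks = [], []
    for _ in range(n_trees):
        idx = rng.integers(0, n, size=n)
        oob = np.ones(n, dtype=bool)
        oob[idx] = False
        tree = DecisionTreeClassifier(
            max_features=max_features,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(X[idx], y[idx])
        trees.append(tree)
        oob_masks.append(oob)

    def oob_auc(Xq: np.ndarray) -> float:
        prob_sum = np.zeros(n)
        counts = np.zeros(n)
        for tree, oob in zip(trees, oob_masks):
            if not oob.any():
                continue
            probs = tree.predict_proba(Xq[oob])
            pos = probs[:, list(tree.classes_).index(1)] if 1 in tree.classes_ else np.zeros(oob.sum())
            prob_sum[oob] += pos
            counts[oob] += 1
        seen = counts > 0
        return auc_mann_whitney(prob_sum[seen] / counts[seen], y[seen])

    baseline = oob_auc(X)
    rows = []
    for j, var in enumerate(variables):
        var_rng = np.random.default_rng([seed, 1, var_order[str(var)]])
        drops = np.empty(n_permutations)
        for r in range(n_permutations):
            Xp = X.copy()
            Xp[:, j] = X[var_rng.permutation(n), j]
            drops[r] = baseline - oob_auc(Xp)
        rows.append({"variable": var, "importance": drops.mean(),
                     "importance_sd": drops.std(ddof=1), "baseline_oob_auc": baseline,
                     "n": n})
    table = pd.DataFrame(rows).sort_values("importance", ascending=False,
                                           kind="mergesort").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table
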