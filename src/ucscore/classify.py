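"""The Mayo_Prob median-ensemble activity classifiers.

Stratified 10-fold cross-validation with fold-internal feature selection:
inside every fold the top 20 probe sets by two-sample t-test on the
training split alone are fed to a panel of 12 commodity learners, each
emitting a probability of active disease in [0, 1]; the per-sample median
across the panel is the ensemble score.  Out-of-fold ensemble scores are
pooled into a single rank-based AUC.  A final refit on all included samples
produces a deployable model for scoring new biopsies.

The learner panel maps the classical 12-algorithm roster onto scikit-learn
analogues (shrinkage discriminant for regularized DA, a regularized
quadratic discriminant for mixture DA, interaction-expanded logistic
regression for flexible DA, a pruned tree for C5.0, ridge logistic for
Bayesian GLM, elastic-net logistic for glmnet); the roster is a plain list
and can be swapped wholesale.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import joblib
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import PolynomialFeatures, StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .data import ClassLabels
from .outcomes import auc_mann_whitney

logger = logging.getLogger(__name__)

N_SELECTED_FEATURES = 20


@dataclass
class LearnerSpec:
    """One roster entry: a name and a factory building a fresh estimator."""

    name: str
    factory: Callable[[int], object]  # random_state -> unfitted estimator


def default_roster() -> list[LearnerSpec]:
    """The 12-learner panel with fixed, untuned hyperparameters."""
    return [
        LearnerSpec("lda", lambda rs: LinearDiscriminantAnalysis()),
        LearnerSpec("rda", lambda rs: LinearDiscriminantAnalysis(
            solver="lsqr", shrinkage="auto")),
        LearnerSpec("mda", lambda rs: QuadraticDiscriminantAnalysis(reg_param=0.5)),
        LearnerSpec("fda", lambda rs: make_pipeline(
            PolynomialFeatures(degree=2, interaction_only=True, include_bias=False),
            StandardScaler(),
            LogisticRegression(C=0.5, max_iter=2000))),
        LearnerSpec("gbm", lambda rs: GradientBoostingClassifier(
            n_estimators=100, max_depth=2, learning_rate=0.1, random_state=rs)),
        LearnerSpec("svm_radial", lambda rs: make_pipeline(
            StandardScaler(), SVC(kernel="rbf", C=1.0, probability=True, random_state=rs))),
        LearnerSpec("svm_linear", lambda rs: make_pipeline(
            StandardScaler(), SVC(kernel="linear", C=1.0, probability=True, random_state=rs))),
        LearnerSpec("rf", lambda rs: RandomForestClassifier(
            n_estimators=200, random_state=rs)),
        LearnerSpec("c5_tree", lambda rs: DecisionTreeClassifier(
            min_samples_leaf=5, random_state=rs)),
        LearnerSpec("nnet", lambda rs: make_pipeline(
            StandardScaler(), MLPClassifier(hidden_layer_sizes=(8,), alpha=0.01,
                                            max_iter=500, random_state=rs))),
        LearnerSpec("bayes_glm", lambda rs: make_pipeline(
            StandardScaler(), LogisticRegression(C=1.0, max_iter=1000))),
        LearnerSpec("glmnet", lambda rs: make_pipeline(
            StandardScaler(), LogisticRegression(penalty="elasticnet", solver="saga",
                                                 l1_ratio=0.5, C=1.0, max_iter=5000,
                                                 random_state=rs))),
    ]


# ---------------------------------------------------------------------------
# folds and feature selection
# ---------------------------------------------------------------------------

@dataclass
class FoldAssignment:
    """Stratified fold membership, 1-based fold indices."""

    folds: pd.Series  # sample id -> fold index
    k: int
    seed: int

    def train_test(self, fold: int) -> tuple[list[str], list[str]]:
        test = list(self.folds.index[self.folds == fold])
        train = list(self.folds.index[self.folds != fold])
        return train, test


def assign_folds(classes: ClassLabels, k: int, seed: int) -> FoldAssignment:
    """Stratified random partition into k folds, deterministic per seed.

    ``k == n`` is leave-one-out (no stratification possible or needed);
    otherwise each class must have at least k samples.
    """
    ids = np.array(classes.included)
    y = classes.binary().to_numpy()
    n = len(ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    folds = pd.Series(0, index=pd.Index(ids, name="sample_id"), name="fold")
    if k == n:
        order = np.random.default_rng(seed).permutation(n)
        folds.iloc[order] = np.arange(1, n + 1)
        return FoldAssignment(folds=folds, k=k, seed=seed)
    for label in (0, 1):
        n_class = int((y == label).sum())
        if n_class < k:
            name = "active" if label == 1 else "inactive"
            raise ValueError(f"class '{name}' has {n_class} samples, fewer than k={k}")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for fold_idx, (_, test_idx) in enumerate(splitter.split(np.zeros(n), y), start=1):
        folds.iloc[test_idx] = fold_idx
    return FoldAssignment(folds=folds, k=k, seed=seed)


def select_fold_features(matrix: pd.DataFrame, classes: ClassLabels,
                         training_ids, m: int = N_SELECTED_FEATURES) -> list[str]:
    """Top-m probes by two-sample (pooled) t-test on training samples only.

    Ties on p break toward larger |t|, then lexicographic probe id.  Only
    the training columns of the matrix are ever read.
    """
    if m > matrix.shape[0]:
        raise ValueError(f"cannot select {m} features from {matrix.shape[0]} probes")
    training_ids = list(training_ids)
    labels = classes.labels.loc[training_ids]
    act_ids = [s for s in training_ids if labels[s] == "active"]
    ina_ids = [s for s in training_ids if labels[s] == "inactive"]
    if not act_ids or not ina_ids:
        raise ValueError("both classes must be present in the training split")

    a = matrix[act_ids].to_numpy(dtype=float)
    b = matrix[ina_ids].to_numpy(dtype=float)
    n1, n2 = a.shape[1], b.shape[1]
    delta = a.mean(axis=1) - b.mean(axis=1)
    s2 = (a.var(axis=1, ddof=0) * n1 + b.var(axis=1, ddof=0) * n2) / (n1 + n2 - 2)
    se = np.sqrt(s2 * (1 / n1 + 1 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, delta / se, np.where(delta == 0, 0.0, np.inf * np.sign(delta)))
    p = np.where(np.isinf(t), 0.0, 2.0 * stats.t.sf(np.abs(t), df=n1 + n2 - 2))
    p = np.where((se == 0) & (delta == 0), 1.0, p)

    ranking = pd.DataFrame(
        {"p": p, "abs_t": np.abs(t)}, index=matrix.index.rename("probe_id")
    ).reset_index().sort_values(["p", "abs_t", "probe_id"],
                                ascending=[True, False, True], kind="mergesort")
    return ranking["probe_id"].head(m).tolist()


# ---------------------------------------------------------------------------
# panel training and scoring
# ---------------------------------------------------------------------------

@dataclass
class FittedPanel:
    """A trained learner panel over a fixed feature list."""

    features: list[str]
    learners: dict[str, object]  # name -> fitted estimator


def train_learner_panel(matrix: pd.DataFrame, classes: ClassLabels, training_ids,
                        features, roster: list[LearnerSpec], seed: int = 0) -> FittedPanel:
    """Fit every roster learner on the feature-restricted training submatrix.

    A learner that errors is retried once and otherwise dropped with a
    warning; if more than half the roster fails the fold is aborted.
    """
    if not roster:
        raise ValueError("roster is empty")
    training_ids = list(training_ids)
    X = matrix.loc[list(features), training_ids].T.to_numpy(dtype=float)
    y = classes.binary().loc[training_ids].to_numpy()

    fitted: dict[str, object] = {}
    failures = []
    import warnings

    for i, spec in enumerate(roster):
        rs = (seed * 1000 + i) % (2**31 - 1)
        est = None
        for attempt in range(2):
            try:
                candidate = spec.factory(rs + attempt)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    candidate.fit(X, y)
                est = candidate
                break
            except Exception as exc:  # noqa: BLE001 - roster robustness
                logger.warning("learner %s failed (attempt %d): %s", spec.name, attempt + 1, exc)
        if est is None:
            failures.append(spec.name)
        else:
            fitted[spec.name] = est
    if len(failures) > len(roster) / 2:
        raise RuntimeError(f"more than half the roster failed to train: {failures}")
    if failures:
        logger.warning("dropped learners: %s; ensemble median over the rest", failures)
    return FittedPanel(features=list(features), learners=fitted)


def score_with_panel(panel: FittedPanel, matrix: pd.DataFrame, sample_ids) -> pd.DataFrame:
    """Probability-of-active scores, learners x samples, each in [0, 1]."""
    sample_ids = list(sample_ids)
    missing = [f for f in panel.features if f not in matrix.index]
    if missing:
        raise KeyError(f"samples lack panel features: {missing}")
    X = matrix.loc[panel.features, sample_ids].T.to_numpy(dtype=float)
    rows = {}
    import warnings

    for name, est in panel.learners.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            probs = est.predict_proba(X)
        classes_ = list(est.classes_)
        scores = probs[:, classes_.index(1)] if 1 in classes_ else np.zeros(len(sample_ids))
        if np.any(scores < -1e-9) or np.any(scores > 1 + 1e-9):
            raise ValueError(f"learner {name} produced scores outside [0, 1]")
        rows[name] = np.clip(scores, 0.0, 1.0)
    return pd.DataFrame(rows, index=pd.Index(sample_ids, name="sample_id")).T


def ensemble_median(learner_scores: pd.DataFrame) -> pd.Series:
    """Per-sample median across learners (mean of central pair when even)."""
    if learner_scores.shape[0] < 1:
        raise ValueError("need at least one learner row")
    return learner_scores.median(axis=0).rename("ensemble")


# ---------------------------------------------------------------------------
# cross-validation and the final model
# ---------------------------------------------------------------------------

@dataclass
class CVResults:
    """Out-of-fold scores, per-fold feature lists, and the pooled AUC."""

    scores: pd.DataFrame  # index sample; fold, class, per-learner, ensemble
    fold_features: dict[int, list[str]]
    auc: float
    cohort_tag: str
    k: int
    seed: int
    learner_names: list[str]

    def summary(self) -> str:
        counts = self.scores["class"].value_counts().to_dict()
        return (
            f"{self.cohort_tag}: {self.k}-fold cross-validated median ensemble "
            f"({len(self.learner_names)} learners)\n"
            f"  samples: {len(self.scores)} {counts}\n"
            f"  pooled out-of-fold AUC: {self.auc:.3f}\n"
            f"  mean ensemble score (active / inactive): "
            f"{self.scores.loc[self.scores['class'] == 'active', 'ensemble'].mean():.3f} / "
            f"{self.scores.loc[self.scores['class'] == 'inactive', 'ensemble'].mean():.3f}"
        )


class ActivityClassifier:
    """Median-ensemble activity classifier over a cohort (model object).

    ``cross_validate`` yields out-of-fold scores and AUC; ``fit`` refits on
    all included samples for deployment.
    """

    def __init__(self, matrix: pd.DataFrame, classes: ClassLabels,
                 roster: list[LearnerSpec] | None = None,
                 n_features: int = N_SELECTED_FEATURES):
        self.matrix = matrix
        self.classes = classes
        self.roster = roster if roster is not None else default_roster()
        self.n_features = n_features

    def cross_validate(self, k: int = 10, seed: int = 0) -> CVResults:
        assignment = assign_folds(self.classes, k, seed)
        included = self.classes.included
        learner_names = [s.name for s in self.roster]
        scores = pd.DataFrame(index=pd.Index(included, name="sample_id"),
                              columns=["fold", "class"] + learner_names + ["ensemble"],
                              dtype=object)
        scores["class"] = self.classes.labels
        fold_features: dict[int, list[str]] = {}
        for fold in range(1, assignment.k + 1):
            train_ids, test_ids = assignment.train_test(fold)
            features = select_fold_features(self.matrix, self.classes, train_ids,
                                            m=self.n_features)
            fold_features[fold] = features
            panel = train_learner_panel(self.matrix, self.classes, train_ids,
                                        features, self.roster, seed=seed + fold)
            fold_scores = score_with_panel(panel, self.matrix, test_ids)
            for name in fold_scores.index:
                scores.loc[test_ids, name] = fold_scores.loc[name].to_numpy()
            scores.loc[test_ids, "fold"] = fold
            scores.loc[test_ids, "ensemble"] = ensemble_median(fold_scores).to_numpy()
        numeric_cols = learner_names + ["ensemble"]
        scores[numeric_cols] = scores[numeric_cols].astype(float)
        scores["fold"] = scores["fold"].astype(int)
        auc = auc_mann_whitney(scores["ensemble"].to_numpy(),
                               (scores["class"] == "active").to_numpy())
        return CVResults(scores=scores, fold_features=fold_features, auc=float(auc),
                         cohort_tag=self.classes.cohort_tag, k=assignment.k,
                         seed=seed, learner_names=learner_names)

    def fit(self, seed: int = 0) -> "FittedEnsemble":
        features = select_fold_features(self.matrix, self.classes,
                                        self.classes.included, m=self.n_features)
        panel = train_learner_panel(self.matrix, self.classes, self.classes.included,
                                    features, self.roster, seed=seed)
        return FittedEnsemble(panel=panel, cohort_tag=self.classes.cohort_tag, seed=seed)


@dataclass
class FittedEnsemble:
    """Deployment model: final feature list plus the fitted panel."""

    panel: FittedPanel
    cohort_tag: str
    seed: int

    @property
    def features(self) -> list[str]:
        return self.panel.features

    def score(self, matrix: pd.DataFrame, sample_ids) -> pd.Series:
        return ensemble_median(score_with_panel(self.panel, matrix, sample_ids))

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {"features": self.panel.features, "cohort_tag": self.cohort_tag,
                "seed": self.seed, "learners": list(self.panel.learners)}
        (directory / "model.json").write_text(json.dumps(meta, indent=1))
        joblib.dump(self.panel.learners, directory / "learners.joblib")

    @classmethod
    def load(cls, directory) -> "FittedEnsemble":
        directory = Path(directory)
        meta = json.loads((directory / "model.json").read_text())
        learners = joblib.load(directory / "learners.joblib")
        panel = FittedPanel(features=meta["features"], learners=learners)
        return cls(panel=panel, cohort_tag=meta["cohort_tag"], seed=meta["seed"])
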