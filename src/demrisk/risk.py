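"""Step 1 of the two-step procedure: cross-validated risk scoring.

A candidate probabilistic classifier is tuned by repeated stratified
k-fold cross-validation (default 10 repetitions of 10 folds): for every
meta-parameter grid point, out-of-fold predicted probabilities are pooled
within each repeat, scored by AUROC, and averaged over repeats; the best
grid point is refitted on the full training set. Class imbalance is handled
with observation weights inversely proportional to class size wherever the
learner accepts them. The fitted model emits a risk score equal to 100
times the predicted dementia probability.

Learners come from a pluggable registry backed by scikit-learn; the
contract here is the weighting, the cross-validation protocol and the
score scaling, not learner internals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import ParameterGrid, RepeatedStratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import SplineTransformer, StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .metrics import auroc
from .prep import compute_class_weights

#: Default predictor set: the cohort's summary variables.
FEATURE_COLUMNS = [
    "age", "married", "female", "education", "sbp", "dbp",
    "dx_stroke", "dx_heart", "dx_diabetes", "dx_hypertension", "dx_depression",
    "dx_dementia", "dx_psychiatric", "dx_neurologic", "dx_vision", "dx_hearing",
    "hmse", "tics", "csid", "judgment", "numeracy",
    "adl", "iadl", "mobility", "cesd", "anxiety",
    "iqcode", "blessed_habits", "blessed_performance",
]


class CapabilityError(ValueError):
    """Requested learner is not in the registry."""


@dataclass(frozen=True)
class CVSpec:
    """Repeated cross-validation contract (selection metric is AUROC)."""

    folds: int = 10
    repeats: int = 10
    seed: int = 0

    def validate(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass(frozen=True)
class LearnerSpec:
    name: str
    grid: dict = field(default_factory=dict)
    supports_weights: bool = True


def _make_gb(seed):
    return GradientBoostingClassifier(subsample=0.8, random_state=seed)


def _make_rf(seed):
    return RandomForestClassifier(random_state=seed)


def _make_svm(seed):
    return Pipeline([
        ("scale", StandardScaler()),
        ("clf", SVC(kernel="rbf", probability=True, random_state=seed)),
    ])


def _make_enet(seed):
    return Pipeline([
        ("scale", StandardScaler()),
        ("clf", LogisticRegression(solver="saga", l1_ratio=0.5, tol=1e-3,
                                   max_iter=2000, random_state=seed)),
    ])


def _make_splines(seed):
    # penalized logistic model on a spline basis expansion (an adaptive-
    # splines-family candidate; not the forward/backward MARS algorithm)
    return Pipeline([
        ("scale", StandardScaler()),
        ("spline", SplineTransformer(degree=3)),
        ("clf", LogisticRegression(max_iter=2000, random_state=seed)),
    ])


def _make_mlp(seed):
    return Pipeline([
        ("scale", StandardScaler()),
        ("clf", MLPClassifier(max_iter=800, random_state=seed)),
    ])


# name -> (factory, default grid, supports_weights). The MLP grid is seeded
# around a single hidden layer of 5 neurons; MLPClassifier accepts no
# observation weights, so that learner trains unweighted.
LEARNER_REGISTRY: dict[str, tuple] = {
    "gradient_boosting": (
        _make_gb,
        {"n_estimators": [100, 300], "max_depth": [2, 3]},
        True,
    ),
    "random_forest": (
        _make_rf,
        {"n_estimators": [200, 500]},
        True,
    ),
    "svm_rbf": (
        _make_svm,
        {"clf__C": [1.0, 10.0], "clf__gamma": ["scale"]},
        True,
    ),
    "elastic_net": (
        _make_enet,
        {"clf__C": [0.1, 1.0], "clf__l1_ratio": [0.5]},
        True,
    ),
    "regression_splines": (
        _make_splines,
        {"spline__n_knots": [5], "clf__C": [0.1, 1.0]},
        True,
    ),
    "mlp": (
        _make_mlp,
        {"clf__hidden_layer_sizes": [(5,), (10,)], "clf__alpha": [1e-3]},
        False,
    ),
}


def available_learners() -> list[str]:
    return sorted(LEARNER_REGISTRY)


def get_learner_spec(name: str, grid: dict | None = None) -> LearnerSpec:
    if name not in LEARNER_REGISTRY:
        raise CapabilityError(
            f"unknown learner {name!r}; available: {', '.join(available_learners())}"
        )
    _, default_grid, supports_w = LEARNER_REGISTRY[name]
    return LearnerSpec(name=name, grid=dict(default_grid if grid is None else grid),
                       supports_weights=supports_w)


def _fit_with_weights(est, X, y, w, supports_weights):
    if w is None or not supports_weights:
        return est.fit(X, y)
    if isinstance(est, Pipeline):
        return est.fit(X, y, **{f"{est.steps[-1][0]}__sample_weight": w})
    return est.fit(X, y, sample_weight=w)


class DementiaRiskScorer(BaseEstimator, ClassifierMixin):
    """Cross-validation-tuned probabilistic classifier emitting 0-100 risk
    scores.

    Parameters
    ----------
    learner : str
        Registry name: one of ``available_learners()``.
    grid : dict or None
        Meta-parameter grid (name -> candidate list); None uses the
        registry default for the learner.
    cv_folds, cv_repeats : int
        Repeated stratified k-fold protocol for grid selection.
    class_weighting : bool
        Weight observations inversely to class size during fitting (where
        the learner accepts weights).
    random_state : int
        Seeds fold assignment and stochastic learners.

    Attributes
    ----------
    best_params_ : dict — selected grid point.
    cv_auroc_ : float — its mean out-of-fold AUROC (pooled per repeat,
        averaged over repeats).
    cv_results_ : list of (params, mean AUROC) over the grid.
    model_ : fitted underlying estimator.
    feature_names_ : list of predictor columns.
    """

    def __init__(self, learner: str = "svm_rbf", grid: dict | None = None,
                 cv_folds: int = 10, cv_repeats: int = 10,
                 class_weighting: bool = True, random_state: int = 0):
        self.learner = learner
        self.grid = grid
        self.cv_folds = cv_folds
        self.cv_repeats = cv_repeats
        self.class_weighting = class_weighting
        self.random_state = random_state

    def _extract(self, X) -> tuple[np.ndarray, list[str]]:
        if isinstance(X, pd.DataFrame):
            names = getattr(self, "feature_names_", None)
            if names is None:
                names = [c for c in FEATURE_COLUMNS if c in X.columns] or list(X.columns)
            missing = [c for c in names if c not in X.columns]
            if missing:
                raise ValueError(f"records missing model features: {missing}")
            return X[names].to_numpy(float), list(names)
        arr = np.asarray(X, dtype=float)
        names = getattr(self, "feature_names_", None)
        if names is not None and arr.shape[1] != len(names):
            raise ValueError(
                f"expected {len(names)} features, got {arr.shape[1]}"
            )
        return arr, names or [f"x{i}" for i in range(arr.shape[1])]

    def fit(self, X, y, sample_weight=None):
        spec = get_learner_spec(self.learner, self.grid)
        cv_spec = CVSpec(self.cv_folds, self.cv_repeats, self.random_state)
        cv_spec.validate()
        Xa, names = self._extract(X)
        self.feature_names_ = names
        y = np.asarray(y).astype(int)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("risk scoring needs exactly two classes in y")

        if sample_weight is None and self.class_weighting:
            sample_weight = compute_class_weights(y)
        factory, _, supports_w = LEARNER_REGISTRY[spec.name]

        splitter = RepeatedStratifiedKFold(
            n_splits=cv_spec.folds, n_repeats=cv_spec.repeats,
            random_state=cv_spec.seed,
        )
        splits = list(splitter.split(Xa, y))

        results = []
        oof_by_point = []
        for params in ParameterGrid(spec.grid) if spec.grid else [{}]:
            oof = np.full((cv_spec.repeats, len(y)), np.nan)
            for i, (tr, va) in enumerate(splits):
                rep = i // cv_spec.folds
                if np.unique(y[tr]).size < 2:
                    warnings.warn("single-class training fold skipped", UserWarning)
                    continue
                est = clone(factory(self.random_state))
                est.set_params(**params)
                w = None if sample_weight is None else np.asarray(sample_weight)[tr]
                _fit_with_weights(est, Xa[tr], y[tr], w, supports_w)
                oof[rep, va] = est.predict_proba(Xa[va])[:, 1]
            rep_aurocs = [
                auroc(row[~np.isnan(row)], y[~np.isnan(row)])
                for row in oof if (~np.isnan(row)).any()
            ]
            results.append((dict(params), float(np.mean(rep_aurocs))))
            oof_by_point.append(oof)

        best_idx = int(np.argmax([a for _, a in results]))
        self.cv_results_ = results
        self.best_params_, self.cv_auroc_ = results[best_idx]
        # cross-validated risk scores for the training samples (mean
        # out-of-fold probability over repeats, x100): downstream cutoff
        # fitting must use these, not in-sample predictions, or an
        # overfitting learner would push every cutoff toward 100
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            oof_mean = np.nanmean(oof_by_point[best_idx], axis=0)
        self.oof_scores_ = np.clip(100.0 * oof_mean, 0.0, 100.0)

        final = clone(factory(self.random_state))
        final.set_params(**self.best_params_)
        _fit_with_weights(final, Xa, y, sample_weight, supports_w)
        self.model_ = final
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        Xa, _ = self._extract(X)
        return self.model_.predict_proba(Xa)

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def risk_score(self, X) -> np.ndarray:
        """100 x predicted dementia probability, clipped to [0, 100]."""
        return np.clip(100.0 * self.predict_proba(X)[:, 1], 0.0, 100.0)


def tune_and_fit(train, labels, weights=None, learner: str = "svm_rbf",
                 grid: dict | None = None, cv_spec: CVSpec | None = None,
                 class_weighting: bool = True) -> DementiaRiskScorer:
    """Functional wrapper over :class:`DementiaRiskScorer`."""
    cv = cv_spec or CVSpec()
    scorer = DementiaRiskScorer(
        learner=learner, grid=grid, cv_folds=cv.folds, cv_repeats=cv.repeats,
        class_weighting=class_weighting, random_state=cv.seed,
    )
    return scorer.fit(train, labels, sample_weight=weights)


def risk_score(model: DementiaRiskScorer, records) -> np.ndarray:
    return model.risk_score(records)
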