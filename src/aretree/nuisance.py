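"""Cross-validated ensemble ("super learner") nuisance estimation.

The outcome regression ``Q(T,W) = E[Y | T, W]`` and the propensity
``g(W) = P(T=1 | W)`` are each estimated by a convex combination of base
learners.  Weights are chosen by non-negative least squares on out-of-fold
predictions and normalised to sum to one, the standard discrete-to-convex
super-learner recipe.

Internal cross-validation folds are assigned in a canonical row order
(lexicographic sort of the design), so predictions do not depend on the
order in which rows happen to arrive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import nnls
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.dummy import DummyClassifier, DummyRegressor
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import ElasticNet, LinearRegression, LogisticRegression
from xgboost import XGBClassifier, XGBRegressor

__all__ = [
    "EnsembleConfig",
    "NuisanceFits",
    "SuperLearner",
    "SuperLearnerClassifier",
    "fit_outcome_ensemble",
    "fit_propensity_ensemble",
    "make_learners",
    "EnsembleFitError",
    "SingleClassError",
    "DEFAULT_G_MIN",
]

DEFAULT_G_MIN = 0.025


class EnsembleFitError(RuntimeError):
    """Every base learner failed to fit."""


class SingleClassError(ValueError):
    """The binary treatment vector contains a single class (positivity failure)."""


# -- learner registry ---------------------------------------------------------
# Default menu mirrors the package defaults: intercept-only mean, GLM,
# elastic net, random forest and gradient boosting.  Sizes are modest so a
# full cross-validated fit stays fast on a single core.

def _regressor_registry(seed: int | None) -> dict:
    return {
        "mean": lambda **kw: DummyRegressor(strategy="mean", **kw),
        "glm": lambda **kw: LinearRegression(**kw),
        "enet": lambda **kw: ElasticNet(**{"alpha": 0.01, "l1_ratio": 0.5, "max_iter": 5000, **kw}),
        "rf": lambda **kw: RandomForestRegressor(
            **{"n_estimators": 50, "min_samples_leaf": 5, "random_state": seed, "n_jobs": 1, **kw}
        ),
        "xgb": lambda **kw: XGBRegressor(
            **{
                "n_estimators": 50,
                "max_depth": 3,
                "learning_rate": 0.3,
                "random_state": 0 if seed is None else seed,
                "n_jobs": 1,
                "verbosity": 0,
                **kw,
            }
        ),
    }


def _classifier_registry(seed: int | None) -> dict:
    return {
        "mean": lambda **kw: DummyClassifier(strategy="prior", **kw),
        "glm": lambda **kw: LogisticRegression(**{"max_iter": 1000, **kw}),
        "enet": lambda **kw: LogisticRegression(**{"C": 0.1, "max_iter": 1000, **kw}),
        "rf": lambda **kw: RandomForestClassifier(
            **{"n_estimators": 50, "min_samples_leaf": 5, "random_state": seed, "n_jobs": 1, **kw}
        ),
        "xgb": lambda **kw: XGBClassifier(
            **{
                "n_estimators": 50,
                "max_depth": 3,
                "learning_rate": 0.3,
                "random_state": 0 if seed is None else seed,
                "n_jobs": 1,
                "verbosity": 0,
                **kw,
            }
        ),
    }


DEFAULT_MENU: tuple[tuple[str, dict], ...] = (
    ("mean", {}),
    ("glm", {}),
    ("enet", {}),
    ("rf", {}),
    ("xgb", {}),
)


def make_learners(
    menu: Sequence[tuple[str, dict]],
    task: str,
    seed: int | None = None,
) -> list[tuple[str, BaseEstimator]]:
    """Instantiate named base learners from a (name, hyperparameter) menu."""
    registry = _regressor_registry(seed) if task == "regression" else _classifier_registry(seed)
    out = []
    for name, params in menu:
        if name not in registry:
            raise KeyError(f"unknown learner {name!r}; available: {sorted(registry)}")
        out.append((name, registry[name](**dict(params))))
    return out


@dataclass
class EnsembleConfig:
    """Learner menu and super-learner settings.

    ``menu`` entries are (name, hyperparameter-dict) pairs resolved against
    the learner registry; ``cv`` is the internal fold count; ``g_min`` the
    propensity clip bound.
    """

    menu: tuple[tuple[str, dict], ...] = DEFAULT_MENU
    cv: int = 5
    g_min: float = DEFAULT_G_MIN

    def __post_init__(self) -> None:
        if len(self.menu) == 0:
            raise ValueError("learner menu must be nonempty")
        if not (0.0 < self.g_min < 0.5):
            raise ValueError("g_min must lie in (0, 0.5)")
        if self.cv < 2:
            raise ValueError("internal CV fold count must be >= 2")


@dataclass
class NuisanceFits:
    """Per-observation nuisance predictions on the scaled outcome."""

    Q1: np.ndarray
    Q0: np.ndarray
    QT: np.ndarray
    ghat: np.ndarray
    g_min: float

    def __post_init__(self) -> None:
        n = len(self.QT)
        for name in ("Q1", "Q0", "QT", "ghat"):
            v = getattr(self, name)
            if len(v) != n or not np.all(np.isfinite(v)):
                raise ValueError(f"{name} must be length {n} and finite")
        if np.any(self.ghat < self.g_min - 1e-12) or np.any(self.ghat > 1 - self.g_min + 1e-12):
            raise ValueError("ghat must be clipped to [g_min, 1-g_min]")


def _canonical_fold_assignment(X: np.ndarray, y: np.ndarray, cv: int) -> np.ndarray:
    """Deal rows to folds in lexicographic order of (X, y) content."""
    design = np.column_stack([X, y]) if X.size else y.reshape(-1, 1)
    order = np.lexsort(design.T[::-1])
    folds = np.empty(len(y), dtype=int)
    folds[order] = np.arange(len(y)) % cv
    return folds


class _SuperLearnerBase(BaseEstimator):
    """Shared machinery for the regression and classification ensembles."""

    _task = "regression"

    def __init__(self, menu=DEFAULT_MENU, cv=5, random_state=None):
        self.menu = menu
        self.cv = cv
        self.random_state = random_state

    def _raw_predict(self, est, X):
        if self._task == "regression":
            return np.asarray(est.predict(X), dtype=float)
        return np.asarray(est.predict_proba(X)[:, 1], dtype=float)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(-1, 1)
        y = np.asarray(y, dtype=float).ravel()
        n = len(y)
        if n < 2 * self.cv:
            raise ValueError(f"need n >= {2 * self.cv} observations for {self.cv}-fold fitting")
        if self._task == "classification" and len(np.unique(y)) < 2:
            raise SingleClassError("treatment vector contains a single class")

        names_and_learners = make_learners(self.menu, self._task, self.random_state)
        folds = _canonical_fold_assignment(X, y, self.cv)

        Z = np.full((n, len(names_and_learners)), np.nan)
        failed = np.zeros(len(names_and_learners), dtype=bool)
        for j, (name, proto) in enumerate(names_and_learners):
            try:
                for k in range(self.cv):
                    tr, te = folds != k, folds == k
                    est = clone(proto)
                    est.fit(X[tr], y[tr])
                    Z[te, j] = self._raw_predict(est, X[te])
            except Exception as exc:  # noqa: BLE001 - a learner may legitimately fail
                failed[j] = True
                warnings.warn(f"learner {name!r} failed and was dropped: {exc}")
        if failed.all():
            raise EnsembleFitError("all base learners failed to fit")

        keep = ~failed
        Zk = Z[:, keep]
        risks = np.mean((y[:, None] - Zk) ** 2, axis=0)
        w, _ = nnls(Zk, y)
        if w.sum() <= 0:
            w = np.zeros_like(w)
            w[np.argmin(risks)] = 1.0
        w = w / w.sum()

        kept = [nl for nl, f in zip(names_and_learners, failed) if not f]
        self.learner_names_ = [name for name, _ in kept]
        self.learners_ = []
        for name, proto in kept:
            est = clone(proto)
            est.fit(X, y)
            self.learners_.append(est)
        self.weights_ = w
        self.cv_risk_ = dict(zip(self.learner_names_, risks))
        ensemble_oof = Zk @ w
        self.ensemble_cv_risk_ = float(np.mean((y - ensemble_oof) ** 2))
        self.oof_prediction_ = ensemble_oof
        self.n_features_in_ = X.shape[1]
        return self

    def _combine(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(-1, 1)
        preds = np.column_stack([self._raw_predict(est, X) for est in self.learners_])
        return preds @ self.weights_


class SuperLearner(_SuperLearnerBase, RegressorMixin):
    """NNLS-weighted convex ensemble regressor."""

    _task = "regression"

    def predict(self, X):
        return self._combine(X)


class SuperLearnerClassifier(_SuperLearnerBase):
    """NNLS-weighted convex ensemble for binary probabilities."""

    _task = "classification"

    def predict_proba(self, X):
        p1 = np.clip(self._combine(X), 0.0, 1.0)
        return np.column_stack([1 - p1, p1])

    def predict(self, X):
        return (self._combine(X) >= 0.5).astype(int)


def fit_outcome_ensemble(
    T: np.ndarray,
    W: np.ndarray,
    Y: np.ndarray,
    config: EnsembleConfig | None = None,
    seed: int | None = None,
) -> SuperLearner:
    """Fit the outcome super learner regressing Y on (T, W).

    The returned estimator's ``predict`` evaluates ``Qhat(t, w)`` on any
    design built as ``column_stack([t, w])``.  A constant outcome is
    handled by the intercept-only learner, not an error.
    """
    config = config or EnsembleConfig()
    W = np.asarray(W, dtype=float)
    if W.ndim == 1:
        W = W.reshape(-1, 1)
    design = np.column_stack([np.asarray(T, dtype=float), W]) if W.size else np.asarray(
        T, dtype=float
    ).reshape(-1, 1)
    sl = SuperLearner(menu=config.menu, cv=config.cv, random_state=seed)
    sl.fit(design, np.asarray(Y, dtype=float))
    return sl


def fit_propensity_ensemble(
    T: np.ndarray,
    W: np.ndarray,
    config: EnsembleConfig | None = None,
    seed: int | None = None,
    return_model: bool = False,
):
    """Cross-fitted, clipped propensity predictions ``ghat_i = P(T=1|W_i)``.

    Each returned prediction comes from an ensemble whose internal folds
    excluded that observation.  Raises :class:`SingleClassError` when T is
    degenerate.
    """
    config = config or EnsembleConfig()
    T = np.asarray(T, dtype=float).ravel()
    W = np.asarray(W, dtype=float)
    if W.ndim == 1:
        W = W.reshape(-1, 1)
    if len(np.unique(T)) < 2:
        raise SingleClassError("treatment vector contains a single class")
    sl = SuperLearnerClassifier(menu=config.menu, cv=config.cv, random_state=seed)
    sl.fit(W if W.size else np.zeros((len(T), 1)), T)
    ghat = np.clip(sl.oof_prediction_, config.g_min, 1.0 - config.g_min)
    if return_model:
        return ghat, sl
    return ghat
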