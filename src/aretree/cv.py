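"""K-fold cross-estimation of the data-adaptive attributable regional effect.

Each fold k discovers a threshold region and trains nuisance estimators on
the parameter-generating sample (everything but fold k), then evaluates on
the held-out estimation sample.  Out-of-fold nuisance predictions are
stacked and a single pooled fluctuation yields the cross-validated
estimate

    Psi_CV = (1/K) sum_k { (1/n_k) sum_{i in fold k} [Q*_{-k}(1, W_i) - Y_i] },

with influence-function inference over all n.  If any fold fails to
discover a region, the procedure reports "no consistent region found":
pooling is only meaningful when every fold flags a region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .nuisance import EnsembleConfig, fit_outcome_ensemble, fit_propensity_ensemble
from .regions import MixtureDataset, Operator, Region, ThresholdRule, membership
from .tmle import (
    OutcomeScale,
    TMLEFit,
    estimate_are,
    scale_outcome,
    tmle_treated_mean,
)
from .tree import TreeConfig, build_tree_greedy, extract_region, search_exhaustive

__all__ = [
    "FoldResult",
    "RegionGroupResult",
    "PooledResult",
    "make_folds",
    "fit_fold",
    "pool_tmle",
    "summarize_cutpoints",
    "CVRegionTMLE",
]


def make_folds(n: int, K: int, seed: int | None = None) -> np.ndarray:
    """Balanced random fold assignment (sizes differ by at most one)."""
    if K < 2:
        raise ValueError("K must be >= 2")
    if K > n:
        raise ValueError("K must not exceed n")
    rng = np.random.default_rng(seed)
    assignment = np.arange(n) % K
    rng.shuffle(assignment)
    return assignment


@dataclass
class FoldResult:
    """Discovery and held-out estimation output for one fold."""

    fold_id: int
    region: Region | None
    fit: TMLEFit | None = None
    estimate_available: bool = False
    root_any_valid: bool = False
    # validation-sample nuisance material retained for pooling (scaled scale)
    val_index: np.ndarray | None = None
    Q1: np.ndarray | None = None
    QT: np.ndarray | None = None
    ghat: np.ndarray | None = None
    T: np.ndarray | None = None
    Y_scaled: np.ndarray | None = None

    @property
    def are(self) -> float | None:
        return self.fit.psi_hat if self.fit else None


@dataclass
class RegionGroupResult:
    """Pooled estimate for the folds sharing one variable signature."""

    signature: tuple[str, ...]
    n_folds: int
    proportion_folds: float
    are: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    region_label: str
    mean_region: Region
    cutpoint_summary: dict


@dataclass
class PooledResult:
    """Omnibus pooled CV-TMLE result across all folds."""

    status: str  # "ok" | "no_consistent_region"
    K: int
    are: float | None = None
    se: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    p_value: float | None = None
    eps_fluct: float | None = None
    groups: list[RegionGroupResult] = field(default_factory=list)


def summarize_cutpoints(regions: list[Region]) -> dict:
    """Per (exposure, operator): mean cutpoint and (min, max) across folds.

    Returns ``{(name, op): {"mean": ..., "min": ..., "max": ..., "label": ...}}``
    with labels like ``"X5 > 1.957 (1.9, 2)"``.
    """
    if not regions:
        raise ValueError("cutpoint summary requires at least one region")
    buckets: dict[tuple[str, Operator], list[float]] = {}
    order: list[tuple[str, Operator]] = []
    for region in regions:
        for rule in region.rules:
            key = (rule.exposure, rule.operator)
            if key not in buckets:
                buckets[key] = []
                order.append(key)
            buckets[key].append(rule.cutpoint)
    out = {}
    for key in order:
        name, op = key
        cuts = np.asarray(buckets[key], dtype=float)
        sym = "≤" if op is Operator.LE else ">"
        out[key] = {
            "mean": float(cuts.mean()),
            "min": float(cuts.min()),
            "max": float(cuts.max()),
            "label": f"{name} {sym} {cuts.mean():g} ({cuts.min():g}, {cuts.max():g})",
        }
    return out


def _mean_cutpoint_region(regions: list[Region]) -> Region:
    """Region built from the mean cutpoint of each (exposure, operator)."""
    summary = summarize_cutpoints(regions)
    return Region(
        tuple(ThresholdRule(name, op, info["mean"]) for (name, op), info in summary.items())
    )


def fit_fold(
    data: MixtureDataset,
    assignment: np.ndarray,
    k: int,
    tree_config: TreeConfig,
    ensemble_config: EnsembleConfig,
    scale: OutcomeScale,
    seed: int | None = None,
    trace: list | None = None,
) -> FoldResult:
    """Discover a region on the parameter-generating sample and evaluate
    the ARE on the held-out estimation sample of fold ``k``."""
    val_mask = assignment == k
    train = data.subset(np.flatnonzero(~val_mask))
    val = data.subset(np.flatnonzero(val_mask))
    if val.n == 0:
        raise ValueError(f"fold {k} is empty")

    if tree_config.exhaustive:
        region, _ = search_exhaustive(train, tree_config, scale)
        root_any_valid = not region.is_full_space
    else:
        root = build_tree_greedy(train, tree_config, scale, trace=trace)
        region = extract_region(root, tree_config.objective)
        root_any_valid = root.n_valid_candidates > 0
    result = FoldResult(fold_id=k, region=None, root_any_valid=root_any_valid)
    if region.is_full_space:
        return result
    result.region = region

    T_train = membership(region, train.A)
    T_val = membership(region, val.A)
    W_train = train.W.to_numpy(dtype=float) if train.p else np.zeros((train.n, 1))
    W_val = val.W.to_numpy(dtype=float) if val.p else np.zeros((val.n, 1))
    Ys_train = scale.forward(train.Y)
    Ys_val = scale.forward(val.Y)

    q_model = fit_outcome_ensemble(T_train, W_train, Ys_train, ensemble_config, seed)
    _, g_model = fit_propensity_ensemble(T_train, W_train, ensemble_config, seed, return_model=True)

    ones, zeros = np.ones(val.n), np.zeros(val.n)
    Q1 = np.clip(q_model.predict(np.column_stack([ones, W_val])), 0.0, 1.0)
    Q0 = np.clip(q_model.predict(np.column_stack([zeros, W_val])), 0.0, 1.0)
    QT = np.where(T_val == 1, Q1, Q0)
    ghat = np.clip(
        g_model.predict_proba(W_val)[:, 1], ensemble_config.g_min, 1 - ensemble_config.g_min
    )

    result.val_index = np.flatnonzero(val_mask)
    result.Q1, result.QT, result.ghat = Q1, QT, ghat
    result.T, result.Y_scaled = T_val, Ys_val

    if len(np.unique(T_val)) < 2 or T_val.sum() == 0:
        # region exists but the held-out sample cannot support estimation
        return result
    Qstar1, QstarT, eps = tmle_treated_mean(Q1, QT, T_val, ghat, Ys_val)
    result.fit = estimate_are(Qstar1, QstarT, T_val, ghat, Ys_val, scale, eps)
    result.estimate_available = True
    return result


def _pooled_fit(folds: list[FoldResult], scale: OutcomeScale) -> tuple[TMLEFit, float]:
    """Stack validation predictions, run one fluctuation, apply Psi_CV."""
    Q1 = np.concatenate([f.Q1 for f in folds])
    QT = np.concatenate([f.QT for f in folds])
    T = np.concatenate([f.T for f in folds])
    g = np.concatenate([f.ghat for f in folds])
    Ys = np.concatenate([f.Y_scaled for f in folds])
    Qstar1, QstarT, eps = tmle_treated_mean(Q1, QT, T, g, Ys)
    fit = estimate_are(Qstar1, QstarT, T, g, Ys, scale, eps)
    # Psi_CV: average of per-fold means of Q*(1,W) - Y (scaled, then unscaled)
    offsets = np.cumsum([0] + [len(f.Y_scaled) for f in folds])
    fold_means = [
        float(np.mean(Qstar1[a:b] - Ys[a:b])) for a, b in zip(offsets[:-1], offsets[1:])
    ]
    psi_cv = scale.unscale_diff(float(np.mean(fold_means)))
    return fit, psi_cv


def pool_tmle(fold_results: list[FoldResult], K: int, scale: OutcomeScale) -> PooledResult:
    """Pooled cross-validated TMLE with per-signature region groups.

    Any fold without a region makes pooling undefined: the result status
    is ``no_consistent_region`` and carries no estimate.
    """
    if len(fold_results) != K:
        raise ValueError("expected one FoldResult per fold")
    if any(f.region is None for f in fold_results):
        return PooledResult(status="no_consistent_region", K=K)
    usable = [f for f in fold_results if f.Q1 is not None]
    fit, psi_cv = _pooled_fit(usable, scale)
    shift = psi_cv - fit.psi_hat
    pooled = PooledResult(
        status="ok",
        K=K,
        are=psi_cv,
        se=fit.se,
        ci_low=fit.ci_low + shift,
        ci_high=fit.ci_high + shift,
        p_value=fit.p_value,
        eps_fluct=fit.eps_fluct,
    )

    by_sig: dict[tuple[str, ...], list[FoldResult]] = {}
    for f in fold_results:
        by_sig.setdefault(f.region.signature(), []).append(f)
    for sig, members in sorted(by_sig.items(), key=lambda kv: -len(kv[1])):
        regions = [f.region for f in members]
        summary = summarize_cutpoints(regions)
        label = " & ".join(info["label"] for info in summary.values())
        g_fit, g_psi = _pooled_fit([f for f in members if f.Q1 is not None], scale)
        g_shift = g_psi - g_fit.psi_hat
        pooled.groups.append(
            RegionGroupResult(
                signature=sig,
                n_folds=len(members),
                proportion_folds=len(members) / K,
                are=g_psi,
                se=g_fit.se,
                ci_low=g_fit.ci_low + g_shift,
                ci_high=g_fit.ci_high + g_shift,
                p_value=g_fit.p_value,
                region_label=label,
                mean_region=_mean_cutpoint_region(regions),
                cutpoint_summary=summary,
            )
        )
    return pooled


class CVRegionTMLE(BaseEstimator):
    """Cross-validated discovery and estimation of threshold-region effects.

    Fit on a DataFrame ``X`` holding exposure and covariate columns and an
    outcome vector ``y``.  In each of ``n_folds`` folds a significance- and
    positivity-filtered decision tree discovers a candidate exposure region
    on the training split; super-learner nuisance fits from the same split
    are evaluated on the held-out split and pooled into a single
    cross-validated TMLE estimate of the attributable regional effect.

    Parameters
    ----------
    exposures : list of str
        Exposure column names in X (remaining columns are covariates).
    n_folds : int, default 10
        K for the cross-estimation scheme (2 is common in simulations).
    max_depth, min_node, epsilon, alpha, objective, exhaustive,
    threshold_strategy, threshold_param :
        Tree-search settings; see :class:`aretree.tree.TreeConfig`.
    learner_menu : sequence of (name, params), optional
        Super-learner base-learner menu; defaults to mean/GLM/elastic
        net/random forest/gradient boosting.
    ensemble_cv : int, default 5
        Internal folds of each super learner.
    g_min : float, default 0.025
        Propensity clip bound.
    random_state : int, optional
        Single seed; fold assignment, learner seeds and any tree
        randomness all derive from it by seed-sequence spawning.

    Attributes
    ----------
    fold_results_ : list of FoldResult
    pooled_ : PooledResult
    scale_ : OutcomeScale
    """

    def __init__(
        self,
        exposures=None,
        n_folds=10,
        max_depth=3,
        min_node=10,
        epsilon=0.01,
        alpha=0.05,
        objective="max",
        exhaustive=False,
        threshold_strategy="rounded",
        threshold_param=1,
        learner_menu=None,
        ensemble_cv=5,
        g_min=0.025,
        keep_trace=False,
        random_state=None,
    ):
        self.exposures = exposures
        self.n_folds = n_folds
        self.max_depth = max_depth
        self.min_node = min_node
        self.epsilon = epsilon
        self.alpha = alpha
        self.objective = objective
        self.exhaustive = exhaustive
        self.threshold_strategy = threshold_strategy
        self.threshold_param = threshold_param
        self.learner_menu = learner_menu
        self.ensemble_cv = ensemble_cv
        self.g_min = g_min
        self.keep_trace = keep_trace
        self.random_state = random_state

    # -- config assembly --------------------------------------------------
    def _tree_config(self) -> TreeConfig:
        return TreeConfig(
            max_depth=self.max_depth,
            min_node=self.min_node,
            epsilon=self.epsilon,
            alpha=self.alpha,
            objective=self.objective,
            exhaustive=self.exhaustive,
            threshold_strategy=self.threshold_strategy,
            threshold_param=self.threshold_param,
            seed=self.random_state,
        )

    def _ensemble_config(self) -> EnsembleConfig:
        from .nuisance import DEFAULT_MENU

        menu = tuple(self.learner_menu) if self.learner_menu is not None else DEFAULT_MENU
        return EnsembleConfig(menu=menu, cv=self.ensemble_cv, g_min=self.g_min)

    def fit(self, X, y):
        X = pd.DataFrame(X)
        exposures = list(self.exposures) if self.exposures is not None else list(X.columns)
        covariates = [c for c in X.columns if c not in exposures]
        data = MixtureDataset(X[covariates], X[exposures], np.asarray(y, dtype=float))
        return self._fit_dataset(data)

    def fit_dataset(self, data: MixtureDataset):
        """Fit directly from a :class:`MixtureDataset`."""
        return self._fit_dataset(data)

    def _fit_dataset(self, data: MixtureDataset):
        ss = np.random.SeedSequence(self.random_state)
        fold_seed, *learner_seeds = [
            int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(1 + self.n_folds)
        ]
        _, scale = scale_outcome(data.Y)
        assignment = make_folds(data.n, self.n_folds, fold_seed)
        tree_config = self._tree_config()
        ensemble_config = self._ensemble_config()
        self.trace_ = [] if self.keep_trace else None
        self.fold_results_ = []
        for k in range(self.n_folds):
            fold_trace: list | None = [] if self.keep_trace else None
            self.fold_results_.append(
                fit_fold(
                    data,
                    assignment,
                    k,
                    tree_config,
                    ensemble_config,
                    scale,
                    learner_seeds[k],
                    trace=fold_trace,
                )
            )
            if self.keep_trace:
                self.trace_.append({"fold": k, "nodes": fold_trace})
        self.pooled_ = pool_tmle(self.fold_results_, self.n_folds, scale)
        self.scale_ = scale
        self.fold_assignment_ = assignment
        self.n_features_in_ = data.m + data.p
        return self

    # -- reporting ---------------------------------------------------------
    def fold_table(self) -> pd.DataFrame:
        """Per-fold table: Fold, ARE, SE, CI, p-value, Region."""
        rows = []
        for f in self.fold_results_:
            rows.append(
                {
                    "Fold": f.fold_id + 1,
                    "ARE": f.fit.psi_hat if f.estimate_available else np.nan,
                    "SE": f.fit.se if f.estimate_available else np.nan,
                    "Lower CI": f.fit.ci_low if f.estimate_available else np.nan,
                    "Upper CI": f.fit.ci_high if f.estimate_available else np.nan,
                    "p-value": f.fit.p_value if f.estimate_available else np.nan,
                    "Region": str(f.region) if f.region is not None else "(none)",
                }
            )
        return pd.DataFrame(rows)

    def pooled_table(self) -> pd.DataFrame:
        """Pooled per-signature table mirroring the fold-group summary."""
        if self.pooled_.status != "ok":
            return pd.DataFrame(
                [{"Solution": "(none)", "Status": "no consistent region found"}]
            )
        rows = []
        for i, g in enumerate(self.pooled_.groups, start=1):
            rows.append(
                {
                    "Solution": f"({i}) " + "-".join(g.signature),
                    "ARE": g.are,
                    "SE": g.se,
                    "Lower CI": g.ci_low,
                    "Upper CI": g.ci_high,
                    "p-value": g.p_value,
                    "Region": g.region_label,
                    "Prop. folds": g.proportion_folds,
                }
            )
        return pd.DataFrame(rows)
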