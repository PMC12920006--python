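"""Greedy (and optional exhaustive) targeted recursive partitioning.

Each node enumerates candidate splits ``T = 1{A_j <= s}`` over the
exposure coordinates.  A split is kept only when

* both children hold at least ``min_node`` observations,
* the estimated split propensity ``pi_i = P(T=1 | W_i)`` lies inside
  ``[epsilon, 1 - epsilon]`` for every observation (empirical positivity),
* the targeted mean of the child in the objective direction differs from
  the parent mean with a two-sided Wald p-value below ``alpha``.

Child means are debiased with the one-dimensional TMLE fluctuation from
:mod:`aretree.tmle`; the in-tree nuisance fits are deliberately simple and
fast (a linear outcome sketch and a shallow-tree stratified propensity)
— reported inference never comes from the tree, only from the fold-level
cross-validated TMLE.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Literal

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.linear_model import LogisticRegression
from sklearn.tree import DecisionTreeRegressor

from .regions import MixtureDataset, Operator, Region, ThresholdRule, normalize_region
from .tmle import FluctuationError, OutcomeScale, scale_outcome, tmle_node_mean
from scipy import stats

__all__ = [
    "TreeConfig",
    "SplitCandidate",
    "TreeNode",
    "enumerate_thresholds",
    "check_positivity",
    "evaluate_split",
    "build_tree_greedy",
    "search_exhaustive",
    "extract_region",
    "RegionTree",
]

EPSILON_RANGE = (0.001, 0.05)  # recommended positivity-bound range


@dataclass
class TreeConfig:
    """Tuning parameters of the partitioning search."""

    max_depth: int = 3
    min_node: int = 10
    epsilon: float = 0.01
    alpha: float = 0.05
    objective: Literal["min", "max"] = "max"
    exhaustive: bool = False
    threshold_strategy: Literal["unique", "rounded", "quantile"] = "rounded"
    threshold_param: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.min_node < 2:
            raise ValueError("min_node must be >= 2")
        if not (0.0 < self.epsilon < 0.5):
            raise ValueError("epsilon must lie in (0, 0.5)")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.objective not in ("min", "max"):
            raise ValueError("objective must be 'min' or 'max'")


@dataclass
class SplitCandidate:
    """One evaluated candidate threshold with its filter decision."""

    exposure: str
    cutpoint: float
    n_left: int = 0
    n_right: int = 0
    theta_left: float = np.nan
    theta_right: float = np.nan
    se_left: float = np.nan
    se_right: float = np.nan
    p_left: float = np.nan
    p_right: float = np.nan
    pi_min: float = np.nan
    pi_max: float = np.nan
    improving_arm: str | None = None
    score: float = np.nan
    valid: bool = False
    reason: str = ""

    def trace_record(self) -> dict:
        return {
            "exposure": self.exposure,
            "cutpoint": self.cutpoint,
            "n_left": self.n_left,
            "n_right": self.n_right,
            "theta_left": self.theta_left,
            "theta_right": self.theta_right,
            "p_left": self.p_left,
            "p_right": self.p_right,
            "pi_min": self.pi_min,
            "pi_max": self.pi_max,
            "valid": self.valid,
            "reason": self.reason,
        }


@dataclass
class TreeNode:
    """Node of the fitted partition tree.

    ``node_estimate`` is the (targeted) mean handed down by the parent —
    the sample mean of Y at the root — matching the convention that a leaf
    reports its parent-passed mean.
    """

    depth: int
    region: Region
    parent_mean: float
    n: int
    node_estimate: float
    split: SplitCandidate | None = None
    children: tuple["TreeNode", "TreeNode"] | None = None
    n_valid_candidates: int = 0

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def leaves(self) -> Iterator["TreeNode"]:
        if self.is_leaf:
            yield self
        else:
            for child in self.children:
                yield from child.leaves()

    @property
    def max_depth_reached(self) -> int:
        if self.is_leaf:
            return self.depth
        return max(c.max_depth_reached for c in self.children)


def enumerate_thresholds(values: np.ndarray, strategy: str = "unique", param: int | None = None) -> np.ndarray:
    """Sorted candidate cutpoints, excluding the maximum observed value.

    ``rounded`` rounds to ``param`` decimals first; ``quantile`` returns at
    most ``param`` interior empirical quantiles.  A constant column yields
    an empty list.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return np.array([])
    if strategy == "rounded":
        decimals = 1 if param is None else int(param)
        values = np.round(values, decimals)
        cuts = np.unique(values)
    elif strategy == "unique":
        cuts = np.unique(values)
    elif strategy == "quantile":
        q = 20 if param is None else int(param)
        probs = np.arange(1, q + 1) / (q + 1)
        cuts = np.unique(np.quantile(values, probs))
    else:
        raise ValueError(f"unknown threshold strategy {strategy!r}")
    vmax = np.max(values)
    return cuts[cuts < vmax]


def check_positivity(
    T: np.ndarray,
    W: np.ndarray,
    epsilon: float,
    propensity_estimator: BaseEstimator | None = None,
) -> tuple[bool, tuple[float, float]]:
    """Estimate ``pi_i = P(T=1|W_i)`` and check it stays in [eps, 1-eps]."""
    T = np.asarray(T).ravel()
    if len(np.unique(T)) < 2:
        p = float(np.mean(T))
        return False, (p, p)
    W = np.asarray(W, dtype=float)
    if W.ndim == 1:
        W = W.reshape(-1, 1)
    if W.size == 0:
        W = np.zeros((len(T), 1))
    est = propensity_estimator or LogisticRegression(max_iter=1000)
    est.fit(W, T)
    pi = est.predict_proba(W)[:, 1]
    lo, hi = float(np.min(pi)), float(np.max(pi))
    return bool(lo >= epsilon and hi <= 1 - epsilon), (lo, hi)


# -- fast per-node machinery --------------------------------------------------


class _NodeContext:
    """Precomputed quantities shared by all candidate splits of one node.

    Both in-tree nuisances are *cross-fitted* over two canonical halves of
    the node, so the split test's influence-function standard errors are
    honest even in small nodes:

    * the outcome sketch is a per-arm linear fit; cumulative X'X / X'y
      along the sorted exposure give the fit on any prefix {A_j <= s}
      (and its complement) of either half without refitting;
    * the propensity is piecewise constant on strata found by a shallow
      regression tree of the exposure on W, with within-stratum ECDFs
      giving P(A_j <= s | stratum) for all cutpoints in one pass.

    Halves alternate in the lexicographic order of the rows, so the
    assignment does not depend on row order.
    """

    def __init__(self, A: np.ndarray, W: np.ndarray, Y_scaled: np.ndarray, exposure_names: list[str]):
        self.A = A
        self.W = W
        self.Ys = Y_scaled
        self.exposure_names = exposure_names
        self.n = len(Y_scaled)
        self.X = np.column_stack([np.ones(self.n), W]) if W.size else np.ones((self.n, 1))
        canon = np.lexsort(np.column_stack([self.X[:, 1:], A, Y_scaled]).T[::-1])
        half = np.empty(self.n, dtype=bool)
        half[canon] = (np.arange(self.n) % 2).astype(bool)
        self.half = half
        self._ols_cache: dict[int, tuple] = {}
        self._prop_cache: dict[int, tuple] = {}

    # -- outcome sketch ----------------------------------------------------

    def _ols_stats(self, j: int):
        if j not in self._ols_cache:
            order = np.argsort(self.A[:, j], kind="stable")
            Xs, ys = self.X[order], self.Ys[order]
            hs = self.half[order]
            xx = np.einsum("ni,nj->nij", Xs, Xs)
            xy = Xs * ys[:, None]
            stats_per_half = []
            for h in (False, True):
                mask = (hs == h)[:, None, None]
                stats_per_half.append(
                    (
                        np.cumsum(xx * mask, axis=0),
                        np.cumsum(xy * (hs == h)[:, None], axis=0),
                        np.cumsum(hs == h),
                    )
                )
            self._ols_cache[j] = (self.A[order, j], stats_per_half)
        return self._ols_cache[j]

    def arm_outcome_fits(self, j: int, s: float) -> tuple[np.ndarray, np.ndarray]:
        """Cross-fitted per-arm linear outcome predictions (Q_left, Q_right)."""
        sorted_vals, per_half = self._ols_stats(j)
        k = int(np.searchsorted(sorted_vals, s, side="right"))
        dim = self.X.shape[1]
        ridge = 1e-8 * np.eye(dim)
        Ql = np.empty(self.n)
        Qr = np.empty(self.n)
        for h in (False, True):
            cum_xx, cum_xy, cum_ct = per_half[h]
            xx_l, xy_l, ct_l = cum_xx[k - 1], cum_xy[k - 1], cum_ct[k - 1]
            xx_r, xy_r = cum_xx[-1] - xx_l, cum_xy[-1] - xy_l
            ct_r = cum_ct[-1] - ct_l
            # model trained on half h predicts rows of the opposite half
            rows = self.half != h
            if ct_l >= dim + 2:
                beta_l = np.linalg.solve(xx_l + ridge, xy_l)
            else:
                tot_l = per_half[0][0][k - 1] + per_half[1][0][k - 1]
                tot_ly = per_half[0][1][k - 1] + per_half[1][1][k - 1]
                beta_l = np.linalg.solve(tot_l + ridge, tot_ly)
            if ct_r >= dim + 2:
                beta_r = np.linalg.solve(xx_r + ridge, xy_r)
            else:
                tot_r = (
                    per_half[0][0][-1]
                    + per_half[1][0][-1]
                    - per_half[0][0][k - 1]
                    - per_half[1][0][k - 1]
                )
                tot_ry = (
                    per_half[0][1][-1]
                    + per_half[1][1][-1]
                    - per_half[0][1][k - 1]
                    - per_half[1][1][k - 1]
                )
                beta_r = np.linalg.solve(tot_r + ridge, tot_ry)
            Ql[rows] = self.X[rows] @ beta_l
            Qr[rows] = self.X[rows] @ beta_r
        return np.clip(Ql, 0.0, 1.0), np.clip(Qr, 0.0, 1.0)

    # -- propensity --------------------------------------------------------

    def _prop_models(self, j: int):
        """Per half: (stratum id for every row, sorted training values per stratum)."""
        if j not in self._prop_cache:
            col = self.A[:, j]
            models = []
            for h in (False, True):
                tr = self.half == h
                n_tr = int(tr.sum())
                if self.W.size == 0 or n_tr < 40:
                    ids = np.zeros(self.n, dtype=int)
                    groups = [np.sort(col[tr])]
                else:
                    tree = DecisionTreeRegressor(
                        max_depth=2, min_samples_leaf=max(10, n_tr // 20), random_state=0
                    )
                    tree.fit(self.W[tr], col[tr])
                    leaves_all = tree.apply(self.W)
                    uniq, ids = np.unique(leaves_all, return_inverse=True)
                    groups = [np.sort(col[tr & (ids == g)]) for g in range(len(uniq))]
                models.append((ids, groups))
            self._prop_cache[j] = models
        return self._prop_cache[j]

    def propensity(self, j: int, s: float) -> np.ndarray:
        """Cross-fitted pi_i = P(A_j <= s | W_i); rows of one half are
        scored by the stratum ECDFs of the other half."""
        models = self._prop_models(j)
        pi = np.empty(self.n)
        for h in (False, True):
            ids, groups = models[h]
            props = np.array(
                [
                    np.searchsorted(g, s, side="right") / len(g) if len(g) else np.nan
                    for g in groups
                ]
            )
            rows = self.half != h
            pi[rows] = props[ids[rows]]
        # strata empty on the training side fall back to the marginal
        if np.isnan(pi).any():
            marginal = float(np.mean(self.A[:, j] <= s))
            pi = np.where(np.isnan(pi), marginal, pi)
        return pi


def _evaluate_candidate(
    ctx: _NodeContext,
    j: int,
    s: float,
    parent_mean: float,
    config: TreeConfig,
    scale: OutcomeScale,
) -> SplitCandidate:
    cand = SplitCandidate(exposure=ctx.exposure_names[j], cutpoint=float(s))
    col = ctx.A[:, j]
    T = (col <= s).astype(int)
    cand.n_left = int(T.sum())
    cand.n_right = ctx.n - cand.n_left
    if min(cand.n_left, cand.n_right) < config.min_node:
        cand.reason = "min_node"
        return cand

    pi = ctx.propensity(j, s)
    cand.pi_min = float(pi.min())
    cand.pi_max = float(pi.max())
    if cand.pi_min < config.epsilon or cand.pi_max > 1 - config.epsilon:
        cand.reason = "positivity"
        return cand

    g1 = np.clip(pi, config.epsilon, 1 - config.epsilon)
    g0 = 1.0 - g1
    Ql, Qr = ctx.arm_outcome_fits(j, s)
    try:
        th_l, se_l, _ = tmle_node_mean(Ql, Ql, T, g1, ctx.Ys, 1, scale)
        th_r, se_r, _ = tmle_node_mean(Qr, Qr, T, g0, ctx.Ys, 0, scale)
    except FluctuationError:
        cand.reason = "fluctuation_error"
        return cand
    cand.theta_left, cand.theta_right = th_l, th_r
    cand.se_left, cand.se_right = se_l, se_r

    def wald_p(theta: float, se: float) -> float:
        if se <= 0:
            return 0.0 if theta != parent_mean else 1.0
        return float(2 * stats.norm.sf(abs(theta - parent_mean) / se))

    cand.p_left = wald_p(th_l, se_l)
    cand.p_right = wald_p(th_r, se_r)

    if config.objective == "max":
        improving = "left" if th_l >= th_r else "right"
    else:
        improving = "left" if th_l <= th_r else "right"
    theta_imp = th_l if improving == "left" else th_r
    p_imp = cand.p_left if improving == "left" else cand.p_right
    cand.improving_arm = improving
    cand.score = theta_imp

    improves = theta_imp > parent_mean if config.objective == "max" else theta_imp < parent_mean
    if not improves:
        cand.reason = "no_improvement"
        return cand
    if p_imp >= config.alpha:
        cand.reason = "significance"
        return cand
    cand.valid = True
    cand.reason = "ok"
    return cand


def _node_candidates(
    ctx: _NodeContext, parent_mean: float, config: TreeConfig, scale: OutcomeScale
) -> list[SplitCandidate]:
    out = []
    for j in range(ctx.A.shape[1]):
        cuts = enumerate_thresholds(ctx.A[:, j], config.threshold_strategy, config.threshold_param)
        for s in cuts:
            out.append(_evaluate_candidate(ctx, j, float(s), parent_mean, config, scale))
    return out


def _improving_child_size(c: SplitCandidate) -> int:
    return c.n_left if c.improving_arm == "left" else c.n_right


def _improving_child_se(c: SplitCandidate) -> float:
    return c.se_left if c.improving_arm == "left" else c.se_right


def _best_candidate(candidates: list[SplitCandidate], config: TreeConfig, exposure_names: list[str]) -> SplitCandidate | None:
    """Select the split whose improving child has the extremal targeted mean.

    A one-standard-error rule guards against the winner's curse of a raw
    argmax over many noisy candidate means, which drifts toward small,
    high-variance children whose means overshoot by chance.  Among valid
    splits whose score is within one standard error of the extremal
    score, the split with the *largest* improving child is preferred —
    the least restrictive, best-supported boundary among statistically
    indistinguishable candidates.  For two candidates on the same
    exposure the children are nested, so the SE of the score difference
    is sqrt(|se_a^2 - se_b^2|); across exposures the conservative
    sqrt(se_a^2 + se_b^2) is used.  Remaining ties break by exposure
    column order, then smaller cutpoint.
    """
    valid = [c for c in candidates if c.valid]
    if not valid:
        return None
    sign = 1.0 if config.objective == "max" else -1.0
    extremal = max(valid, key=lambda c: sign * c.score)

    se_e = _improving_child_se(extremal)

    def band(c: SplitCandidate) -> float:
        # conservative two-sample band; generous enough to absorb the
        # selection overshoot of the extremal candidate
        return float(np.hypot(_improving_child_se(c), se_e))

    contenders = [c for c in valid if sign * (extremal.score - c.score) <= band(c)]
    return min(
        contenders,
        key=lambda c: (
            -_improving_child_size(c),
            exposure_names.index(c.exposure),
            c.cutpoint,
        ),
    )


def evaluate_split(
    data: MixtureDataset,
    exposure: str,
    cutpoint: float,
    parent_mean: float,
    config: TreeConfig | None = None,
    scale: OutcomeScale | None = None,
) -> SplitCandidate:
    """Evaluate one candidate split on one node's data."""
    config = config or TreeConfig()
    if scale is None:
        _, scale = scale_outcome(data.Y)
    ctx = _NodeContext(
        data.A.to_numpy(dtype=float),
        data.W.to_numpy(dtype=float) if data.p else np.empty((data.n, 0)),
        scale.forward(data.Y),
        data.exposure_names,
    )
    j = data.exposure_names.index(exposure)
    return _evaluate_candidate(ctx, j, float(cutpoint), parent_mean, config, scale)


def build_tree_greedy(
    data: MixtureDataset,
    config: TreeConfig | None = None,
    scale: OutcomeScale | None = None,
    trace: list | None = None,
) -> TreeNode:
    """Algorithmic core: recursively partition, keeping a full split trace.

    The root's parent mean is the sample mean of Y; each child recursion
    receives that child's targeted mean as its parent mean.
    """
    config = config or TreeConfig()
    if scale is None:
        _, scale = scale_outcome(data.Y)
    A = data.A.to_numpy(dtype=float)
    W = data.W.to_numpy(dtype=float) if data.p else np.empty((data.n, 0))
    Ys = scale.forward(data.Y)
    names = data.exposure_names

    def recurse(idx: np.ndarray, depth: int, parent_mean: float, region_rules: tuple) -> TreeNode:
        region = normalize_region(region_rules)
        node = TreeNode(depth, region, parent_mean, len(idx), node_estimate=parent_mean)
        if depth >= config.max_depth:
            return node
        ctx = _NodeContext(A[idx], W[idx], Ys[idx], names)
        candidates = _node_candidates(ctx, parent_mean, config, scale)
        node.n_valid_candidates = sum(c.valid for c in candidates)
        if trace is not None:
            trace.append(
                {
                    "depth": depth,
                    "region": str(region),
                    "n": len(idx),
                    "parent_mean": parent_mean,
                    "candidates": [c.trace_record() for c in candidates],
                }
            )
        best = _best_candidate(candidates, config, names)
        if best is None:
            return node
        node.split = best
        j = names.index(best.exposure)
        left_mask = A[idx, j] <= best.cutpoint
        left_idx, right_idx = idx[left_mask], idx[~left_mask]
        left_rules = region_rules + (ThresholdRule(best.exposure, Operator.LE, best.cutpoint),)
        right_rules = region_rules + (ThresholdRule(best.exposure, Operator.GT, best.cutpoint),)
        node.children = (
            recurse(left_idx, depth + 1, best.theta_left, left_rules),
            recurse(right_idx, depth + 1, best.theta_right, right_rules),
        )
        return node

    return recurse(np.arange(data.n), 0, float(np.mean(data.Y)), ())


def extract_region(root: TreeNode, objective: str = "max") -> Region:
    """Region of the leaf with the extremal node estimate (rules normalized).

    A single-leaf tree yields the empty region (full exposure space) —
    "no region found".
    """
    leaves = list(root.leaves())
    if objective == "max":
        best = max(leaves, key=lambda lf: lf.node_estimate)
    else:
        best = min(leaves, key=lambda lf: lf.node_estimate)
    return normalize_region(best.region.rules)


def search_exhaustive(
    data: MixtureDataset,
    config: TreeConfig | None = None,
    scale: OutcomeScale | None = None,
) -> tuple[Region, float]:
    """Branch on *every* valid threshold, returning the best terminal leaf.

    Exponential in depth and candidate count; intended for few exposures
    with coarse cutpoint grids.
    """
    config = config or TreeConfig()
    if scale is None:
        _, scale = scale_outcome(data.Y)
    A = data.A.to_numpy(dtype=float)
    W = data.W.to_numpy(dtype=float) if data.p else np.empty((data.n, 0))
    Ys = scale.forward(data.Y)
    names = data.exposure_names
    # leaf records: (region, estimate, se of the estimate, leaf size)
    leaves: list[tuple[Region, float, float, int]] = []

    def recurse(idx: np.ndarray, depth: int, parent_mean: float, parent_se: float, region_rules: tuple) -> None:
        if depth >= config.max_depth:
            leaves.append((normalize_region(region_rules), parent_mean, parent_se, len(idx)))
            return
        ctx = _NodeContext(A[idx], W[idx], Ys[idx], names)
        candidates = [c for c in _node_candidates(ctx, parent_mean, config, scale) if c.valid]
        if not candidates:
            leaves.append((normalize_region(region_rules), parent_mean, parent_se, len(idx)))
            return
        for c in candidates:
            j = names.index(c.exposure)
            left_mask = A[idx, j] <= c.cutpoint
            recurse(
                idx[left_mask],
                depth + 1,
                c.theta_left,
                c.se_left,
                region_rules + (ThresholdRule(c.exposure, Operator.LE, c.cutpoint),),
            )
            recurse(
                idx[~left_mask],
                depth + 1,
                c.theta_right,
                c.se_right,
                region_rules + (ThresholdRule(c.exposure, Operator.GT, c.cutpoint),),
            )

    root_se = float(np.std(data.Y, ddof=1) / np.sqrt(data.n)) if data.n > 1 else 0.0
    recurse(np.arange(data.n), 0, float(np.mean(data.Y)), root_se, ())
    # same one-SE selection as the greedy search: among leaves whose
    # estimate is within one (two-sample) SE of the extremal leaf, prefer
    # the largest, best-supported one
    sign = 1.0 if config.objective == "max" else -1.0
    extremal = max(leaves, key=lambda t: sign * t[1])
    contenders = [
        t for t in leaves if sign * (extremal[1] - t[1]) <= float(np.hypot(t[2], extremal[2]))
    ]
    best = max(contenders, key=lambda t: t[3])
    return best[0], best[1]


class RegionTree(BaseEstimator):
    """Scikit-learn style wrapper around the partitioning search.

    Parameters mirror :class:`TreeConfig`; ``exposures`` names the columns
    of X that are exposures (remaining columns are covariates).

    Attributes (after ``fit``): ``root_`` (the :class:`TreeNode` tree),
    ``region_`` (extremal-leaf region), ``trace_`` (per-split audit log).
    """

    def __init__(
        self,
        exposures=None,
        max_depth=3,
        min_node=10,
        epsilon=0.01,
        alpha=0.05,
        objective="max",
        exhaustive=False,
        threshold_strategy="rounded",
        threshold_param=1,
        random_state=None,
    ):
        self.exposures = exposures
        self.max_depth = max_depth
        self.min_node = min_node
        self.epsilon = epsilon
        self.alpha = alpha
        self.objective = objective
        self.exhaustive = exhaustive
        self.threshold_strategy = threshold_strategy
        self.threshold_param = threshold_param
        self.random_state = random_state

    def _config(self) -> TreeConfig:
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

    def fit(self, X, y):
        import pandas as pd

        X = pd.DataFrame(X)
        exposures = list(self.exposures) if self.exposures is not None else list(X.columns)
        covariates = [c for c in X.columns if c not in exposures]
        data = MixtureDataset(X[covariates], X[exposures], np.asarray(y, dtype=float))
        config = self._config()
        self.trace_ = []
        if self.exhaustive:
            self.region_, self.best_leaf_estimate_ = search_exhaustive(data, config)
            self.root_ = None
        else:
            self.root_ = build_tree_greedy(data, config, trace=self.trace_)
            self.region_ = extract_region(self.root_, config.objective)
            best = (max if config.objective == "max" else min)(
                self.root_.leaves(), key=lambda lf: lf.node_estimate
            )
            self.best_leaf_estimate_ = best.node_estimate
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        """Binary region membership for new rows."""
        import pandas as pd

        from .regions import membership

        return membership(self.region_, pd.DataFrame(X)).reshape(-1, 1)
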