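"""Synthetic data-generating processes and oracle ground truth.

Three study designs are emulated:

* a *discrete* design — two exposures on a confounded 5x5 grid with a
  quadratic/interaction outcome surface, where every candidate level
  rectangle can be enumerated exactly;
* a *continuous* design — correlated continuous exposures driven by
  covariates, with a known threshold region ``{A1 > 0.5, A2 < -0.2}``
  that raises the outcome;
* a *null* design — exposures confounded by covariates but an outcome
  strictly independent of them, for error-control studies.

Ground-truth regional means follow the weighted-average identity

    Q_A(1, w) = sum_{a in A} mu0(a, w) p(a|w) / sum_{a in A} p(a|w),

integrated over the covariate law (exactly over grid cells for the
discrete design; by Monte Carlo over (W, A|W) otherwise).  The
attributable regional effect of a region is ``E[Q_A(1,W)] - E[Y]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable

import numpy as np
import pandas as pd

from .regions import MixtureDataset, Operator, Region, ThresholdRule, membership

__all__ = [
    "DiscreteDGPSpec",
    "ContinuousDGPSpec",
    "NullDGPSpec",
    "GroundTruth",
    "generate",
    "true_regional_mean",
    "true_are",
    "oracle_region_discrete",
    "RegionProbabilityError",
]

_SIGMA = np.array([[1.0, 0.5], [0.5, 1.0]])


class RegionProbabilityError(ValueError):
    """The region has (near-)zero probability under the generating law."""


@dataclass(frozen=True)
class GroundTruth:
    """Oracle quantities for a (spec, region) pair, with MC uncertainty."""

    region: Region
    regional_mean: float
    regional_mean_se: float
    ey: float
    ey_se: float
    are: float
    are_se: float


# ---------------------------------------------------------------------------
# discrete 5x5 grid design


@dataclass(frozen=True)
class DiscreteDGPSpec:
    """Confounded 5x5 exposure grid with a quadratic/interaction outcome.

    Covariates mimic age/BMI/sex; the 25 grid cells are sampled from a
    multinomial-logit model in the standardized covariates whose
    coefficient matrix is drawn once from N(0, ``sigma_coef``) under
    ``coef_seed`` and re-drawn (advancing the seed) until every cell
    keeps probability >= 1e-4 across a reference covariate sample, so
    population positivity holds by construction.
    """

    sigma_coef: float = 0.5
    coef_seed: int = 20240901
    noise_sd: float = 0.1
    levels: int = 5
    min_cell_prob: float = 1e-4
    mu0_override: Callable | None = None

    # -- covariates -------------------------------------------------------
    def draw_covariates(self, n: int, rng: np.random.Generator) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "W1": rng.normal(37.0, 3.0, n),
                "W2": rng.normal(20.0, 1.0, n),
                "W3": rng.binomial(1, 0.5, n).astype(float),
            }
        )

    @staticmethod
    def _standardize(W: pd.DataFrame) -> np.ndarray:
        return np.column_stack(
            [
                (W["W1"].to_numpy() - 37.0) / 3.0,
                (W["W2"].to_numpy() - 20.0) / 1.0,
                (W["W3"].to_numpy() - 0.5) / 0.5,
            ]
        )

    @property
    def grid(self) -> np.ndarray:
        """(25, 2) array of (A1, A2) cell coordinates."""
        lv = np.arange(1, self.levels + 1)
        a1, a2 = np.meshgrid(lv, lv, indexing="ij")
        return np.column_stack([a1.ravel(), a2.ravel()]).astype(float)

    def coefficients(self) -> np.ndarray:
        return _discrete_coefficients(self.sigma_coef, self.coef_seed, self.levels, self.min_cell_prob)

    def cell_probs(self, W: pd.DataFrame) -> np.ndarray:
        """(n, 25) conditional cell probabilities P(A = a | W)."""
        X = np.column_stack([np.ones(len(W)), self._standardize(W)])
        logits = X @ self.coefficients().T
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        return p / p.sum(axis=1, keepdims=True)

    def mu0(self, a: np.ndarray, W: pd.DataFrame) -> np.ndarray:
        """True conditional mean surface; broadcasts cells against rows.

        ``a`` has shape (c, 2); returns (n, c).
        """
        if self.mu0_override is not None:
            return self.mu0_override(a, W)
        a1, a2 = a[:, 0][None, :], a[:, 1][None, :]
        exposure_part = 0.2 * a1**2 + 0.5 * a1 * a2 + 0.5 * a2**2
        cov_part = (0.2 * W["W1"].to_numpy() + 0.4 * W["W3"].to_numpy())[:, None]
        return exposure_part + cov_part

    def generate(self, n: int, rng: np.random.Generator) -> MixtureDataset:
        W = self.draw_covariates(n, rng)
        probs = self.cell_probs(W)
        u = rng.random(n)
        cells = (u[:, None] > np.cumsum(probs, axis=1)).sum(axis=1)
        A = pd.DataFrame(self.grid[cells], columns=["A1", "A2"])
        mu = self.mu0(self.grid, W)[np.arange(n), cells]
        Y = mu + rng.normal(0.0, self.noise_sd, n)
        return MixtureDataset(W, A, Y)


@lru_cache(maxsize=8)
def _discrete_coefficients(sigma_coef: float, coef_seed: int, levels: int, min_cell_prob: float) -> np.ndarray:
    n_cells = levels * levels
    ref_rng = np.random.default_rng(1234567)
    W_ref = pd.DataFrame(
        {
            "W1": ref_rng.normal(37.0, 3.0, 2000),
            "W2": ref_rng.normal(20.0, 1.0, 2000),
            "W3": ref_rng.binomial(1, 0.5, 2000).astype(float),
        }
    )
    X = np.column_stack([np.ones(len(W_ref)), DiscreteDGPSpec._standardize(W_ref)])
    for attempt in range(1000):
        rng = np.random.default_rng(coef_seed + attempt)
        B = rng.normal(0.0, sigma_coef, size=(n_cells, 4))
        logits = X @ B.T
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        p /= p.sum(axis=1, keepdims=True)
        if p.min() >= min_cell_prob:
            return B
    raise RuntimeError("could not draw a positivity-respecting coefficient matrix")


# ---------------------------------------------------------------------------
# continuous threshold design


@dataclass(frozen=True)
class ContinuousDGPSpec:
    """Correlated continuous exposures with a known threshold effect.

    Exposure conditional means are small linear functions of the
    standardized covariates (coefficients ``alpha1``/``alpha2``) with zero
    intercepts, so marginals stay near standard normal and the outcome
    thresholds 0.5 and -0.2 are interior.  Exposures are rounded to
    ``round_decimals`` before the outcome is formed, so the threshold
    signal lives on the observed (rounded) grid.
    """

    alpha1: tuple[float, float, float] = (0.1, 0.1, 0.1)
    alpha2: tuple[float, float, float] = (0.1, -0.1, 0.0)
    noise_sd: float = 0.1
    round_decimals: int = 1
    mu0_override: Callable | None = None

    def draw_covariates(self, n: int, rng: np.random.Generator) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "W1": rng.normal(37.0, 3.0, n),
                "W2": rng.normal(20.0, 1.0, n),
                "W3": rng.binomial(1, 0.5, n).astype(float),
            }
        )

    @staticmethod
    def _standardize(W: pd.DataFrame) -> np.ndarray:
        return DiscreteDGPSpec._standardize(W)

    def exposure_means(self, W: pd.DataFrame) -> np.ndarray:
        Z = self._standardize(W)
        return np.column_stack([Z @ np.asarray(self.alpha1), Z @ np.asarray(self.alpha2)])

    def draw_exposures(self, W: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
        mu = self.exposure_means(W)
        noise = rng.multivariate_normal(np.zeros(2), _SIGMA, size=len(W))
        A = np.round(mu + noise, self.round_decimals)
        return pd.DataFrame(A, columns=["A1", "A2"])

    def mu0(self, a: np.ndarray, W: pd.DataFrame) -> np.ndarray:
        """(n, c) conditional mean for cells ``a`` of shape (c, 2)."""
        if self.mu0_override is not None:
            return self.mu0_override(a, W)
        a1, a2 = a[:, 0][None, :], a[:, 1][None, :]
        exposure_part = 3.0 * (a1 > 0.5) + 2.0 * (a2 < -0.2)
        cov_part = (0.2 * W["W1"].to_numpy() + 0.4 * W["W2"].to_numpy())[:, None]
        return exposure_part + cov_part

    def mu0_rows(self, A: pd.DataFrame, W: pd.DataFrame) -> np.ndarray:
        a = A.to_numpy(dtype=float)
        if self.mu0_override is not None:
            return np.diagonal(self.mu0_override(a, W)) if a.ndim > 1 else self.mu0_override(a, W)
        return (
            3.0 * (a[:, 0] > 0.5)
            + 2.0 * (a[:, 1] < -0.2)
            + 0.2 * W["W1"].to_numpy()
            + 0.4 * W["W2"].to_numpy()
        )

    def generate(self, n: int, rng: np.random.Generator) -> MixtureDataset:
        W = self.draw_covariates(n, rng)
        A = self.draw_exposures(W, rng)
        Y = self.mu0_rows(A, W) + rng.normal(0.0, self.noise_sd, n)
        return MixtureDataset(W, A, Y)


# ---------------------------------------------------------------------------
# null design


@dataclass(frozen=True)
class NullDGPSpec:
    """Exposures confounded by covariates; outcome independent of them."""

    noise_sd: float = 5.0
    round_decimals: int = 1
    mu0_override: Callable | None = None

    def draw_covariates(self, n: int, rng: np.random.Generator) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "W1": rng.normal(50.0, 10.0, n),
                "W2": rng.normal(25.0, 3.0, n),
                "W3": rng.binomial(1, 0.5, n).astype(float),
            }
        )

    def exposure_means(self, W: pd.DataFrame) -> np.ndarray:
        w1, w2, w3 = (W[c].to_numpy() for c in ("W1", "W2", "W3"))
        return np.column_stack([0.3 * w1 + 0.1 * w2 + 0.2 * w3, -0.1 * w1 + 0.2 * w2])

    def draw_exposures(self, W: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
        mu = self.exposure_means(W)
        noise = rng.multivariate_normal(np.zeros(2), _SIGMA, size=len(W))
        return pd.DataFrame(np.round(mu + noise, self.round_decimals), columns=["A1", "A2"])

    def mu0(self, a: np.ndarray, W: pd.DataFrame) -> np.ndarray:
        if self.mu0_override is not None:
            return self.mu0_override(a, W)
        n, c = len(W), len(a)
        return np.tile((0.2 * W["W3"].to_numpy())[:, None], (1, c))

    def mu0_rows(self, A: pd.DataFrame, W: pd.DataFrame) -> np.ndarray:
        return 0.2 * W["W3"].to_numpy()

    def generate(self, n: int, rng: np.random.Generator) -> MixtureDataset:
        W = self.draw_covariates(n, rng)
        A = self.draw_exposures(W, rng)
        Y = self.mu0_rows(A, W) + rng.normal(0.0, self.noise_sd, n)
        return MixtureDataset(W, A, Y)


# ---------------------------------------------------------------------------
# public operations

AnySpec = DiscreteDGPSpec | ContinuousDGPSpec | NullDGPSpec


def generate(spec: AnySpec, n: int, seed: int | None = None) -> MixtureDataset:
    """i.i.d. draws from the spec's generating law, deterministic per seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return spec.generate(n, np.random.default_rng(seed))


def _region_cell_mask(spec: DiscreteDGPSpec, region: Region) -> np.ndarray:
    grid = pd.DataFrame(spec.grid, columns=["A1", "A2"])
    return membership(region, grid).astype(bool)


def true_regional_mean(
    spec: AnySpec,
    region: Region,
    n_mc: int = 20000,
    seed: int | None = None,
    n_inner: int = 200,
) -> tuple[float, float]:
    """Oracle E[Q_A(1, W)] with a Monte-Carlo standard error.

    Discrete spec: exact enumeration over grid cells, MC only over W.
    Continuous specs: MC over W with within-draw rejection over A | W.
    """
    rng = np.random.default_rng(seed)
    if isinstance(spec, DiscreteDGPSpec):
        mask = _region_cell_mask(spec, region)
        if not mask.any():
            raise RegionProbabilityError("region contains no grid cells")
        W = spec.draw_covariates(n_mc, rng)
        P = spec.cell_probs(W)
        mu = spec.mu0(spec.grid, W)
        denom = P[:, mask].sum(axis=1)
        if denom.mean() < 1e-6:
            raise RegionProbabilityError("region probability is numerically zero")
        q = (P[:, mask] * mu[:, mask]).sum(axis=1) / denom
        return float(q.mean()), float(q.std(ddof=1) / np.sqrt(n_mc))

    W = spec.draw_covariates(n_mc, rng)
    mu_a = spec.exposure_means(W)
    noise = rng.multivariate_normal(np.zeros(2), _SIGMA, size=(n_mc, n_inner))
    draws = np.round(mu_a[:, None, :] + noise, spec.round_decimals)
    flat = pd.DataFrame(draws.reshape(-1, 2), columns=["A1", "A2"])
    member = membership(region, flat).reshape(n_mc, n_inner).astype(bool)
    counts = member.sum(axis=1)
    usable = counts > 0
    if usable.mean() < 0.5:
        raise RegionProbabilityError(
            f"region has near-zero probability ({usable.mean():.1%} of covariate draws usable)"
        )
    a1, a2 = draws[..., 0], draws[..., 1]
    if isinstance(spec, ContinuousDGPSpec) and spec.mu0_override is None:
        exposure_part = 3.0 * (a1 > 0.5) + 2.0 * (a2 < -0.2)
        cov_part = 0.2 * W["W1"].to_numpy() + 0.4 * W["W2"].to_numpy()
    elif isinstance(spec, NullDGPSpec) and spec.mu0_override is None:
        exposure_part = np.zeros_like(a1)
        cov_part = 0.2 * W["W3"].to_numpy()
    else:
        cells = draws.reshape(-1, 2)
        # generic but memory-heavy path for overridden surfaces: row-wise
        exposure_part = np.empty((n_mc, n_inner))
        for i in range(n_mc):
            exposure_part[i] = spec.mu0(draws[i], W.iloc[[i]])[0]
        cov_part = np.zeros(n_mc)
    mu_vals = exposure_part + cov_part[:, None]
    q = np.where(usable, (mu_vals * member).sum(axis=1) / np.maximum(counts, 1), np.nan)
    q = q[usable]
    return float(np.mean(q)), float(np.std(q, ddof=1) / np.sqrt(len(q)))


def _expected_outcome(spec: AnySpec, n_mc: int, rng: np.random.Generator) -> tuple[float, float]:
    if isinstance(spec, DiscreteDGPSpec):
        W = spec.draw_covariates(n_mc, rng)
        P = spec.cell_probs(W)
        mu = spec.mu0(spec.grid, W)
        ey_i = (P * mu).sum(axis=1)
        return float(ey_i.mean()), float(ey_i.std(ddof=1) / np.sqrt(n_mc))
    data = spec.generate(n_mc, rng)
    mu = spec.mu0_rows(data.A, data.W)
    return float(mu.mean()), float(mu.std(ddof=1) / np.sqrt(n_mc))


def true_are(
    spec: AnySpec,
    region: Region,
    n_mc: int = 20000,
    seed: int | None = None,
    n_inner: int = 200,
) -> GroundTruth:
    """Oracle ARE(region) = E[Q_region(1, W)] - E[Y], with MC errors."""
    ss = np.random.SeedSequence(seed)
    s1, s2 = (int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(2))
    qm, qm_se = true_regional_mean(spec, region, n_mc, s1, n_inner)
    ey, ey_se = _expected_outcome(spec, n_mc, np.random.default_rng(s2))
    return GroundTruth(
        region=region,
        regional_mean=qm,
        regional_mean_se=qm_se,
        ey=ey,
        ey_se=ey_se,
        are=qm - ey,
        are_se=float(np.hypot(qm_se, ey_se)),
    )


def level_rectangle(l1: int, u1: int, l2: int, u2: int, levels: int = 5) -> Region:
    """Region for the level rectangle {A1 in [l1,u1]} x {A2 in [l2,u2]}."""
    rules = []
    if l1 > 1:
        rules.append(ThresholdRule("A1", Operator.GT, float(l1 - 1)))
    if u1 < levels:
        rules.append(ThresholdRule("A1", Operator.LE, float(u1)))
    if l2 > 1:
        rules.append(ThresholdRule("A2", Operator.GT, float(l2 - 1)))
    if u2 < levels:
        rules.append(ThresholdRule("A2", Operator.LE, float(u2)))
    return Region(tuple(rules))


def oracle_region_discrete(
    spec: DiscreteDGPSpec,
    n_mc: int = 20000,
    seed: int | None = None,
    min_region_prob: float = 0.02,
    objective: str = "max",
) -> tuple[Region, GroundTruth]:
    """Enumerate all level rectangles and return the extremal feasible one.

    All ``levels^2 * (levels+1)^2 / 4`` contiguous rectangles (225 for a
    5-level grid) with marginal probability >= ``min_region_prob`` are
    scored by the exact-over-cells oracle integrator.
    """
    rng = np.random.default_rng(seed)
    W = spec.draw_covariates(n_mc, rng)
    P = spec.cell_probs(W)
    mu = spec.mu0(spec.grid, W)
    ey_i = (P * mu).sum(axis=1)
    ey, ey_se = float(ey_i.mean()), float(ey_i.std(ddof=1) / np.sqrt(n_mc))

    lv = spec.levels
    best = None
    sign = 1.0 if objective == "max" else -1.0
    for l1 in range(1, lv + 1):
        for u1 in range(l1, lv + 1):
            for l2 in range(1, lv + 1):
                for u2 in range(l2, lv + 1):
                    region = level_rectangle(l1, u1, l2, u2, lv)
                    mask = _region_cell_mask(spec, region)
                    denom = P[:, mask].sum(axis=1)
                    if denom.mean() < min_region_prob:
                        continue
                    q = (P[:, mask] * mu[:, mask]).sum(axis=1) / denom
                    val = float(q.mean())
                    if best is None or sign * val > sign * best[1]:
                        best = (region, val, float(q.std(ddof=1) / np.sqrt(n_mc)))
    if best is None:
        raise RegionProbabilityError("no rectangle meets the probability floor")
    region, qm, qm_se = best
    truth = GroundTruth(
        region=region,
        regional_mean=qm,
        regional_mean_se=qm_se,
        ey=ey,
        ey_se=ey_se,
        are=qm - ey,
        are_se=float(np.hypot(qm_se, ey_se)),
    )
    return region, truth
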