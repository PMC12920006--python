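"""Targeted maximum likelihood update for the treated-mean parameter.

Given initial nuisance fits (an outcome regression ``Qhat`` and a clipped
propensity ``ghat``), the treated mean ``E[Q(1,W)]`` is targeted by a
one-dimensional logistic fluctuation on the [0,1]-scaled outcome,

    Q*(eps) = expit(logit(Qhat) + eps * H),   H(T,W) = T / ghat(W),

with ``eps`` solving the score equation ``(1/n) sum_i H_i (Y_i - Q*_i) = 0``.
The attributable regional effect (ARE) is the plug-in
``psi = (1/n) sum_i [Q*(1,W_i) - Y_i]`` and its standard error comes from
the empirical variance of the efficient influence function

    D_i = (T_i/g_i)(Y_i - Q*(T_i,W_i)) + Q*(1,W_i) - Y_i - psi.

All estimates are reported back on the original outcome scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "OutcomeScale",
    "scale_outcome",
    "TMLEFit",
    "tmle_treated_mean",
    "tmle_node_mean",
    "estimate_are",
    "NoTreatedError",
    "FluctuationError",
]

Q_CLIP = 1e-4          # clip for logit of initial predictions
EPS_BOUND = 10.0       # fluctuation coefficient search interval
SCORE_TOL = 1e-6


class NoTreatedError(ValueError):
    """The requested arm contains no observations."""


class FluctuationError(RuntimeError):
    """The one-dimensional score equation could not be solved."""


@dataclass(frozen=True)
class OutcomeScale:
    """Affine record of the min-max map Y -> (Y - lo) / (hi - lo)."""

    lo: float
    hi: float

    @property
    def span(self) -> float:
        return self.hi - self.lo

    @property
    def degenerate(self) -> bool:
        return self.span == 0.0

    def forward(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        if self.degenerate:
            return np.full_like(y, 0.5)
        return (y - self.lo) / self.span

    def unscale_mean(self, value: float) -> float:
        if self.degenerate:
            return self.lo
        return self.lo + value * self.span

    def unscale_se(self, se: float) -> float:
        if self.degenerate:
            return 0.0
        return se * self.span

    def unscale_diff(self, value: float) -> float:
        """Back-transform a difference of means (no location shift)."""
        if self.degenerate:
            return 0.0
        return value * self.span


def scale_outcome(Y: np.ndarray) -> tuple[np.ndarray, OutcomeScale]:
    """Min-max scale Y to [0,1]; constant Y maps to all 0.5 by convention."""
    Y = np.asarray(Y, dtype=float)
    record = OutcomeScale(float(np.min(Y)), float(np.max(Y)))
    return record.forward(Y), record


def unscale_estimate(value: float, record: OutcomeScale) -> float:
    return record.unscale_mean(value)


@dataclass
class TMLEFit:
    """Targeted estimate with influence-function inference (outcome units)."""

    theta_hat: float
    psi_hat: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    eps_fluct: float
    eif: np.ndarray
    n: int


def _solve_fluctuation(H: np.ndarray, Y: np.ndarray, Q_init: np.ndarray) -> tuple[float, np.ndarray]:
    """Solve (1/n) sum H (Y - expit(logit(Q)+eps H)) = 0 for eps.

    The score is monotone decreasing in eps (H >= 0), so a bracketing root
    find on [-EPS_BOUND, EPS_BOUND] is robust.  Returns (eps, Q*).
    """
    Qc = np.clip(Q_init, Q_CLIP, 1.0 - Q_CLIP)
    offset = special.logit(Qc)

    def qstar(eps: float) -> np.ndarray:
        return special.expit(offset + eps * H)

    def score(eps: float) -> float:
        return float(np.mean(H * (Y - qstar(eps))))

    s0 = score(0.0)
    if abs(s0) <= SCORE_TOL:
        return 0.0, qstar(0.0)
    lo, hi = -EPS_BOUND, EPS_BOUND
    s_lo, s_hi = score(lo), score(hi)
    if s_lo * s_hi > 0:
        # asymptotic solutions (e.g. degenerate 0/1 outcomes) sit at the
        # boundary with a vanishing score; accept them within tolerance
        if abs(s_hi) <= SCORE_TOL:
            return hi, qstar(hi)
        if abs(s_lo) <= SCORE_TOL:
            return lo, qstar(lo)
        raise FluctuationError(
            "fluctuation score equation has no root in "
            f"[-{EPS_BOUND}, {EPS_BOUND}]: score({lo})={s_lo:.3g}, "
            f"score({hi})={s_hi:.3g}, score(0)={s0:.3g}"
        )
    eps = optimize.brentq(score, lo, hi, xtol=1e-12, rtol=8.9e-16)
    return float(eps), qstar(eps)


def tmle_treated_mean(
    Q1: np.ndarray,
    QT: np.ndarray,
    T: np.ndarray,
    ghat: np.ndarray,
    Y_scaled: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Target E[Q(1,W)] with clever covariate H = T/ghat.

    Parameters are on the scaled outcome; ``Q1``/``QT`` are initial
    predictions at T=1 and at the observed T.  Returns targeted
    ``(Q*(1,W), Q*(T,W), eps)``.
    """
    T = np.asarray(T)
    if not np.any(T == 1):
        raise NoTreatedError("no observations with T=1")
    H = T / ghat
    eps, QstarT = _solve_fluctuation(H, Y_scaled, QT)
    Qc1 = np.clip(Q1, Q_CLIP, 1.0 - Q_CLIP)
    Qstar1 = special.expit(special.logit(Qc1) + eps / ghat)
    return Qstar1, QstarT, eps


def tmle_node_mean(
    Q_arm: np.ndarray,
    QT: np.ndarray,
    T: np.ndarray,
    g_arm: np.ndarray,
    Y_scaled: np.ndarray,
    arm: int,
    scale: OutcomeScale,
) -> tuple[float, float, np.ndarray]:
    """Targeted mean outcome in one arm, E[Q(arm, W)].

    ``g_arm`` is the (clipped) estimated probability of the requested arm
    given W.  Returns ``(theta_hat, se, eif)`` on the original outcome
    scale; the EIF is for the arm mean itself.
    """
    T = np.asarray(T)
    member = T == arm
    if not np.any(member):
        raise NoTreatedError(f"arm T={arm} is empty")
    H = member.astype(float) / g_arm
    eps, QstarT = _solve_fluctuation(H, Y_scaled, QT)
    Qca = np.clip(Q_arm, Q_CLIP, 1.0 - Q_CLIP)
    Qstar_arm = special.expit(special.logit(Qca) + eps / g_arm)
    theta_s = float(np.mean(Qstar_arm))
    eif_s = H * (Y_scaled - QstarT) + Qstar_arm - theta_s
    n = len(Y_scaled)
    se_s = float(np.sqrt(np.var(eif_s, ddof=1) / n)) if n > 1 else 0.0
    return scale.unscale_mean(theta_s), scale.unscale_se(se_s), eif_s * scale.span


def estimate_are(
    Qstar1: np.ndarray,
    QstarT: np.ndarray,
    T: np.ndarray,
    ghat: np.ndarray,
    Y_scaled: np.ndarray,
    scale: OutcomeScale,
    eps_fluct: float = np.nan,
) -> TMLEFit:
    """Plug-in ARE with EIF-based Wald inference on the original scale."""
    n = len(Y_scaled)
    if n < 2:
        raise ValueError("at least two observations are required for a variance")
    T = np.asarray(T)
    psi_s = float(np.mean(Qstar1 - Y_scaled))
    eif_s = (T / ghat) * (Y_scaled - QstarT) + Qstar1 - Y_scaled - psi_s
    eif_s = eif_s - eif_s.mean()  # influence values are defined up to centering
    theta_s = float(np.mean(Qstar1))
    se_s = float(np.sqrt(np.var(eif_s, ddof=1) / n))

    psi = scale.unscale_diff(psi_s)
    se = scale.unscale_se(se_s)
    z = psi / se if se > 0 else (0.0 if psi == 0 else np.inf * np.sign(psi))
    p = float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else 0.0
    return TMLEFit(
        theta_hat=scale.unscale_mean(theta_s),
        psi_hat=psi,
        se=se,
        ci_low=psi - 1.959963984540054 * se,
        ci_high=psi + 1.959963984540054 * se,
        p_value=p,
        eps_fluct=eps_fluct,
        eif=eif_s * scale.span,
        n=n,
    )
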