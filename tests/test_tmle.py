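"""Targeted update: fluctuation solution, EIF inference, outcome scaling."""

import numpy as np
import pytest
from scipy import special

from aretree.tmle import (
    NoTreatedError,
    OutcomeScale,
    estimate_are,
    scale_outcome,
    tmle_node_mean,
    tmle_treated_mean,
)


class TestScaling:
    def test_affine_map(self):
        ys, rec = scale_outcome(np.array([0.0, 5.0, 10.0]))
        assert np.allclose(ys, [0.0, 0.5, 1.0])
        assert rec.unscale_mean(0.5) == 5.0

    def test_roundtrip(self):
        rng = np.random.default_rng(0)
        y = rng.normal(3, 7, 50)
        _, rec = scale_outcome(y)
        for psi in rng.normal(size=5):
            assert np.isclose(rec.unscale_mean(rec.forward(np.array([psi]))[0]), psi)

    def test_constant_outcome_degenerate(self):
        ys, rec = scale_outcome(np.full(4, 3.3))
        assert np.all(ys == 0.5)
        assert rec.unscale_mean(0.5) == 3.3
        assert rec.unscale_se(0.123) == 0.0


def _brute_force_eps(H, Y, Q, grid=None):
    """Independent oracle: dense grid + local bisection of the score."""
    grid = np.linspace(-10, 10, 200001) if grid is None else grid
    Qc = np.clip(Q, 1e-4, 1 - 1e-4)
    off = special.logit(Qc)
    scores = np.array([np.mean(H * (Y - special.expit(off + e * H))) for e in grid])
    return grid[np.argmin(np.abs(scores))]


class TestFluctuation:
    def test_saturated_fit_gives_zero_eps(self):
        # binary W; Qhat equals stratum means among treated, ghat the
        # stratum treatment frequencies -> score already solved
        rng = np.random.default_rng(2)
        n = 400
        W = rng.binomial(1, 0.5, n)
        T = rng.binomial(1, 0.4 + 0.2 * W)
        Y = np.clip(0.3 + 0.2 * W + 0.1 * T + rng.normal(0, 0.05, n), 0.01, 0.99)
        Q = np.empty(n)
        g = np.empty(n)
        for w in (0, 1):
            for t in (0, 1):
                m = (W == w) & (T == t)
                Q[m] = Y[m].mean()
            g[W == w] = T[W == w].mean()
        _, QstarT, eps = tmle_treated_mean(Q, Q, T, g, Y)
        assert abs(eps) < 1e-6
        assert np.allclose(QstarT, Q, atol=1e-6)

    def test_eps_matches_bisection_oracle_on_micro_input(self):
        Q = np.array([0.2, 0.4, 0.6, 0.8, 0.3, 0.7])
        g = np.array([0.3, 0.5, 0.7, 0.4, 0.6, 0.5])
        T = np.array([1, 0, 1, 1, 0, 1])
        Y = np.array([0.9, 0.1, 0.4, 0.95, 0.2, 0.5])
        H = T / g
        _, _, eps = tmle_treated_mean(Q, np.where(T == 1, Q, Q), T, g, Y)
        assert abs(eps - _brute_force_eps(H, Y, Q)) < 1e-4

    def test_score_equation_solved(self):
        rng = np.random.default_rng(9)
        n = 300
        Q = rng.uniform(0.1, 0.9, n)
        g = rng.uniform(0.2, 0.8, n)
        T = rng.binomial(1, g)
        if T.sum() == 0:
            T[0] = 1
        Y = rng.uniform(0, 1, n)
        _, QstarT, _ = tmle_treated_mean(Q, Q, T, g, Y)
        assert abs(np.mean((T / g) * (Y - QstarT))) < 1e-6

    def test_no_treated_raises(self):
        with pytest.raises(NoTreatedError):
            tmle_treated_mean(
                np.array([0.5, 0.5]),
                np.array([0.5, 0.5]),
                np.array([0, 0]),
                np.array([0.5, 0.5]),
                np.array([0.2, 0.8]),
            )


class TestEstimateARE:
    def _identity_scale(self):
        return OutcomeScale(0.0, 1.0)

    def test_perfect_predictions_give_zero(self):
        Y = np.array([0.2, 0.5, 0.8, 0.4])
        T = np.array([1, 0, 1, 0])
        g = np.full(4, 0.5)
        fit = estimate_are(Y, Y, T, g, Y, self._identity_scale())
        assert fit.psi_hat == pytest.approx(0.0, abs=1e-12)

    def test_hand_arithmetic_average_of_differences(self):
        scale = OutcomeScale(0.0, 10.0)
        Q1 = np.array([2.0, 4.0, 6.0, 8.0]) / 10
        Y = np.array([1.0, 1.0, 1.0, 1.0]) / 10
        T = np.array([1, 1, 0, 0])
        g = np.full(4, 0.5)
        fit = estimate_are(Q1, Q1, T, g, Y, scale)
        assert fit.psi_hat == pytest.approx(4.0)

    def test_eif_centered_and_ci_ordering(self):
        rng = np.random.default_rng(4)
        n = 200
        Q1 = rng.uniform(0.2, 0.8, n)
        QT = rng.uniform(0.2, 0.8, n)
        T = rng.binomial(1, 0.5, n)
        g = rng.uniform(0.3, 0.7, n)
        Y = rng.uniform(0, 1, n)
        fit = estimate_are(Q1, QT, T, g, Y, OutcomeScale(-2.0, 3.0))
        assert abs(fit.eif.mean()) < 1e-8
        assert fit.ci_low <= fit.psi_hat <= fit.ci_high
        assert fit.se >= 0

    def test_affine_equivariance(self):
        rng = np.random.default_rng(6)
        n = 150
        Q1 = rng.uniform(0.2, 0.8, n)
        QT = rng.uniform(0.2, 0.8, n)
        T = rng.binomial(1, 0.5, n)
        g = rng.uniform(0.3, 0.7, n)
        Y = rng.uniform(0, 1, n)
        fit1 = estimate_are(Q1, QT, T, g, Y, OutcomeScale(0.0, 1.0))
        fit2 = estimate_are(Q1, QT, T, g, Y, OutcomeScale(5.0, 5.0 + 3.0))
        assert fit2.psi_hat == pytest.approx(3.0 * fit1.psi_hat)
        assert fit2.se == pytest.approx(3.0 * fit1.se)


class TestNodeMean:
    def test_null_arms_agree_with_sample_mean(self):
        rng = np.random.default_rng(12)
        n = 2000
        Y = rng.normal(5, 1, n)
        T = rng.binomial(1, 0.5, n)
        ys, rec = scale_outcome(Y)
        g1 = np.full(n, 0.5)
        th1, se1, _ = tmle_node_mean(ys * 0 + ys.mean(), ys * 0 + ys.mean(), T, g1, ys, 1, rec)
        th0, se0, _ = tmle_node_mean(ys * 0 + ys.mean(), ys * 0 + ys.mean(), T, 1 - g1, ys, 0, rec)
        assert abs(th1 - Y.mean()) < 3 * se1
        assert abs(th0 - Y.mean()) < 3 * se0

    def test_deterministic_outcome_by_arm(self):
        rng = np.random.default_rng(13)
        n = 500
        T = rng.binomial(1, 0.5, n)
        Y = T.astype(float)
        ys, rec = scale_outcome(Y)
        Q = np.clip(ys.copy(), 1e-4, 1 - 1e-4)
        g = np.full(n, T.mean())
        # Q for arm 1: predict 1 for everyone
        th, _, _ = tmle_node_mean(np.full(n, 1 - 1e-4), Q, T, g, ys, 1, rec)
        assert th == pytest.approx(1.0, abs=1e-3)

    def test_empty_arm_raises(self):
        with pytest.raises(NoTreatedError):
            tmle_node_mean(
                np.array([0.5, 0.5]),
                np.array([0.5, 0.5]),
                np.array([1, 1]),
                np.array([0.5, 0.5]),
                np.array([0.5, 0.5]),
                0,
                OutcomeScale(0, 1),
            )


def test_double_robustness_with_misspecified_outcome():
    """Constant (wrong) Qhat with correct ghat still estimates the truth."""
    rng = np.random.default_rng(21)
    n = 5000
    W = rng.normal(0, 1, n)
    g = special.expit(0.5 * W)
    T = rng.binomial(1, g)
    Y_raw = 1.0 + 0.5 * W + 0.8 * T + rng.normal(0, 0.3, n)
    ys, rec = scale_outcome(Y_raw)
    truth = 1.0 + 0.8 - Y_raw.mean()  # E[Y(1)] - E[Y]; E[W]=0
    Q_bad = np.full(n, float(ys.mean()))
    Qstar1, QstarT, eps = tmle_treated_mean(Q_bad, Q_bad, T, np.clip(g, 0.025, 0.975), ys)
    fit = estimate_are(Qstar1, QstarT, T, np.clip(g, 0.025, 0.975), ys, rec, eps)
    assert abs(fit.psi_hat - truth) < 3 * fit.se
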