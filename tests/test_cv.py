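"""Cross-estimation: folds, per-fold discovery, pooled TMLE, grouping."""

import numpy as np
import pytest

from aretree.cv import (
    CVRegionTMLE,
    FoldResult,
    make_folds,
    pool_tmle,
    summarize_cutpoints,
)
from aretree.nuisance import EnsembleConfig
from aretree.regions import Operator, Region, ThresholdRule
from aretree.tmle import OutcomeScale

FAST_MENU = (("mean", {}), ("glm", {}), ("rf", {"n_estimators": 20}))


class TestMakeFolds:
    def test_balanced_assignment(self):
        a = make_folds(10, 5, 0)
        counts = np.bincount(a, minlength=5)
        assert counts.tolist() == [2, 2, 2, 2, 2]

    def test_deterministic_per_seed(self):
        assert np.array_equal(make_folds(37, 4, 9), make_folds(37, 4, 9))
        assert not np.array_equal(make_folds(500, 4, 9), make_folds(500, 4, 10))

    @pytest.mark.parametrize("n,K", [(10, 1), (5, 6)])
    def test_invalid_K_raises(self, n, K):
        with pytest.raises(ValueError):
            make_folds(n, K)


class TestSummarizeCutpoints:
    def test_mean_and_range(self):
        regions = [
            Region((ThresholdRule("X5", Operator.GT, c),)) for c in (1.9, 2.0, 2.0)
        ]
        out = summarize_cutpoints(regions)
        info = out[("X5", Operator.GT)]
        assert info["mean"] == pytest.approx(1.9667, abs=1e-3)
        assert (info["min"], info["max"]) == (1.9, 2.0)

    def test_single_fold_degenerate_range(self):
        out = summarize_cutpoints([Region((ThresholdRule("A1", Operator.LE, 3.0),))])
        info = out[("A1", Operator.LE)]
        assert info["mean"] == info["min"] == info["max"] == 3.0

    def test_reported_molybdenum_style_average(self):
        cuts = [102.9, 103.6, 104.5, 112.4, 107.3, 102.9, 104.9, 96.7, 100.2, 102.5]
        regions = [Region((ThresholdRule("molybdenum", Operator.LE, c),)) for c in cuts]
        info = summarize_cutpoints(regions)[("molybdenum", Operator.LE)]
        assert info["mean"] == pytest.approx(103.79, abs=0.01)
        assert (info["min"], info["max"]) == (96.7, 112.4)

    def test_mixed_operators_reported_separately(self):
        regions = [
            Region((ThresholdRule("A1", Operator.LE, 2.0),)),
            Region((ThresholdRule("A1", Operator.GT, 1.0),)),
        ]
        out = summarize_cutpoints(regions)
        assert ("A1", Operator.LE) in out and ("A1", Operator.GT) in out


def _stub_fold(fold_id, region, n=40, seed=0, are_offset=0.0):
    rng = np.random.default_rng(seed)
    Y = rng.uniform(0.2, 0.8, n)
    T = rng.binomial(1, 0.5, n)
    if T.sum() == 0:
        T[0] = 1
    Q1 = np.clip(Y + are_offset + rng.normal(0, 0.01, n), 0.01, 0.99)
    return FoldResult(
        fold_id=fold_id,
        region=region,
        estimate_available=True,
        val_index=np.arange(n),
        Q1=Q1,
        QT=np.clip(Y + rng.normal(0, 0.01, n), 0.01, 0.99),
        ghat=np.full(n, 0.5),
        T=T,
        Y_scaled=Y,
    )


class TestPoolTMLE:
    def test_any_region_missing_gives_no_consistent_region(self):
        region = Region((ThresholdRule("A1", Operator.LE, 1.0),))
        folds = [_stub_fold(0, region), FoldResult(fold_id=1, region=None)]
        pooled = pool_tmle(folds, 2, OutcomeScale(0, 1))
        assert pooled.status == "no_consistent_region"
        assert pooled.are is None

    def test_group_proportions(self):
        r5 = Region((ThresholdRule("X5", Operator.GT, 2.0),))
        r7 = Region((ThresholdRule("X7", Operator.LE, 0.3),))
        r71 = Region(
            (ThresholdRule("X7", Operator.LE, 0.4), ThresholdRule("X1", Operator.LE, 0.6))
        )
        sig_plan = [r5] * 7 + [r7] * 2 + [r71]
        folds = [_stub_fold(i, r, seed=i) for i, r in enumerate(sig_plan)]
        pooled = pool_tmle(folds, 10, OutcomeScale(0, 1))
        assert pooled.status == "ok"
        props = {g.signature: g.proportion_folds for g in pooled.groups}
        assert props == {("X5",): 0.7, ("X7",): 0.2, ("X1", "X7"): 0.1}
        assert sum(props.values()) == pytest.approx(1.0)

    def test_pooled_equals_fold_average_when_no_fluctuation_needed(self):
        # Q already solves the score equation approximately -> eps ~ 0 and
        # pooled ARE equals the K-fold average of plug-in AREs
        region = Region((ThresholdRule("A1", Operator.LE, 1.0),))
        folds = []
        rng = np.random.default_rng(5)
        for k in range(3):
            n = 50
            Y = rng.uniform(0.3, 0.7, n)
            T = rng.binomial(1, 0.5, n)
            if T.sum() == 0:
                T[0] = 1
            folds.append(
                FoldResult(
                    fold_id=k,
                    region=region,
                    estimate_available=True,
                    val_index=np.arange(n),
                    Q1=Y.copy(),
                    QT=Y.copy(),  # residuals zero -> score solved at eps=0
                    ghat=np.full(n, 0.5),
                    T=T,
                    Y_scaled=Y,
                )
            )
        pooled = pool_tmle(folds, 3, OutcomeScale(0, 1))
        fold_avg = np.mean([np.mean(f.Q1 - f.Y_scaled) for f in folds])
        assert pooled.are == pytest.approx(float(fold_avg), abs=1e-9)


class TestCVRegionTMLE:
    def test_step_signal_both_folds_and_positive_are(self, step_data):
        est = CVRegionTMLE(
            exposures=["A1", "A2"],
            n_folds=2,
            objective="max",
            learner_menu=FAST_MENU,
            random_state=4,
        )
        est.fit_dataset(step_data)
        assert est.pooled_.status == "ok"
        assert all(f.region is not None for f in est.fold_results_)
        for f in est.fold_results_:
            rules = {r.exposure: r.cutpoint for r in f.region.rules}
            assert "A1" in rules and abs(rules["A1"] - 2.0) <= 0.3
        # true ARE of {A1<=2} is 10 * (1 - P(A1<=2)) = 5 under uniform A1
        assert abs(est.pooled_.are - 5.0) < 4 * est.pooled_.se

    def test_no_leakage_between_discovery_and_validation(self, step_data):
        est = CVRegionTMLE(
            exposures=["A1", "A2"],
            n_folds=2,
            objective="max",
            learner_menu=FAST_MENU,
            random_state=4,
        )
        est.fit_dataset(step_data)
        idx = np.concatenate([f.val_index for f in est.fold_results_ if f.val_index is not None])
        assert len(idx) == step_data.n
        assert len(np.unique(idx)) == step_data.n

    def test_null_data_returns_no_consistent_region(self, null_data_small):
        est = CVRegionTMLE(
            exposures=["A1", "A2"],
            n_folds=2,
            objective="max",
            learner_menu=FAST_MENU,
            random_state=0,
        )
        est.fit_dataset(null_data_small)
        # a strict-null dataset should essentially never satisfy both folds
        assert est.pooled_.status == "no_consistent_region"

    def test_determinism_under_seed(self, step_data):
        kw = dict(
            exposures=["A1", "A2"],
            n_folds=2,
            objective="max",
            learner_menu=FAST_MENU,
            random_state=7,
        )
        t1 = CVRegionTMLE(**kw).fit_dataset(step_data).fold_table()
        t2 = CVRegionTMLE(**kw).fit_dataset(step_data).fold_table()
        assert t1.equals(t2)

    def test_sklearn_params_roundtrip(self):
        est = CVRegionTMLE(exposures=["A1"], alpha=0.01)
        assert est.get_params()["alpha"] == 0.01
        est.set_params(alpha=0.10, n_folds=3)
        assert est.alpha == 0.10 and est.n_folds == 3

    def test_pooled_eif_centered(self, step_data):
        est = CVRegionTMLE(
            exposures=["A1", "A2"],
            n_folds=2,
            objective="max",
            learner_menu=FAST_MENU,
            random_state=4,
        )
        est.fit_dataset(step_data)
        from aretree.cv import _pooled_fit

        fit, _ = _pooled_fit([f for f in est.fold_results_ if f.Q1 is not None], est.scale_)
        assert abs(fit.eif.mean()) < 1e-8
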