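"""Partitioning search: threshold enumeration, filters, greedy/exhaustive."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from aretree.regions import MixtureDataset, Operator, Region, ThresholdRule
from aretree.tree import (
    TreeConfig,
    build_tree_greedy,
    check_positivity,
    enumerate_thresholds,
    evaluate_split,
    extract_region,
    search_exhaustive,
)


class TestEnumerateThresholds:
    def test_constant_column_empty(self):
        assert enumerate_thresholds(np.full(10, 3.0), "unique").size == 0

    def test_unique_excludes_maximum(self):
        cuts = enumerate_thresholds(np.array([1, 2, 3, 4, 5], dtype=float), "unique")
        assert cuts.tolist() == [1, 2, 3, 4]

    def test_rounded_collapses_values(self):
        cuts = enumerate_thresholds(np.array([0.11, 0.14, 0.49, 0.92]), "rounded", 1)
        assert cuts.tolist() == [0.1, 0.5]

    def test_quantile_matches_direct_computation(self):
        rng = np.random.default_rng(0)
        values = rng.uniform(size=1000)
        cuts = enumerate_thresholds(values, "quantile", 20)
        expected = np.unique(np.quantile(values, np.arange(1, 21) / 21))
        expected = expected[expected < values.max()]
        assert len(cuts) <= 20
        assert np.allclose(cuts, expected)


class TestCheckPositivity:
    def test_degenerate_treatment_fails(self):
        ok, _ = check_positivity(np.ones(50), np.random.default_rng(0).normal(size=(50, 1)), 0.01)
        assert not ok

    def test_bounded_generating_propensity_passes(self):
        passes = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            W = rng.normal(size=(2000, 1))
            T = rng.binomial(1, expit(0.5 * W[:, 0]))
            ok, (lo, hi) = check_positivity(T, W, 0.05)
            passes += ok
        assert passes >= 18  # true pi roughly in [0.2, 0.8] on typical draws

    def test_tight_epsilon_separates_half_from_point_three(self):
        rng = np.random.default_rng(1)
        n = 50000
        W = rng.normal(size=(n, 1))
        T_half = rng.binomial(1, 0.5, n)
        ok_half, _ = check_positivity(T_half, W, 0.49)
        assert ok_half
        T_three = rng.binomial(1, 0.3, n)
        ok_three, _ = check_positivity(T_three, W, 0.49)
        assert not ok_three


class TestEvaluateSplit:
    def test_step_function_split_detected(self, step_data):
        config = TreeConfig(objective="max")
        cand = evaluate_split(step_data, "A1", 2.0, float(step_data.Y.mean()), config)
        assert cand.valid
        assert cand.improving_arm == "left"
        assert cand.theta_left - cand.theta_right == pytest.approx(10.0, abs=0.2)
        assert cand.p_left < 1e-6

    def test_small_child_invalid_with_min_node_reason(self, step_data):
        config = TreeConfig(objective="max", min_node=10)
        tiny_cut = float(np.sort(step_data.A["A1"].unique())[0])
        cand = evaluate_split(step_data, "A1", tiny_cut, float(step_data.Y.mean()), config)
        if min(cand.n_left, cand.n_right) < 10:
            assert not cand.valid and cand.reason == "min_node"

    def test_null_split_rarely_valid(self):
        # per-candidate false-validity should be near the nominal level
        rng = np.random.default_rng(10)
        hits = 0
        trials = 100
        for i in range(trials):
            n = 300
            W = pd.DataFrame({"W1": rng.normal(size=n)})
            A = pd.DataFrame({"A1": np.round(rng.normal(size=n), 1)})
            Y = rng.normal(size=n)
            data = MixtureDataset(W, A, Y)
            cand = evaluate_split(data, "A1", 0.0, float(Y.mean()), TreeConfig(objective="max"))
            hits += cand.valid
        # binomial(100, 0.05) upper tail; generous bound
        assert hits <= 13


class TestGreedyTree:
    def test_null_data_mostly_single_leaf(self, null_data_small):
        config = TreeConfig(objective="max")
        leaves_only = 0
        for seed in range(5):
            from aretree.synthetic import NullDGPSpec, generate

            data = generate(NullDGPSpec(), 400, 600 + seed)
            root = build_tree_greedy(data, config)
            leaves_only += root.is_leaf
        assert leaves_only >= 3

    def test_step_function_region_recovered(self, step_data):
        root = build_tree_greedy(step_data, TreeConfig(objective="max"))
        region = extract_region(root, "max")
        rules = {(r.exposure, r.operator): r.cutpoint for r in region.rules}
        assert ("A1", Operator.LE) in rules
        assert abs(rules[("A1", Operator.LE)] - 2.0) <= 0.2

    def test_min_objective_mirrors_max_on_negated_outcome(self, step_data):
        neg = MixtureDataset(step_data.W, step_data.A, -step_data.Y)
        r_max = extract_region(build_tree_greedy(step_data, TreeConfig(objective="max")), "max")
        r_min = extract_region(build_tree_greedy(neg, TreeConfig(objective="min")), "min")
        assert r_max == r_min

    def test_depth_bound_and_split_filters_respected(self, continuous_data):
        config = TreeConfig(objective="max", max_depth=2, min_node=25)
        root = build_tree_greedy(continuous_data, config)
        assert root.max_depth_reached <= 2
        stack = [root]
        while stack:
            node = stack.pop()
            if node.split is not None:
                assert min(node.split.n_left, node.split.n_right) >= 25
                assert node.split.valid
                assert config.epsilon <= node.split.pi_min <= node.split.pi_max <= 1 - config.epsilon
                stack.extend(node.children)

    def test_single_leaf_tree_gives_full_space(self):
        rng = np.random.default_rng(3)
        data = MixtureDataset(
            pd.DataFrame({"W1": rng.normal(size=50)}),
            pd.DataFrame({"A1": np.round(rng.normal(size=50), 1)}),
            rng.normal(size=50),
        )
        root = build_tree_greedy(data, TreeConfig(objective="max", alpha=1e-6))
        region = extract_region(root, "max")
        assert region.is_full_space


class TestExhaustive:
    def test_depth_one_matches_greedy(self, step_data):
        config = TreeConfig(objective="max", max_depth=1)
        greedy = extract_region(build_tree_greedy(step_data, config), "max")
        exhaustive_region, _ = search_exhaustive(step_data, config)
        assert exhaustive_region == greedy

    def test_matches_brute_force_on_coarse_grid(self):
        # 2 exposures x few levels, strong separable signal
        rng = np.random.default_rng(4)
        n = 1500
        A = pd.DataFrame(
            {
                "A1": rng.integers(1, 5, n).astype(float),
                "A2": rng.integers(1, 5, n).astype(float),
            }
        )
        W = pd.DataFrame({"W1": rng.normal(size=n)})
        Y = 5.0 * (A["A1"] > 2).to_numpy() + 3.0 * (A["A2"] > 3).to_numpy() + rng.normal(
            0, 0.2, n
        )
        data = MixtureDataset(W, A, Y)
        config = TreeConfig(objective="max", max_depth=2, threshold_strategy="unique")
        region, estimate = search_exhaustive(data, config)
        # brute force over all one-cut-per-exposure conjunctions by plug-in
        # means; the maximizer is the oracle rectangle {A1>2, A2>3} up to
        # noise among its sub-rectangles (which share the same true mean)
        best_val = -np.inf
        for c1 in (1, 2, 3):
            for c2 in (1, 2, 3):
                for side1 in (0, 1):
                    for side2 in (0, 1):
                        m = np.ones(n, dtype=bool)
                        m &= (A["A1"] <= c1).to_numpy() if side1 else (A["A1"] > c1).to_numpy()
                        m &= (A["A2"] <= c2).to_numpy() if side2 else (A["A2"] > c2).to_numpy()
                        if m.sum() < 10:
                            continue
                        best_val = max(best_val, Y[m].mean())
        oracle_mean = 8.0  # both indicators active
        assert best_val == pytest.approx(oracle_mean, abs=0.1)
        assert estimate == pytest.approx(best_val, abs=3 * 0.2 / np.sqrt(100))
        # discovered region must consist solely of active cells
        member = data.membership(region).astype(bool)
        assert member.sum() >= 10
        assert np.all((A["A1"].to_numpy() > 2)[member]) and np.all(
            (A["A2"].to_numpy() > 3)[member]
        )

    def test_no_valid_splits_returns_full_space(self):
        rng = np.random.default_rng(5)
        data = MixtureDataset(
            pd.DataFrame({"W1": rng.normal(size=80)}),
            pd.DataFrame({"A1": np.round(rng.normal(size=80), 1)}),
            rng.normal(size=80),
        )
        region, _ = search_exhaustive(data, TreeConfig(objective="max", alpha=1e-9, max_depth=2))
        assert region.is_full_space


def test_extract_region_normalizes_repeated_exposure_cuts():
    from aretree.tree import TreeNode
    from aretree.regions import normalize_region

    r = normalize_region(
        (
            ThresholdRule("A1", Operator.LE, 4.0),
            ThresholdRule("A1", Operator.LE, 2.0),
        )
    )
    assert [(x.exposure, x.cutpoint) for x in r.rules] == [("A1", 2.0)]
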