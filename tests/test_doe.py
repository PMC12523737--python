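"""Factorial screening, Lenth significance, desirability optimization."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from haarisk.doe import (
    DesirabilityOptimizer,
    Factor,
    FactorialDesign,
    Goal,
    ResponseGoal,
    build_face_centered,
    build_full_factorial,
    desirability,
    desirability_single,
    estimate_effects,
    lenth_pse,
    optimize_conditions,
)
from haarisk.errors import ComputationError, InsufficientDesignError
from haarisk.simulate import generate_doe_responses

FACTORS3 = [Factor("A", 0, 1), Factor("B", 0, 1), Factor("C", 0, 1)]


def brute_force_effects(runs, y):
    """Oracle: per-term mean(+1) − mean(−1) by explicit python loops."""
    k = runs.shape[1]
    out = {}
    for order in range(1, k + 1):
        for combo in itertools.combinations(range(k), order):
            term = ":".join("ABCDEF"[j] for j in combo)
            plus, minus = [], []
            for row, yi in zip(runs, y):
                contrast = 1.0
                for j in combo:
                    contrast *= row[j]
                (plus if contrast > 0 else minus).append(yi)
            out[term] = sum(plus) / len(plus) - sum(minus) / len(minus)
    return out


class TestBuild:
    def test_two_cubed_has_eight_runs_each_combination_once(self):
        design = build_full_factorial(FACTORS3)
        assert design.runs.shape == (8, 3)
        assert len({tuple(r) for r in design.runs}) == 8

    def test_center_points_appended_all_zero(self):
        design = build_full_factorial(FACTORS3, n_center=3)
        assert design.runs.shape == (11, 3)
        assert design.is_center.sum() == 3
        assert np.all(design.runs[design.is_center] == 0)

    @pytest.mark.parametrize("k", [1, 7])
    def test_factor_count_out_of_range(self, k):
        with pytest.raises(InsufficientDesignError):
            build_full_factorial([Factor(str(i), 0, 1) for i in range(k)])

    def test_face_centered_layout(self):
        X = build_face_centered([Factor(str(i), 0, 1) for i in range(4)], n_center=3)
        assert X.shape == (16 + 8 + 3, 4)
        assert np.all(np.abs(X) <= 1)


class TestEffects:
    def test_pure_main_effect_is_twice_the_coefficient(self):
        design = build_full_factorial(FACTORS3)
        design.responses["y"] = generate_doe_responses(
            {"intercept": 10.0, "A": 3.0}, design
        )
        effects = {e.term: e.effect for e in estimate_effects(design, "y").entries}
        assert effects["A"] == pytest.approx(6.0)
        for term, value in effects.items():
            if term != "A":
                assert value == pytest.approx(0.0, abs=1e-12)

    def test_interaction_effect_matches_contrast_sum(self):
        design = build_full_factorial(FACTORS3)
        design.responses["y"] = generate_doe_responses(
            {"intercept": 10.0, "A": 3.0, "A:B": 2.0}, design
        )
        effects = {e.term: e.effect for e in estimate_effects(design, "y").entries}
        assert effects["A:B"] == pytest.approx(4.0)

    @given(y=st.lists(st.integers(0, 3), min_size=8, max_size=8))
    def test_equivalence_with_brute_force_oracle(self, y):
        design = build_full_factorial(FACTORS3)
        design.responses["y"] = np.array(y, dtype=float)
        table = estimate_effects(design, "y")
        oracle = brute_force_effects(design.runs, [float(v) for v in y])
        for entry in table.entries:
            assert entry.effect == pytest.approx(oracle[entry.term], abs=1e-12)

    @given(seed=st.integers(0, 500))
    @settings(max_examples=30)
    def test_run_order_invariance(self, seed):
        rng = np.random.default_rng(seed)
        design = build_full_factorial(FACTORS3)
        y = rng.normal(size=8)
        design.responses["y"] = y
        ref = {e.term: e.effect for e in estimate_effects(design, "y").entries}
        perm = rng.permutation(8)
        shuffled = FactorialDesign(
            FACTORS3, design.runs[perm], {"y": y[perm]}
        )
        got = {e.term: e.effect for e in estimate_effects(shuffled, "y").entries}
        for term in ref:
            assert got[term] == pytest.approx(ref[term], abs=1e-12)

    def test_lenth_margin_matches_brute_force_pse(self):
        rng = np.random.default_rng(42)
        design = build_full_factorial(FACTORS3)
        design.responses["y"] = rng.normal(10, 2, size=8)
        table = estimate_effects(design, "y")
        effects = np.array([abs(e.effect) for e in table.entries])
        s0 = 1.5 * np.median(effects)
        pse = 1.5 * np.median(effects[effects < 2.5 * s0])
        assert table.pse == pytest.approx(pse, rel=1e-12)
        assert table.margin_of_error == pytest.approx(
            sps.t.ppf(0.975, 7 / 3) * pse, rel=1e-12
        )

    def test_center_point_pure_error_used_when_available(self):
        design = build_full_factorial(FACTORS3, n_center=3)
        y = generate_doe_responses({"intercept": 10.0, "A": 3.0}, design)
        y[design.is_center] += np.array([-0.1, 0.0, 0.1])
        design.responses["y"] = y
        table = estimate_effects(design, "y")
        assert table.method == "center_pure_error"
        by_term = {e.term: e for e in table.entries}
        assert by_term["A"].significant
        assert not by_term["B:C"].significant

    def test_missing_response_is_an_error(self):
        design = build_full_factorial(FACTORS3)
        with pytest.raises(ComputationError, match="no response"):
            estimate_effects(design, "y")

    def test_effect_count_and_sorting(self):
        rng = np.random.default_rng(0)
        design = build_full_factorial(FACTORS3)
        design.responses["y"] = rng.normal(size=8)
        table = estimate_effects(design, "y")
        assert len(table.entries) == 7  # 2^3 − 1
        mags = [abs(e.standardized) for e in table.entries]
        assert mags == sorted(mags, reverse=True)


class TestDesirability:
    GOAL_MAX = ResponseGoal(Goal.MAXIMIZE, 0.0, 10.0)

    def test_target_goal_definition(self):
        goal = ResponseGoal(Goal.TARGET, 0.0, 10.0, target=5.0)
        assert desirability_single(5.0, goal) == 1.0
        assert desirability_single(0.0, goal) == 0.0
        assert desirability_single(10.0, goal) == 0.0

    def test_maximize_linear_ramp(self):
        assert desirability_single(5.0, self.GOAL_MAX) == pytest.approx(0.5)
        assert desirability_single(-1.0, self.GOAL_MAX) == 0.0
        assert desirability_single(11.0, self.GOAL_MAX) == 1.0

    def test_overall_is_order_invariant_geometric_mean(self):
        spec = {"a": self.GOAL_MAX, "b": ResponseGoal(Goal.MINIMIZE, 0.0, 10.0)}
        responses = {"a": 5.0, "b": 2.0}
        D = desirability(responses, spec)
        assert D == pytest.approx(math.sqrt(0.5 * 0.8))
        spec_rev = dict(reversed(list(spec.items())))
        assert desirability(responses, spec_rev) == pytest.approx(D)

    def test_any_zero_component_zeroes_the_overall(self):
        spec = {"a": self.GOAL_MAX, "b": ResponseGoal(Goal.MINIMIZE, 0.0, 10.0)}
        assert desirability({"a": 0.0, "b": 2.0}, spec) == 0.0

    def test_missing_response_raises(self):
        with pytest.raises(ComputationError, match="missing"):
            desirability({"a": 1.0}, {"b": self.GOAL_MAX})


class TestOptimizer:
    def test_noiseless_quadratic_truth_recovered_to_grid_resolution(self):
        X = np.array([[-1.0], [-0.5], [0.0], [0.5], [1.0]])
        y = -(X[:, 0] ** 2) + 1.0
        spec = {"y": ResponseGoal(Goal.MAXIMIZE, 0.0, 1.0)}
        x_opt, predicted, D = optimize_conditions(X, {"y": y}, spec)
        assert x_opt[0] == pytest.approx(0.0, abs=0.05)
        assert predicted["y"] == pytest.approx(1.0, abs=1e-9)
        assert D == pytest.approx(1.0, abs=1e-9)

    def test_opposing_linear_trends_optimum_at_midpoint(self):
        X = np.array([[-1.0], [0.0], [1.0]])
        responses = {"up": X[:, 0], "down": -X[:, 0]}
        spec = {
            "up": ResponseGoal(Goal.MAXIMIZE, -1.0, 1.0),
            "down": ResponseGoal(Goal.MAXIMIZE, -1.0, 1.0),
        }
        x_opt, _, _ = optimize_conditions(X, responses, spec)
        assert x_opt[0] == pytest.approx(0.0, abs=1e-9)

    def test_underdetermined_quadratic_surrogate_rejected(self):
        X = np.array([[-1.0, -1.0], [1.0, 1.0], [0.0, 0.0]])
        with pytest.raises(InsufficientDesignError):
            DesirabilityOptimizer().fit(X, {"y": np.zeros(3)})

    def test_network_surrogate_is_seed_reproducible(self):
        rng = np.random.default_rng(5)
        X = build_face_centered([Factor(str(i), 0, 1) for i in range(2)], 3)
        y = 5.0 - X[:, 0] ** 2 - X[:, 1] ** 2 + rng.normal(0, 0.05, X.shape[0])
        spec = {"y": ResponseGoal(Goal.MAXIMIZE, 0.0, 5.0)}
        results = [
            optimize_conditions(
                X, {"y": y}, spec, surrogate="small_network", seed=3, resolution=11
            )
            for _ in range(2)
        ]
        assert np.allclose(results[0][0], results[1][0])
        assert results[0][2] == pytest.approx(results[1][2])

    def test_sklearn_style_params(self):
        opt = DesirabilityOptimizer(resolution=11)
        assert opt.get_params()["resolution"] == 11
        opt.set_params(resolution=21)
        assert opt.resolution == 21
        with pytest.raises(ValueError):
            opt.set_params(bogus=1)
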