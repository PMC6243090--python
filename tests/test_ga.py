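"""Genetic-algorithm calibration: bounds, encoding, cost, optimisation."""

import numpy as np
import pytest

import emgnms as E
from emgnms.ga import (
    GAConfig,
    GENES_PER_MUSCLE,
    ParameterBounds,
    chromosome_length,
    decode,
    encode,
    fix_gauge,
    make_bounds,
    make_cost,
    optimize_ga,
)
from emgnms.gravity import ArmAnthropometry
from emgnms.linear import calibrate_linear
from emgnms.muscle import MuscleTendonUnit


@pytest.fixture(scope="module")
def setup(defaults):
    models, anthro0 = defaults
    return models, anthro0


class TestBounds:
    def test_maximum_force_range(self, setup):
        models, anthro0 = setup
        b = make_bounds(models["elbow"], anthro0)
        i = b.names.index("BB.F_O")
        F = models["elbow"].muscles[0].F_O
        assert b.lower[i] == pytest.approx(0.7 * F)
        assert b.upper[i] == pytest.approx(4.0 * F)

    def test_sigma_range_is_ten_percent(self, setup):
        models, anthro0 = setup
        b = make_bounds(models["elbow"], anthro0)
        i = b.names.index("BB.sigma_A")
        s = models["elbow"].muscles[0].sigma_A
        assert b.lower[i] == pytest.approx(0.9 * s)
        assert b.upper[i] == pytest.approx(1.1 * s)

    def test_defaults_always_feasible(self, setup):
        models, anthro0 = setup
        for joint in ("elbow", "shoulder"):
            b = make_bounds(models[joint], anthro0)
            assert b.contains(encode(models[joint], anthro0))

    def test_negative_coefficient_bounds_are_ordered(self, setup):
        models, anthro0 = setup
        b = make_bounds(models["elbow"], anthro0)
        assert np.all(b.lower < b.upper)

    def test_zero_default_coefficient_widened_with_warning(self, setup):
        models, anthro0 = setup
        m0 = models["elbow"].muscles[0]
        from dataclasses import replace
        degenerate = replace(m0, coeff_l=(0.1, 0.0, 0.0, 0.0))
        model = replace(models["elbow"], muscles=(degenerate, models["elbow"].muscles[1]))
        with pytest.warns(UserWarning, match="degenerate"):
            b = make_bounds(model, anthro0)
        i = b.names.index("BB.coeff_l[1]")
        assert b.lower[i] < 0 < b.upper[i]


class TestChromosome:
    def test_shoulder_layout_has_50_genes(self, setup):
        models, anthro0 = setup
        assert chromosome_length("shoulder") == 50
        assert encode(models["shoulder"], anthro0).size == 50

    def test_elbow_layout_has_25_genes(self, setup):
        models, anthro0 = setup
        assert chromosome_length("elbow") == 25
        assert encode(models["elbow"], anthro0).size == 25

    def test_twelve_parameters_per_muscle(self):
        assert GENES_PER_MUSCLE == 12

    def test_roundtrip_on_random_in_bounds_vectors(self, setup):
        models, anthro0 = setup
        rng = np.random.default_rng(6)
        for joint in ("elbow", "shoulder"):
            b = make_bounds(models[joint], anthro0)
            for _ in range(10):
                genes = b.lower + (b.upper - b.lower) * rng.random(b.n_genes)
                model, anthro = decode(genes, models[joint], anthro0)
                assert np.allclose(encode(model, anthro), genes, rtol=1e-14)

    def test_length_mismatch_raises(self, setup):
        models, anthro0 = setup
        with pytest.raises(ValueError, match="genes"):
            decode(np.zeros(30), models["elbow"], anthro0)


class TestCost:
    def test_cost_of_defaults_equals_evaluation_erms(self, setup,
                                                     noiseless_linear_case):
        """With the chromosome frozen at the defaults, the GA cost equals
        the non-optimised model's E_RMS from the evaluation module."""
        models, anthro0 = setup
        train = noiseless_linear_case["train"]
        for joint in ("elbow", "shoulder"):
            cost = make_cost(train, models[joint], anthro0)
            expected = E.evaluate_model(models[joint], anthro0, train)["e_rms"]
            assert cost(encode(models[joint], anthro0)) == pytest.approx(
                expected, rel=1e-12
            )

    def test_perfect_prediction_gives_zero_cost(self, setup, noiseless_linear_case):
        models, anthro0 = setup
        train = noiseless_linear_case["train"]
        model = models["elbow"]
        pred = E.predict_external_torque(model, anthro0, train)
        doctored = Design_with_target(train, tau_el=pred)
        cost = make_cost(doctored, model, anthro0)
        assert cost(encode(model, anthro0)) == pytest.approx(0.0, abs=1e-12)

    def test_constant_offset_costs_its_magnitude(self, setup, noiseless_linear_case):
        models, anthro0 = setup
        train = noiseless_linear_case["train"]
        model = models["elbow"]
        pred = E.predict_external_torque(model, anthro0, train)
        doctored = Design_with_target(train, tau_el=pred + 2.5)
        cost = make_cost(doctored, model, anthro0)
        assert cost(encode(model, anthro0)) == pytest.approx(2.5, rel=1e-12)

    def test_invalid_geometry_returns_penalty(self, setup, noiseless_linear_case):
        models, anthro0 = setup
        train = noiseless_linear_case["train"]
        genes = encode(models["elbow"], anthro0)
        genes[4:8] = [-0.01, 0, 0, 0]  # negative fiber length at every pose
        cost = make_cost(train, models["elbow"], anthro0)
        assert cost(genes) == 1e6


def Design_with_target(design, tau_el=None, tau_sh=None):
    from dataclasses import replace

    kw = {}
    if tau_el is not None:
        kw["tau_m_el"] = np.asarray(tau_el)
    if tau_sh is not None:
        kw["tau_m_sh"] = np.asarray(tau_sh)
    return replace(design, **kw)


class TestOptimizer:
    def _toy_bounds(self):
        return ParameterBounds(
            lower=np.array([0.0]), upper=np.array([1.0]), names=("x",), joint="elbow"
        )

    def test_toy_quadratic_optimum_found(self):
        cost = lambda g: float((g[0] - 0.3) ** 2)
        res = optimize_ga(cost, self._toy_bounds(),
                          GAConfig(seed=0, max_generations=50, polish=False))
        assert abs(res.best_genes[0] - 0.3) < 0.01

    def test_best_cost_trace_is_monotone_nonincreasing(self):
        cost = lambda g: float(np.sin(13 * g[0]) + (g[0] - 0.7) ** 2)
        res = optimize_ga(cost, self._toy_bounds(),
                          GAConfig(seed=1, max_generations=80))
        assert np.all(np.diff(res.trace) <= 0)

    def test_zero_generations_returns_initial_best(self):
        cost = lambda g: float(g[0])
        res = optimize_ga(cost, self._toy_bounds(),
                          GAConfig(seed=2, max_generations=0))
        assert res.trace.size == 1
        assert res.stop_reason == "max_generations"

    def test_all_evaluated_individuals_respect_bounds(self):
        seen = []

        def cost(g):
            seen.append(g.copy())
            return float((g[0] - 0.5) ** 2)

        optimize_ga(cost, self._toy_bounds(),
                    GAConfig(seed=3, max_generations=30, polish=False))
        seen = np.array(seen)
        assert np.all(seen >= 0.0) and np.all(seen <= 1.0)

    def test_stall_criterion_fires_and_is_recorded(self):
        cost = lambda g: 1.0  # flat landscape: immediate stall
        res = optimize_ga(cost, self._toy_bounds(),
                          GAConfig(seed=4, max_generations=400,
                                   stall_generations=10, fitness_tol=1e-9))
        assert res.stop_reason == "fitness_variation"
        assert res.n_generations < 400


class TestGaugeFixing:
    def test_gauge_fix_preserves_cost_exactly(self, setup, noiseless_linear_case):
        models, anthro0 = setup
        train = noiseless_linear_case["train"]
        rng = np.random.default_rng(8)
        for joint in ("elbow", "shoulder"):
            b = make_bounds(models[joint], anthro0)
            cost = make_cost(train, models[joint], anthro0)
            defaults_vec = encode(models[joint], anthro0)
            for _ in range(5):
                genes = b.lower + (b.upper - b.lower) * rng.random(b.n_genes)
                fixed = fix_gauge(genes, b, defaults_vec)
                assert b.contains(fixed)
                assert cost(fixed) == pytest.approx(cost(genes), rel=1e-9)


class TestCalibration:
    def test_ga_beats_linear_fit_in_most_seeded_runs(self, setup,
                                                     noiseless_full_case):
        """On deterministic data from an in-bounds ground truth, the GA's
        validation error beats the linear fit's in at least 80% of seeded
        runs (the deep calibration can correct geometry mismatch that the
        linear method cannot)."""
        models, anthro0 = setup
        train = noiseless_full_case["train"]
        val = noiseless_full_case["val"]
        lo = calibrate_linear(train, models["elbow"], anthro0)
        lo_val = E.evaluate_model(lo.model, lo.anthro, val)["e_rms"]
        wins = 0
        n_runs = 10
        for seed in range(n_runs):
            ga = E.calibrate_ga(train, models["elbow"], anthro0,
                                GAConfig(seed=seed, max_generations=120))
            ga_val = E.evaluate_model(ga.model, ga.anthro, val)["e_rms"]
            wins += ga_val <= lo_val
        assert wins >= 0.8 * n_runs

    def test_calibrated_model_stays_in_bounds(self, setup, noiseless_full_case):
        models, anthro0 = setup
        train = noiseless_full_case["train"]
        fit = E.calibrate_ga(train, models["elbow"], anthro0,
                             GAConfig(seed=9, max_generations=60))
        b = make_bounds(models["elbow"], anthro0)
        assert b.contains(encode(fit.model, fit.anthro))
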