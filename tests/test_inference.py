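"""Interpolation, the weighted objective, and the genetic algorithm."""

import numpy as np
import pandas as pd
import pytest

from mapkfit.dynamics import RasInput, build_initial_condition
from mapkfit.inference import (
    GAConfig,
    ObjectiveSpec,
    TimeCourseDataset,
    interpolate_timecourse,
    make_objective,
    multi_start,
    run_ga,
    weighted_error,
)
from mapkfit.synthetic import SyntheticSpec, generate_dataset, sample_ground_truth


def five_point_dataset(values, kinase="MEK", compartment="cytosol", kind="normalized"):
    return TimeCourseDataset(pd.DataFrame({
        "kinase": kinase,
        "compartment": compartment,
        "time_min": [0.0, 1.0, 5.0, 10.0, 20.0],
        "value": values,
        "kind": kind,
    }))


class TestDataset:
    def test_duplicate_rows_rejected(self):
        frame = pd.DataFrame({
            "kinase": ["MEK", "MEK"], "compartment": ["cytosol"] * 2,
            "time_min": [5.0, 5.0], "value": [1.0, 1.0], "kind": ["normalized"] * 2,
        })
        with pytest.raises(ValueError, match="duplicate"):
            TimeCourseDataset(frame)

    def test_normalized_trace_must_anchor_at_one(self):
        with pytest.raises(ValueError, match="equal 1"):
            five_point_dataset([0.0, 0.5, 0.9, 1.2, 0.8])


class TestInterpolation:
    def test_linear_between_measured_points(self):
        dense = interpolate_timecourse(five_point_dataset([0.0, 0.2, 1.0, 0.8, 1.0],
                                                          kind="absolute"))
        t, v, _ = dense.trace("MEK", "cytosol")
        assert v[np.isclose(t, 3.0)][0] == pytest.approx(0.2 + (1.0 - 0.2) * 2 / 4)

    def test_dense_grid_has_sixteen_new_points(self):
        dense = interpolate_timecourse(five_point_dataset([0.0, 0.2, 1.0, 0.8, 1.0],
                                                          kind="absolute"))
        t, v, _ = dense.trace("MEK", "cytosol")
        assert len(t) == 21
        measured = {0.0, 1.0, 5.0, 10.0, 20.0}
        assert sum(1 for x in t if x not in measured) == 16

    def test_measured_points_reproduced_exactly(self):
        vals = [0.3, 0.6, 1.0, 0.9, 0.4]
        dense = interpolate_timecourse(five_point_dataset(vals, kind="absolute"))
        t, v, _ = dense.trace("MEK", "cytosol")
        for tm, vm in zip([0, 1, 5, 10, 20], vals):
            assert v[np.isclose(t, tm)][0] == vm

    def test_constant_trace_stays_constant(self):
        dense = interpolate_timecourse(five_point_dataset([1.0] * 5))
        _, v, _ = dense.trace("MEK", "cytosol")
        np.testing.assert_allclose(v, 1.0)

    def test_missing_measured_time_rejected(self):
        frame = pd.DataFrame({
            "kinase": "MEK", "compartment": "cytosol",
            "time_min": [0.0, 1.0, 5.0, 10.0], "value": [0.1, 0.2, 1.0, 0.9],
            "kind": "normalized",
        })
        with pytest.raises(ValueError, match="measured times"):
            interpolate_timecourse(TimeCourseDataset(frame))


class TestWeightedError:
    def test_perfect_agreement_is_zero(self):
        dense = interpolate_timecourse(five_point_dataset([0.0, 0.2, 1.0, 0.8, 1.0],
                                                          kind="absolute"))
        spec = ObjectiveSpec.for_dataset(dense)
        t, y, _ = dense.trace("MEK", "cytosol")
        assert weighted_error({("MEK", "cytosol"): y}, dense, spec) == 0.0

    def test_residual_arithmetic(self):
        data = five_point_dataset([0.0, 0.2, 1.0, 0.8, 1.0], kind="absolute")
        spec = ObjectiveSpec(fit_grid=np.array([0, 1, 5, 10, 20.0]),
                             weights={("MEK", "cytosol"): 1.0})
        t, y, _ = data.trace("MEK", "cytosol")
        sim = y.copy()
        sim[0] += 0.1
        sim[1] -= 0.1
        assert weighted_error({("MEK", "cytosol"): sim}, data, spec) == pytest.approx(0.02)

    def test_weight_scaling_equivalence(self):
        # residual r with weight w scores like residual r/w with weight 1
        data = five_point_dataset([0.0, 0.2, 1.0, 0.8, 1.0], kind="absolute")
        t, y, _ = data.trace("MEK", "cytosol")
        heavy = ObjectiveSpec(fit_grid=t, weights={("MEK", "cytosol"): 2.0})
        unit = ObjectiveSpec(fit_grid=t, weights={("MEK", "cytosol"): 1.0})
        e_heavy = weighted_error({("MEK", "cytosol"): y + 0.2}, data, heavy)
        e_unit = weighted_error({("MEK", "cytosol"): y + 0.1}, data, unit)
        assert e_heavy == pytest.approx(e_unit)
        # brute-force recomputation
        assert e_heavy == pytest.approx(float(np.sum((0.2 / 2.0) ** 2 * np.ones(5))))

    def test_missing_trace_rejected(self):
        data = five_point_dataset([0.0, 0.2, 1.0, 0.8, 1.0], kind="absolute")
        spec = ObjectiveSpec()
        with pytest.raises(KeyError):
            weighted_error({}, data, spec)

    def test_default_weights_follow_kind(self):
        rows = []
        for kind, kin in [("normalized", "MEK"), ("absolute", "ERK")]:
            rows.append(pd.DataFrame({
                "kinase": kin, "compartment": "total",
                "time_min": [0.0, 1.0, 5.0, 10.0, 20.0],
                "value": [0.0, 0.5, 1.0, 0.9, 0.4] if kind == "normalized"
                         else [0.0, 0.3, 0.48, 0.4, 0.2],
                "kind": kind,
            }))
        dense = interpolate_timecourse(TimeCourseDataset(pd.concat(rows)))
        spec = ObjectiveSpec.for_dataset(dense)
        assert spec.weight("MEK", "total") == 1.0
        assert spec.weight("ERK", "total") == pytest.approx(0.48)


def quadratic_objective(target):
    return lambda rates: float(np.sum((rates - target) ** 2))


class TestGeneticAlgorithm:
    def test_beats_initial_population_on_toy_problem(self):
        target = np.array([3.0, 7.0, 1.5])
        obj = quadratic_objective(target)
        cfg = GAConfig(generations=200, population=30, w_max=10.0, seed=4)
        cand = run_ga(obj, 3, cfg)
        # median error of a uniform-random population at the same budget
        rng = np.random.default_rng(4)
        random_errors = [obj(rng.uniform(0, 10, 3)) for _ in range(30)]
        assert cand.error < 1e-2 * float(np.median(random_errors))
        assert cand.error < min(random_errors)

    def test_deterministic_given_seed(self):
        obj = quadratic_objective(np.array([2.0, 5.0]))
        cfg = GAConfig(generations=30, population=20, w_max=10.0, seed=9)
        a, b = run_ga(obj, 2, cfg), run_ga(obj, 2, cfg)
        assert a.error == b.error
        assert np.array_equal(a.rates.values, b.rates.values)

    def test_degenerate_single_individual(self):
        obj = quadratic_objective(np.array([1.0]))
        cfg = GAConfig(generations=5, population=1, w_max=10.0,
                       crossover_rate=0.0, mutation_rate=0.0, seed=2)
        cand = run_ga(obj, 1, cfg)
        # no variation operators: the best-of-initial individual survives
        assert cand.error == pytest.approx(obj(cand.rates.values))
        assert np.all(np.asarray(cand.history) == cand.history[0])

    def test_best_ever_error_never_increases(self):
        obj = quadratic_objective(np.array([4.0, 2.0, 8.0, 0.5]))
        cand = run_ga(obj, 4, GAConfig(generations=60, population=16, w_max=10.0, seed=1))
        assert np.all(np.diff(cand.history) <= 0)


class TestMultiStart:
    def test_ranking_contract(self):
        obj = quadratic_objective(np.array([3.0, 1.0]))
        cfg = GAConfig(generations=10, population=10, w_max=5.0, seed=0)
        ranked = multi_start(obj, 2, cfg, n_seeds=3, top_k=2)
        assert len(ranked) == 3
        errors = [c.error for c in ranked]
        assert errors == sorted(errors)
        assert [c.selected for c in ranked] == [True, True, False]
        assert [c.rank for c in ranked] == [0, 1, 2]

    def test_duplicate_seeds_rejected(self):
        obj = quadratic_objective(np.array([1.0]))
        cfg = GAConfig(generations=2, population=4, w_max=5.0, seed=0)
        with pytest.raises(ValueError, match="distinct"):
            multi_start(obj, 1, cfg, n_seeds=2, top_k=1, seeds=[3, 3])

    def test_top_k_bounds_validated(self):
        obj = quadratic_objective(np.array([1.0]))
        cfg = GAConfig(generations=2, population=4, w_max=5.0, seed=0)
        with pytest.raises(ValueError, match="top_k"):
            multi_start(obj, 1, cfg, n_seeds=2, top_k=3)


class TestTrajectoryRecovery:
    def test_fit_beats_true_rates_on_interpolated_data(self, network):
        """Trajectory recovery, not parameter recovery: a short GA run must
        score at or below the true rates against the interpolated noiseless
        data (the truth itself carries the interpolation mismatch)."""
        rng = np.random.default_rng(42)
        truth = sample_ground_truth(network, rng)
        data = generate_dataset(network, SyntheticSpec(
            ground_truth=truth, system="system1", cv=0.0, seed=1))
        dense = interpolate_timecourse(data)
        init = build_initial_condition("system1")
        ras = RasInput(peak_amplitude=init.ras_amplitude)
        objective = make_objective(network, init, ras, dense)
        floor = objective(truth.values)
        cand = run_ga(objective, network.n_rates,
                      GAConfig(generations=15, population=24, seed=0),
                      network.rate_names)
        assert cand.error <= floor

    def test_integration_failure_ranks_worst(self, network):
        from mapkfit.inference import PENALTY_BASE

        rng = np.random.default_rng(42)
        truth = sample_ground_truth(network, rng)
        data = generate_dataset(network, SyntheticSpec(
            ground_truth=truth, system="system1", cv=0.0, seed=1))
        dense = interpolate_timecourse(data)
        init = build_initial_condition("system1")
        objective = make_objective(network, init,
                                   RasInput(peak_amplitude=1.0), dense)
        # all-zero rates produce no activity: degenerate normalization
        assert objective(np.zeros(network.n_rates)) >= PENALTY_BASE
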