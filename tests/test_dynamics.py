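"""Integration, observables, and the normalization/rescaling arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mapkfit.dynamics import (
    ActivityTrace,
    DegenerateNormalizationError,
    RasInput,
    build_initial_condition,
    default_grid,
    normalize_at_reference,
    observable_activity,
    rescale_to_absolute,
    simulate,
    trajectory_conservation_error,
)
from mapkfit.network import conservation_totals, make_rate_vector


class TestRasInput:
    def test_parametric_pulse_shape(self):
        ras = RasInput(peak_amplitude=0.4, peak_time=2.0)
        assert ras(0.0) == 0.0
        assert ras(2.0) == pytest.approx(0.4)  # peak value A at t_p
        assert 0 < ras(10.0) < ras(2.0)

    def test_tabulated_interpolation_and_validation(self):
        ras = RasInput("tabulated", table=[(0, 0.0), (2, 0.4), (20, 0.1)])
        assert ras(1.0) == pytest.approx(0.2)
        with pytest.raises(ValueError, match="increasing"):
            RasInput("tabulated", table=[(0, 0.1), (0, 0.2)])
        with pytest.raises(ValueError, match="non-negative"):
            RasInput("tabulated", table=[(0, -0.1), (1, 0.2)])

    def test_rescaled_preserves_shape(self):
        ras = RasInput(peak_amplitude=0.4, peak_time=2.0)
        low = ras.rescaled(0.004)
        t = np.linspace(0.1, 20, 50)
        np.testing.assert_allclose(low(t) / ras(t), 0.01)


class TestSimulate:
    def test_zero_rates_keep_initial_state(self, network, system2, ras2):
        rates = make_rate_vector(network, np.zeros(network.n_rates))
        traj = simulate(network, rates, system2, ras2)
        np.testing.assert_allclose(traj.states - traj.states[0], 0.0, atol=1e-12)

    def test_shuttling_two_box_closed_form(self, network, system2, ras2):
        # only MEK shuttles (both constants 1): the cytosolic/nuclear pools
        # relax as 0.7 (1 +/- exp(-2t)) from [MEK](0) = 1.4
        vals = np.zeros(network.n_rates)
        names = list(network.rate_names)
        vals[names.index("kin_MEK")] = 1.0
        vals[names.index("kout_MEK")] = 1.0
        traj = simulate(network, make_rate_vector(network, vals), system2, ras2)
        i_c, i_n = network.species_index("MEK"), network.species_index("N-MEK")
        for t in (1.0, 5.0):
            expected_c = 0.7 * (1 + np.exp(-2 * t))
            expected_n = 0.7 * (1 - np.exp(-2 * t))
            assert traj.state_at(t)[i_c] == pytest.approx(expected_c, abs=1e-6)
            assert traj.state_at(t)[i_n] == pytest.approx(expected_n, abs=1e-6)

    def test_mass_conservation_along_trajectory(self, network, system2, ras2, moderate_rates):
        traj = simulate(network, moderate_rates, system2, ras2)
        assert trajectory_conservation_error(traj) < 1e-6
        start = conservation_totals(network, traj.states[0])
        end = conservation_totals(network, traj.states[-1])
        for base, v0 in start.items():
            assert end[base] == pytest.approx(v0, rel=1e-6)

    def test_non_negative_concentrations(self, network, system1, ras1, moderate_rates):
        traj = simulate(network, moderate_rates, system1, ras1)
        assert traj.states.min() >= -1e-9

    def test_grid_refinement_consistency(self, network, system1, ras1, moderate_rates):
        coarse = simulate(network, moderate_rates, system1, ras1, default_grid(dt=1.0))
        fine = simulate(network, moderate_rates, system1, ras1, default_grid(dt=0.5))
        act_c = observable_activity(coarse, "ERK", "total").values
        act_f = observable_activity(fine, "ERK", "total").values[::2]
        assert np.max(np.abs(act_c - act_f)) / np.max(np.abs(act_c)) < 1e-6

    def test_determinism(self, network, system1, ras1, moderate_rates):
        a = simulate(network, moderate_rates, system1, ras1)
        b = simulate(network, moderate_rates, system1, ras1)
        assert np.array_equal(a.states, b.states)


class TestObservables:
    def test_free_mekpp_only(self, network):
        state = np.zeros(network.n_species)
        state[network.species_index("MEKpp")] = 0.07
        traj = _single_state_traj(network, state)
        assert observable_activity(traj, "MEK", "cytosol").values[0] == pytest.approx(0.07)

    def test_zero_state_zero_activity(self, network):
        traj = _single_state_traj(network, np.zeros(network.n_species))
        for kinase, comp in [("Raf", "cytosol"), ("MEK", "total"), ("ERK", "nucleus")]:
            assert observable_activity(traj, kinase, comp).values[0] == 0.0

    def test_complex_counts_for_enzyme_not_substrate(self, network):
        state = np.zeros(network.n_species)
        state[network.species_index("MEKpp:ERK")] = 0.01
        traj = _single_state_traj(network, state)
        assert observable_activity(traj, "MEK", "cytosol").values[0] == pytest.approx(0.01)
        assert observable_activity(traj, "ERK", "total").values[0] == 0.0

    def test_free_only_switch(self, network):
        state = np.zeros(network.n_species)
        state[network.species_index("MEKpp")] = 0.02
        state[network.species_index("MEKpp:ERK")] = 0.01
        traj = _single_state_traj(network, state)
        assert observable_activity(traj, "MEK", "cytosol", free_only=True).values[0] == pytest.approx(0.02)
        assert observable_activity(traj, "MEK", "cytosol").values[0] == pytest.approx(0.03)

    def test_compartment_additivity(self, network, system1, ras1, moderate_rates):
        traj = simulate(network, moderate_rates, system1, ras1)
        for kinase in ("MEK", "ERK"):
            cyt = observable_activity(traj, kinase, "cytosol").values
            nuc = observable_activity(traj, kinase, "nucleus").values
            tot = observable_activity(traj, kinase, "total").values
            np.testing.assert_allclose(cyt + nuc, tot, rtol=1e-12, atol=1e-15)

    def test_raf_in_nucleus_rejected(self, network):
        traj = _single_state_traj(network, np.zeros(network.n_species))
        with pytest.raises(ValueError, match="cytosolic"):
            observable_activity(traj, "Raf", "nucleus")


def _single_state_traj(network, state):
    from mapkfit.dynamics import Trajectory

    return Trajectory(np.array([0.0]), state[None, :], np.array([0.0]), network)


class TestNormalization:
    def test_five_point_example(self):
        trace = ActivityTrace("MEK", "cytosol", "raw",
                              np.array([0., 1., 5., 10., 20.]),
                              np.array([0.0, 0.2, 0.5, 0.8, 1.0]))
        normalized = normalize_at_reference(trace)
        np.testing.assert_allclose(normalized.values, [0.0, 0.4, 1.0, 1.6, 2.0])
        assert normalized.kind == "normalized"

    def test_constant_trace_becomes_ones(self):
        trace = ActivityTrace("ERK", "total", "raw",
                              np.array([0., 5., 20.]), np.full(3, 0.37))
        np.testing.assert_allclose(normalize_at_reference(trace).values, 1.0)

    def test_zero_reference_raises(self):
        trace = ActivityTrace("ERK", "total", "raw",
                              np.array([0., 5., 20.]), np.zeros(3))
        with pytest.raises(DegenerateNormalizationError):
            normalize_at_reference(trace)

    def test_rescale_anchors(self):
        times = np.array([0., 5., 20.])
        normalized = ActivityTrace("MEK", "total", "normalized", times,
                                   np.array([0.5, 1.0, 0.8]))
        absolute = rescale_to_absolute(normalized, 1.4 * 0.05)
        assert absolute.value_at(5.0) == pytest.approx(0.07)
        erk = rescale_to_absolute(
            ActivityTrace("ERK", "total", "normalized", times, np.array([0.2, 1.0, 0.6])),
            0.96 * 0.50,
        )
        assert erk.value_at(5.0) == pytest.approx(0.48)

    def test_rescale_by_zero_gives_zero_trace(self):
        normalized = ActivityTrace("MEK", "total", "normalized",
                                   np.array([0., 5.]), np.array([0.5, 1.0]))
        assert np.all(rescale_to_absolute(normalized, 0.0).values == 0.0)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0.01, 100.0), min_size=3, max_size=3))
    def test_normalize_rescale_round_trip(self, values):
        trace = ActivityTrace("ERK", "cytosol", "raw",
                              np.array([0., 5., 20.]), np.array(values))
        back = rescale_to_absolute(normalize_at_reference(trace), trace.value_at(5.0))
        np.testing.assert_allclose(back.values, trace.values, rtol=1e-12)

    def test_rescale_preserves_ratios(self):
        times = np.array([0., 5., 10.])
        normalized = ActivityTrace("MEK", "total", "normalized", times,
                                   np.array([0.25, 1.0, 1.75]))
        absolute = rescale_to_absolute(normalized, 0.07)
        np.testing.assert_allclose(absolute.values / absolute.value_at(5.0),
                                   normalized.values)


class TestInitialConditions:
    def test_system1_all_unit(self, system1):
        assert all(v == 1.0 for v in system1.totals.values())
        assert system1.ras_amplitude == 1.0

    def test_system2_table(self, system2):
        assert system2.totals["P_MEK"] == pytest.approx(0.14)
        assert system2.totals["Raf"] == pytest.approx(0.013)
        assert system2.ras_amplitude == pytest.approx(0.4)

    def test_system2_activated_anchors(self, system2):
        assert system2.activated_at_ref["MEK"] == pytest.approx(1.4 * 0.05)
        assert system2.activated_at_ref["ERK"] == pytest.approx(0.48)

    def test_unknown_system_rejected(self):
        with pytest.raises(ValueError):
            build_initial_condition("system3")

    def test_unlisted_species_start_at_zero(self, network, system2):
        state = system2.to_state(network)
        nonzero = {network.species[i].name for i in np.nonzero(state)[0]}
        assert nonzero == {"Raf", "MEK", "ERK", "P_Raf", "P_MEK", "P_ERK",
                           "N-P_MEK", "N-P_ERK"}
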