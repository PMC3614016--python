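"""Synthetic-trace generation: schedules, mixing, dead time, noise,
titrations."""

import numpy as np
import pytest
from pydantic import ValidationError

from clampflow import (
    ExperimentDesign,
    RateParameters,
    add_noise,
    generate_titration_series,
    loading_design,
    reload_design,
    run_design,
    sampling_schedule,
    simulate_noisy,
    unload_trap_design,
)
from clampflow.stoichiometry import labeled_fraction_from_design


class TestSamplingSchedule:
    def test_loading_schedule_is_8000_points_over_60s(self):
        s = sampling_schedule("loading", 60.0)
        assert s.segments == [(10.0, 5000), (50.0, 3000)]
        grid = s.grid()
        assert len(grid) == 8000
        assert np.sum(grid <= 10.0) == 5000
        assert grid[-1] == pytest.approx(60.0)

    @pytest.mark.parametrize("duration,expected", [(60.0, 1000), (180.0, 3000)])
    def test_unloading_schedule_density(self, duration, expected):
        s = sampling_schedule("unloading", duration)
        assert s.n_points == expected

    def test_grid_strictly_increasing(self):
        grid = sampling_schedule("loading", 60.0).grid()
        assert np.all(np.diff(grid) > 0)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            sampling_schedule("loading", 0.0)


class TestDesignValidation:
    def test_poldelta_forbidden_in_plain_reload(self):
        with pytest.raises(ValidationError, match="poldelta"):
            ExperimentDesign(
                kind="reload",
                syringe_A={"rfc": 100.0, "pcna_unlabeled": 100.0, "dna": 200.0},
                syringe_B={"pcna_labeled": 100.0, "poldelta": 50.0},
            )

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValidationError):
            ExperimentDesign(kind="loading", syringe_A={"rfc": -5.0})

    def test_unknown_species_rejected(self):
        with pytest.raises(ValidationError, match="unknown species"):
            ExperimentDesign(kind="loading", syringe_A={"helicase": 10.0})

    def test_duration_must_exceed_dead_time(self):
        with pytest.raises(ValidationError):
            ExperimentDesign(kind="loading", syringe_A={"rfc": 1.0},
                             total_duration=0.001, dead_time=0.002)


class TestRunDesign:
    def test_mixing_halves_concentrations(self, params, loading_trace):
        # premix 200 nM of each; the trajectory starts from 100 nM totals
        net, traj = loading_trace.network, loading_trace.trajectory
        dna_total = traj.concentrations[0, list(net.conservation["dna"])].sum()
        loader_total = traj.concentrations[0, list(net.conservation["loader"])].sum()
        assert dna_total == pytest.approx(100.0)
        assert loader_total == pytest.approx(100.0)

    def test_no_sample_before_dead_time(self, loading_trace):
        assert loading_trace.time[0] >= loading_trace.design.dead_time

    def test_loading_with_zero_rfc_is_flat_baseline(self, params):
        clean = run_design(loading_design(rfc=0.0), params)
        np.testing.assert_allclose(clean.signal, 0.1, rtol=0, atol=1e-9)

    def test_zero_clamp_is_flat_not_error(self, params):
        clean = run_design(loading_design(pcna_labeled=0.0), params)
        np.testing.assert_allclose(clean.signal, 0.1, rtol=0, atol=1e-9)

    def test_unload_without_trap_stays_at_equilibrium_plateau(self, params):
        clean = run_design(unload_trap_design(trap=0.0), params)
        assert np.ptp(clean.signal) < 0.005 * clean.signal.mean()

    def test_loading_rise_fall_plateau(self, loading_trace):
        y, t = loading_trace.signal, loading_trace.time
        i_peak = np.argmax(y)
        assert 0 < i_peak < len(y) - 1
        assert y[i_peak] > y[0]            # rise
        late = y[t > 10.0]
        assert y[i_peak] > late[0]         # fall after the peak
        assert np.ptp(late) < 0.02 * np.ptp(y)  # flat plateau out to 60 s


class TestAddNoise:
    def test_zero_sigma_returns_input_exactly(self, loading_trace):
        noisy = add_noise(loading_trace, 0.0, seed=5)
        np.testing.assert_array_equal(noisy.signal, loading_trace.signal)

    def test_same_seed_reproducible(self, loading_trace):
        a = add_noise(loading_trace, 0.01, seed=11)
        b = add_noise(loading_trace, 0.01, seed=11)
        np.testing.assert_array_equal(a.signal, b.signal)
        c = add_noise(loading_trace, 0.01, seed=12)
        assert not np.array_equal(a.signal, c.signal)

    def test_noise_mean_within_clt_bound(self, loading_trace):
        sigma = 0.01
        noisy = add_noise(loading_trace, sigma, seed=3)
        diff = noisy.signal - loading_trace.signal
        assert abs(diff.mean()) < 4 * sigma / np.sqrt(len(diff))

    def test_negative_sigma_rejected(self, loading_trace):
        with pytest.raises(ValueError):
            add_noise(loading_trace, -0.1, seed=0)


class TestTitrationSeries:
    def test_labeled_fractions_of_study_titration(self):
        for lab, expected in [(33.0, 0.25), (100.0, 0.50), (300.0, 0.75)]:
            frac = labeled_fraction_from_design(reload_design(pcna_labeled=lab))
            assert frac == pytest.approx(expected, abs=0.002)

    def test_zero_member_of_rfc_series_is_flat(self, params):
        traces = generate_titration_series(
            loading_design(), "rfc", [0.0, 100.0], params, sigma=0.0, seed=9
        )
        assert np.ptp(traces[0].signal) < 1e-9
        assert np.ptp(traces[1].signal) > 0.05

    def test_member_seeds_derived_from_base(self, params):
        traces = generate_titration_series(
            loading_design(), "rfc", [50.0, 100.0], params, sigma=0.005, seed=40
        )
        assert [t.metadata["seed"] for t in traces] == [40, 41]

    def test_unknown_species_rejected(self, params):
        with pytest.raises(ValueError, match="species"):
            generate_titration_series(loading_design(), "ligase", [1.0], params)


def test_noisy_simulation_defaults_to_one_percent_noise(params):
    clean, noisy = simulate_noisy(loading_design(), params, seed=0)
    assert noisy.metadata["noise_sigma"] == pytest.approx(
        0.01 * np.ptp(clean.signal))
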