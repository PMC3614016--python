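"""Multi-exponential fitting: exact recovery, amplitude bookkeeping,
phase-count selection."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from clampflow import (
    PhaseCollapseWarning,
    dead_time_amplitude,
    fit_multiexponential,
    half_life,
    relative_amplitudes,
    select_phase_count,
    total_amplitude,
)
from clampflow.fitting import ExponentialFit


def synth(t, c, phases):
    y = np.full_like(t, c, dtype=float)
    for a, k in phases:
        y = y + a * np.exp(-k * t)
    return y


T_UNLOAD = np.linspace(0.06, 60.0, 1000)


class TestExactRecovery:
    @pytest.mark.parametrize("phases", [
        [(0.35, 0.32), (0.080, 0.026)],    # trap-dissociation amplitudes
        [(0.32, 0.40), (0.067, 0.039)],
        [(-0.5, 6.4), (0.3, 1.4)],         # rise + fall
    ])
    def test_noise_free_biexponential_recovered_to_1e6(self, phases):
        y = synth(T_UNLOAD, 0.1, phases)
        fit = fit_multiexponential((T_UNLOAD, y), 2)
        want = sorted(phases, key=lambda p: -p[1])
        for (a_f, k_f), (a_w, k_w) in zip(fit.phases, want):
            assert k_f == pytest.approx(k_w, rel=1e-6)
            assert a_f == pytest.approx(a_w, rel=1e-6)
        assert fit.c_inf == pytest.approx(0.1, rel=1e-6)

    def test_single_exponential_exact_and_two_phase_collapse_warns(self):
        y = synth(T_UNLOAD, 0.2, [(0.5, 0.3)])
        fit1 = fit_multiexponential((T_UNLOAD, y), 1)
        assert fit1.rates[0] == pytest.approx(0.3, rel=1e-8)
        with pytest.warns(PhaseCollapseWarning):
            fit_multiexponential((T_UNLOAD, y), 2)

    def test_slow_single_phase_like_hydrolysis_disabled_unloading(self):
        t = np.linspace(0.18, 180.0, 3000)
        y = synth(t, 0.1, [(0.5, 6.2e-3)])
        fit = fit_multiexponential((t, y), 1)
        assert fit.rates[0] == pytest.approx(6.2e-3, rel=1e-6)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(
        k1=st.floats(0.05, 5.0),
        ratio=st.floats(8.0, 60.0),
        a1=st.floats(0.05, 1.0),
        a2=st.floats(0.05, 1.0),
        c=st.floats(-0.5, 0.5),
    )
    def test_self_consistency_property(self, k1, ratio, a1, a2, c):
        """Fitting a trace synthesized from any two-phase model recovers
        it to relative 1e-6 (rates well separated)."""
        k2 = k1 / ratio
        t = np.linspace(0.01, 12.0 / k2, 1200)
        y = synth(t, c, [(a1, k1), (a2, k2)])
        fit = fit_multiexponential((t, y), 2)
        assert fit.rates[0] == pytest.approx(k1, rel=1e-6)
        assert fit.rates[1] == pytest.approx(k2, rel=1e-6)
        assert fit.amplitudes[0] == pytest.approx(a1, rel=1e-5)
        assert fit.amplitudes[1] == pytest.approx(a2, rel=1e-5)

    def test_phases_sorted_fastest_first(self):
        y = synth(T_UNLOAD, 0.0, [(0.1, 0.02), (0.4, 2.0)])
        fit = fit_multiexponential((T_UNLOAD, y), 2)
        assert fit.rates[0] > fit.rates[1]

    def test_too_few_points_rejected(self):
        t = np.linspace(0.1, 1.0, 15)
        with pytest.raises(ValueError):
            fit_multiexponential((t, np.ones_like(t)), 2)


class TestDeadTimeAmplitude:
    def test_flat_no_loader_trace_has_zero_dead_amplitude(self):
        y = np.full_like(T_UNLOAD, 0.1)
        fit = fit_multiexponential((T_UNLOAD, y), 0, y0=0.1)
        assert fit.a_dead == pytest.approx(0.0, abs=1e-12)

    def test_identity_holds_exactly_as_stored(self):
        fit = ExponentialFit(c_inf=1.0, phases=[(-0.5, 2.0), (0.3, 0.5)],
                             rss=0.0, n_points=100)
        a_dead = dead_time_amplitude(fit, y0=0.2)
        # model value at time zero minus the control level
        assert a_dead == pytest.approx(fit.c_inf + (-0.5 + 0.3) - 0.2)
        assert fit.a_dead == a_dead and fit.y0 == 0.2

    def test_recovers_censored_jump_of_loading_trace(self, loading_trace):
        """The dead phase equals the clean trace's value at t=0+ minus
        the zero-FRET level, within fit tolerance."""
        fit = fit_multiexponential(
            (loading_trace.time, loading_trace.signal), 2, y0=0.1)
        true_jump = loading_trace.signal[0] - 0.1  # first sample, 2 ms in
        assert fit.a_dead == pytest.approx(true_jump, rel=0.05)


class TestAmplitudeBookkeeping:
    def test_total_amplitude_of_trap_dissociation_pair(self):
        fit = ExponentialFit(c_inf=0.0, phases=[(0.32, 0.4), (0.067, 0.04)],
                             rss=0.0, n_points=100)
        assert total_amplitude(fit) == pytest.approx(0.39, abs=0.005)
        fit2 = ExponentialFit(c_inf=0.0, phases=[(0.35, 0.4), (0.080, 0.04)],
                              rss=0.0, n_points=100)
        assert total_amplitude(fit2) == pytest.approx(0.43, abs=0.005)

    def test_no_phases_gives_zero_total(self):
        fit = ExponentialFit(c_inf=0.3, phases=[], rss=0.0, n_points=10)
        assert total_amplitude(fit) == 0.0

    def test_dead_amplitude_included_only_on_request(self):
        fit = ExponentialFit(c_inf=1.0, phases=[(-0.4, 2.0)], rss=0.0,
                             n_points=50)
        dead_time_amplitude(fit, y0=0.1)
        assert total_amplitude(fit, include_dead=False) == pytest.approx(0.4)
        assert total_amplitude(fit, include_dead=True) == pytest.approx(
            0.4 + abs(fit.a_dead))

    @pytest.mark.parametrize("amps,expected", [
        ((0.35, 0.080), (81, 19)),
        ((0.24, 0.051), (83, 17)),
    ])
    def test_relative_amplitudes_match_reported_percentages(self, amps, expected):
        fit = ExponentialFit(c_inf=0.0,
                             phases=[(amps[0], 1.0), (amps[1], 0.1)],
                             rss=0.0, n_points=100)
        rel = relative_amplitudes(fit)
        # reported percentages are rounded; match at their printed precision
        assert rel[0] == pytest.approx(expected[0], abs=1.0)
        assert rel[1] == pytest.approx(expected[1], abs=1.0)
        assert rel.sum() == pytest.approx(100.0)

    def test_single_phase_is_100_percent(self):
        fit = ExponentialFit(c_inf=0.0, phases=[(0.2, 1.0)], rss=0.0,
                             n_points=50)
        assert relative_amplitudes(fit)[0] == 100.0


class TestHalfLife:
    @pytest.mark.parametrize("k,expected,tol", [
        (0.058, 12.0, 0.5),        # slowest pulse-chase decay
        (np.log(2.0), 1.0, 1e-12),
        (6.3e-3, 110.0, 1.0),
    ])
    def test_values(self, k, expected, tol):
        assert half_life(k) == pytest.approx(expected, abs=tol)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            half_life(0.0)


class TestSelectPhaseCount:
    def test_clean_biexponential_selects_two(self):
        y = synth(T_UNLOAD, 0.1, [(0.3, 0.5), (0.1, 0.03)])
        n, report = select_phase_count((T_UNLOAD, y), max_phases=3)
        assert n == 2
        assert set(report) == {0, 1, 2, 3}

    def test_three_decay_chase_like_trace_selects_three(self):
        rng = np.random.default_rng(0)
        t = np.linspace(0.01, 60.0, 4000)
        y = synth(t, 0.1, [(0.12, 1.6), (0.10, 0.43), (0.15, 0.058)])
        y = y + rng.normal(0, 2e-4, len(t))
        n, _ = select_phase_count((t, y), max_phases=4)
        assert n == 3

    def test_flat_trace_selects_constant_model(self):
        y = np.full_like(T_UNLOAD, 0.25)
        n, _ = select_phase_count((T_UNLOAD, y))
        assert n == 0
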