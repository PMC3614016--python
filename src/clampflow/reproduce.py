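"""End-to-end recomputation of the experiments' headline quantities.

Each function runs the full pipeline — simulate the design, fit the
trace, derive the quantity — at the experimental concentrations and default
mechanism parameters.  Used by the acceptance script and the acceptance
tests; nothing here reads stored numbers, everything is computed.
"""

from __future__ import annotations

import numpy as np

from .designs import (
    NoisyTrace,
    add_noise,
    loading_design,
    pulse_chase_design,
    reload_design,
    run_design,
    sampling_schedule,
    simulate_noisy,
    unload_trap_design,
)
from .fitting import (
    ExponentialFit,
    dead_time_amplitude,
    fit_multiexponential,
    relative_amplitudes,
)
from .params import RateParameters
from .stoichiometry import (
    amplitude_ratio,
    fraction_regression,
    labeled_fraction_from_design,
)

BASELINE = 0.1
SCALE = 0.01

#: single-encounter (chase present) parameter set
PULSE_CHASE_PARAMS = dict(k_conf=6.1, k_close=1.6, k_off_fast=0.43,
                          k_off_slow=0.058)

#: reported two-population dissociation parameters: rates (s^-1),
#: fast-phase share, and total amplitude (a.u.) of the unloading trace
TWO_POPULATION_DISSOCIATION = dict(k_fast=0.40, k_slow=0.039, share_fast=0.83,
                          a_total=0.39)


def control_y0(params: RateParameters | None = None) -> float:
    """Zero-FRET level from the loader-free control trace."""
    params = params or RateParameters()
    clean = run_design(loading_design(rfc=0.0), params,
                       scale=SCALE, baseline=BASELINE)
    return float(np.mean(clean.signal))


def unload_reference_fit(params: RateParameters | None = None) -> ExponentialFit:
    """Double-exponential fit of the noise-free unload-trap simulation."""
    params = params or RateParameters()
    clean = run_design(unload_trap_design(), params,
                       scale=SCALE, baseline=BASELINE)
    return fit_multiexponential((clean.time, clean.signal), 2)


def reload_unload_ratio(
    unload_fit: ExponentialFit,
    y0: float,
    params: RateParameters | None = None,
    **reload_kwargs,
):
    """Amplitude ratio for one reload design against the unload reference."""
    params = params or RateParameters()
    design = reload_design(**reload_kwargs)
    clean = run_design(design, params, scale=SCALE, baseline=BASELINE)
    fit = fit_multiexponential((clean.time, clean.signal), 2)
    dead_time_amplitude(fit, y0)
    return amplitude_ratio(fit, unload_fit,
                           labeled_fraction=labeled_fraction_from_design(design))


def fraction_regression_study(unload_fit: ExponentialFit, y0: float):
    """Ratio-vs-labeled-fraction regression over the 33/100/300 nM series."""
    fracs, ratios = [], []
    for lab in (33.0, 100.0, 300.0):
        res = reload_unload_ratio(unload_fit, y0, pcna_labeled=lab)
        fracs.append(res.labeled_fraction)
        ratios.append(res.ratio)
    slope, intercept, r2 = fraction_regression(fracs, ratios)
    return slope, intercept, r2, fracs, ratios


def unload_recovery(seed: int):
    """Fit a seeded noisy unload trace generated from the reported
    two-population dissociation parameter set.

    The trace is the biexponential ground truth (180 s on the unloading
    schedule) plus 1%-of-full-scale Gaussian noise.  Returns
    (fast-phase relative amplitude in %, fast rate, n_points).
    """
    p = TWO_POPULATION_DISSOCIATION
    t = sampling_schedule("unloading", 180.0).grid()
    model = ExponentialFit(
        c_inf=BASELINE,
        phases=[(p["a_total"] * p["share_fast"], p["k_fast"]),
                (p["a_total"] * (1 - p["share_fast"]), p["k_slow"])],
        rss=0.0, n_points=len(t),
    )
    clean = NoisyTrace(time=t, signal=model.predict(t))
    sigma = 0.01 * float(np.ptp(clean.signal))
    noisy = add_noise(clean, sigma, seed)
    fit = fit_multiexponential((noisy.time, noisy.signal), 2)
    return float(relative_amplitudes(fit)[0]), float(fit.rates[0]), len(t)


def loading_rise_recovery(seed: int):
    """Seeded noisy loading-design simulation fitted with the dead-time
    double-exponential model; returns (rise rate, n_points)."""
    params = RateParameters()
    _, noisy = simulate_noisy(loading_design(), params, seed=seed,
                              scale=SCALE, baseline=BASELINE)
    fit = fit_multiexponential((noisy.time, noisy.signal), 2,
                               y0=control_y0(params))
    return float(fit.rates[0]), len(noisy.time)


def pulse_chase_slowest_recovery(seed: int):
    """Seeded noisy pulse-chase simulation fitted with a rise plus three
    decays; returns (slowest rate, n_points)."""
    params = RateParameters(**PULSE_CHASE_PARAMS)
    _, noisy = simulate_noisy(pulse_chase_design(), params, seed=seed,
                              scale=SCALE, baseline=BASELINE)
    fit = fit_multiexponential((noisy.time, noisy.signal), 4)
    return float(fit.rates[-1]), len(noisy.time)
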