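"""Amplitude-ratio stoichiometry inference.

The total amplitude A_T of a FRET trace is proportional to the amount of
labeled clamp gained or lost on DNA.  When a pre-assembled unlabeled
complex is mixed with labeled clamp, the ratio A_T,Reload / A_T,Unload
equals the labeled fraction of the solution clamp pool if every loaded
clamp is returned to solution — and rises to 1 when a stoichiometric
amount of polymerase captures all loaded clamp on DNA.  Plotting the
ratio against labeled fraction therefore yields the line y = x, and
titrating polymerase yields a linear rise that breaks to a plateau at
the loader/unlabeled-clamp concentration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .fitting import ExponentialFit, total_amplitude


@dataclass
class StoichiometryResult:
    a_t_unload: float
    a_t_reload: float
    ratio: float
    labeled_fraction: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "a_t_unload": self.a_t_unload,
            "a_t_reload": self.a_t_reload,
            "ratio": self.ratio,
            "labeled_fraction": self.labeled_fraction,
        }


@dataclass
class BreakpointFit:
    """Two-segment (rising line + flat plateau) fit of a titration."""

    breakpoint: Optional[float]   # None when no plateau is detectable
    slope: float
    intercept: float
    rss: float
    unbounded: bool = False       # monotone rise to the last point
    flat: bool = False            # slope ~ 0 everywhere

    def to_dict(self) -> dict:
        return {
            "breakpoint": self.breakpoint,
            "slope": self.slope,
            "intercept": self.intercept,
            "rss": self.rss,
            "unbounded": self.unbounded,
            "flat": self.flat,
        }


def amplitude_ratio(
    reload_fit: ExponentialFit,
    unload_fit: ExponentialFit,
    labeled_fraction: Optional[float] = None,
) -> StoichiometryResult:
    """A_T,Reload / A_T,Unload on the magnitude convention.

    The unload total is the sum of resolved-phase magnitudes.  For the
    reload (FRET-increase) trace, when the fit carries a control-derived
    ``y0`` the total is taken as the net change ``c_inf - y0``: the rise
    passes through the fast clamp-assembly steps, so the exponential
    model's backward extrapolation to time zero is biased, while the
    physical zero-time level is pinned by the loader-free control — this
    is the same bookkeeping that recovers a censored early amplitude
    from ``c'`` and ``y0`` for loading traces.  Without a ``y0`` the
    sum-of-magnitudes convention is used for both.
    """
    a_unload = total_amplitude(unload_fit, include_dead=False)
    if reload_fit.y0 is not None:
        a_reload = abs(reload_fit.c_inf - reload_fit.y0)
    else:
        a_reload = total_amplitude(reload_fit, include_dead=False)
    if a_unload <= 0:
        raise ValueError("unload total amplitude must be > 0")
    return StoichiometryResult(
        a_t_unload=a_unload,
        a_t_reload=a_reload,
        ratio=a_reload / a_unload,
        labeled_fraction=labeled_fraction,
    )


def labeled_fraction_from_design(design) -> float:
    """Labeled fraction of the total clamp pool after the final mix."""
    syringes = [design.syringe_A, design.syringe_B, design.syringe_C or {}]
    lab = sum(s.get("pcna_labeled", 0.0) for s in syringes)
    unl = sum(s.get("pcna_unlabeled", 0.0) for s in syringes)
    if lab + unl <= 0:
        raise ValueError("design contains no clamp")
    return lab / (lab + unl)


def fraction_regression(
    fractions: Sequence[float], ratios: Sequence[float]
) -> tuple[float, float, float]:
    """Ordinary least-squares line of amplitude ratio on labeled fraction.

    Returns (slope, intercept, R^2).  Full clamp recycling predicts the
    identity line: slope 1, intercept 0.
    """
    x = np.asarray(fractions, dtype=float)
    y = np.asarray(ratios, dtype=float)
    if x.shape != y.shape or len(x) < 2:
        raise ValueError("need matched x/y with at least 2 points")
    if np.allclose(x, x[0]):
        raise ValueError("degenerate x-values: regression undefined")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)


def _segmented_rss(x: np.ndarray, y: np.ndarray, cb: float):
    """LSQ of y = a + b*min(x, cb) for a fixed junction cb."""
    M = np.column_stack([np.ones_like(x), np.minimum(x, cb)])
    coef, *_ = np.linalg.lstsq(M, y, rcond=None)
    rss = float(np.sum((y - M @ coef) ** 2))
    return rss, float(coef[1]), float(coef[0])


def titration_breakpoint(
    concentrations: Sequence[float], ratios: Sequence[float]
) -> BreakpointFit:
    """Junction of a continuous rising-line-plus-plateau fit.

    Candidate junctions are scanned at the data abscissae and refined by
    golden-section search between the bracketing neighbors.  A series
    that rises all the way to the last point has no detectable plateau
    and is reported as unbounded; an all-flat series is reported with
    the junction at the first point and the ``flat`` flag set.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(ratios, dtype=float)
    if x.shape != y.shape or len(x) < 4:
        raise ValueError("need at least 4 matched points spanning both regimes")
    order = np.argsort(x)
    x, y = x[order], y[order]

    span = float(np.max(np.abs(y)) or 1.0)
    # all-flat series: plateau from the start
    if np.ptp(y) <= 1e-9 * span:
        return BreakpointFit(breakpoint=float(x[0]), slope=0.0,
                             intercept=float(np.mean(y)), rss=0.0, flat=True)

    candidates = x[1:-1]
    scanned = [(*_segmented_rss(x, y, cb), cb) for cb in candidates]
    # include the unbounded model (junction at/after the last point = pure line)
    rss_line, slope_line, int_line = _segmented_rss(x, y, float(x[-1]))
    best_rss, best_slope, best_int, best_cb = min(
        scanned, key=lambda r: r[0], default=(np.inf, 0.0, 0.0, x[-1])
    )

    tol_line = 1e-10 * (span ** 2) * len(x)
    if rss_line <= best_rss + tol_line:
        # a straight line explains the data as well: no plateau detectable
        return BreakpointFit(breakpoint=None, slope=slope_line,
                             intercept=int_line, rss=rss_line, unbounded=True)

    i = int(np.searchsorted(x, best_cb))
    lo = float(x[max(i - 1, 0)])
    hi = float(x[min(i + 1, len(x) - 1)])
    phi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c1, c2 = b - phi * (b - a), a + phi * (b - a)
    f1, f2 = _segmented_rss(x, y, c1)[0], _segmented_rss(x, y, c2)[0]
    for _ in range(80):
        if f1 <= f2:
            b, c2, f2 = c2, c1, f1
            c1 = b - phi * (b - a)
            f1 = _segmented_rss(x, y, c1)[0]
        else:
            a, c1, f1 = c1, c2, f2
            c2 = a + phi * (b - a)
            f2 = _segmented_rss(x, y, c2)[0]
        if b - a < 1e-10 * max(1.0, hi):
            break
    cb = 0.5 * (a + b)
    rss, slope, intercept = _segmented_rss(x, y, cb)
    if rss > best_rss:
        cb, rss, slope, intercept = best_cb, best_rss, best_slope, best_int
    return BreakpointFit(breakpoint=float(cb), slope=slope,
                         intercept=intercept, rss=rss)
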