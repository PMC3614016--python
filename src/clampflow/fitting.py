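"""Multi-exponential trace models and derived amplitude quantities.

The observed trace model is

    y(t) = sum_i A_i * exp(-k_i * t) + c_inf

with signed amplitudes (a rising phase carries a negative A_i) and
``c_inf`` the value at infinite time.  For loading-type traces an initial
signal change occurs within the instrument dead time; its amplitude is
recovered from the fitted quantities as

    A_dead = c_inf - y0 - sum_i A_i

where ``y0`` is the zero-FRET value at time 0, taken from a loader-free
control trace.

Fitting uses variable projection: for trial rates the amplitudes and
offset are solved linearly, and only the log-rates are optimized, from a
deterministic multi-start grid spanning the data's time window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

LOG_K_MIN, LOG_K_MAX = np.log(1e-6), np.log(1e4)
COLLAPSE_REL_TOL = 0.05


class PhaseCollapseWarning(UserWarning):
    """Two fitted rates agree within 5%: the model is over-parameterized."""


class FitConvergenceError(RuntimeError):
    pass


@dataclass
class ExponentialFit:
    """A fitted sum-of-exponentials model, phases sorted fastest-first."""

    c_inf: float
    phases: list[tuple[float, float]]            # (amplitude, rate), k descending
    rss: float
    n_points: int
    y0: Optional[float] = None
    a_dead: Optional[float] = None
    stderr: dict = field(default_factory=dict)

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([a for a, _ in self.phases])

    @property
    def rates(self) -> np.ndarray:
        return np.array([k for _, k in self.phases])

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        y = np.full_like(t, self.c_inf)
        for a, k in self.phases:
            y = y + a * np.exp(-k * t)
        return y

    @property
    def n_parameters(self) -> int:
        return 2 * len(self.phases) + 1

    def to_dict(self) -> dict:
        return {
            "c_inf": self.c_inf,
            "y0": self.y0,
            "a_dead": self.a_dead,
            "phases": [{"amplitude": a, "rate": k} for a, k in self.phases],
            "rss": self.rss,
            "n_points": self.n_points,
            "stderr": self.stderr,
        }


def _as_arrays(trace) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(trace, tuple) and len(trace) == 2:
        t, y = trace
    else:
        t, y = trace.time, trace.signal
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.ndim != 1 or t.shape != y.shape:
        raise ValueError("trace must be matched 1-d time/signal arrays")
    if np.any(np.diff(t) <= 0):
        raise ValueError("trace time must be strictly increasing")
    return t, y


def _solve_linear(t: np.ndarray, y: np.ndarray, k: np.ndarray):
    """Amplitudes and offset for fixed rates (the linear half of VarPro)."""
    M = np.empty((len(t), len(k) + 1))
    M[:, :-1] = np.exp(-np.outer(t, k))
    M[:, -1] = 1.0
    coef, *_ = np.linalg.lstsq(M, y, rcond=None)
    resid = y - M @ coef
    return coef, resid


def _start_grids(t: np.ndarray, n: int) -> list[np.ndarray]:
    """Deterministic multi-start rate tuples.

    Candidate rates are log-spaced between ~1/(3 T) and ~2/dt over the
    data window; starts are all ascending n-subsets of the candidates,
    so well-separated and tight spacings are both explored.
    """
    from itertools import combinations

    t_lo = max(t[0], 1e-9)
    t_hi = t[-1]
    w_lo, w_hi = 1.0 / (3.0 * t_hi), 2.0 / t_lo
    w_lo = max(w_lo, 1e-6)
    w_hi = min(max(w_hi, 10 * w_lo), 1e4)
    if n == 1:
        return [np.array([k]) for k in np.geomspace(w_lo, w_hi, 8)]
    m = 8 if n == 2 else 7
    candidates = np.geomspace(w_lo, w_hi, m)
    return [np.array(c) for c in combinations(candidates, n)]


def fit_multiexponential(
    trace,
    n_phases: int,
    y0: Optional[float] = None,
) -> ExponentialFit:
    """Least-squares fit of ``n_phases`` exponentials plus an offset.

    ``trace`` is a ``(time, signal)`` pair or any object with ``.time`` /
    ``.signal``.  With ``y0`` supplied the dead-phase amplitude is stored
    on the returned fit.  A warning is raised when two fitted rates agree
    within 5% (phase collapse).
    """
    t, y = _as_arrays(trace)
    if not 0 <= n_phases <= 4:
        raise ValueError("n_phases must be between 0 and 4")
    if len(t) < max(2, 10 * n_phases):
        raise ValueError(f"need at least {10 * n_phases} samples for {n_phases} phases")

    if n_phases == 0:
        c = float(np.mean(y))
        rss = float(np.sum((y - c) ** 2))
        fit = ExponentialFit(c_inf=c, phases=[], rss=rss, n_points=len(t),
                             stderr={"c_inf": float(np.std(y) / np.sqrt(len(t)))})
        if y0 is not None:
            dead_time_amplitude(fit, y0)
        return fit

    def residual(log_k: np.ndarray) -> np.ndarray:
        _, resid = _solve_linear(t, y, np.exp(log_k))
        return resid

    # Amplitudes far beyond the observed signal range mark a collapsed
    # phase pair (two near-equal rates mimicking a t*exp(-k t) term with
    # huge cancelling coefficients); such optima are unidentifiable and
    # are only accepted if nothing better converges.
    amp_cap = 20.0 * (np.ptp(y) + 1e-12 * (1 + abs(float(np.mean(y)))))
    best = None
    fallback = None
    for k0 in _start_grids(t, n_phases):
        sol = least_squares(
            residual,
            np.log(k0),
            bounds=(LOG_K_MIN, LOG_K_MAX),
            method="trf",
            xtol=1e-12, ftol=1e-12, gtol=1e-12,
            max_nfev=200 * (n_phases + 1),
        )
        rss = float(np.sum(sol.fun ** 2))
        coef, _ = _solve_linear(t, y, np.exp(sol.x))
        degenerate = bool(np.max(np.abs(coef[:-1]), initial=0.0) > amp_cap)
        if degenerate:
            if fallback is None or rss < fallback[0]:
                fallback = (rss, sol.x)
        elif best is None or rss < best[0] - 1e-15 * (1 + best[0]):
            best = (rss, sol.x)
    if best is None:
        best = fallback
    if best is None:  # pragma: no cover
        raise FitConvergenceError("no start converged")

    k = np.exp(best[1])
    coef, resid = _solve_linear(t, y, k)
    order = np.argsort(-k)
    k = k[order]
    amps = coef[:-1][order]
    c_inf = float(coef[-1])
    rss = float(np.sum(resid ** 2))

    stderr = _standard_errors(t, y, amps, k, rss)
    fit = ExponentialFit(
        c_inf=c_inf,
        phases=[(float(a), float(ki)) for a, ki in zip(amps, k)],
        rss=rss,
        n_points=len(t),
        stderr=stderr,
    )
    for i in range(len(k)):
        for j in range(i + 1, len(k)):
            if abs(k[i] - k[j]) / max(k[i], k[j]) < COLLAPSE_REL_TOL:
                warnings.warn(
                    f"fitted rates {k[i]:.4g} and {k[j]:.4g} s^-1 agree within "
                    f"5%; consider n_phases={n_phases - 1}",
                    PhaseCollapseWarning,
                    stacklevel=2,
                )
    span = float(np.ptp(y))
    for a, ki in zip(amps, k):
        if abs(a) < 1e-6 * span:  # redundant phase: no resolvable amplitude
            warnings.warn(
                f"phase at {ki:.4g} s^-1 has negligible amplitude; "
                f"consider n_phases={n_phases - 1}",
                PhaseCollapseWarning,
                stacklevel=2,
            )
    if y0 is not None:
        dead_time_amplitude(fit, y0)
    return fit


def _standard_errors(t, y, amps, k, rss) -> dict:
    """Asymptotic standard errors from the full (rates+amplitudes+offset)
    Jacobian at the optimum."""
    n = len(k)
    N, p = len(t), 2 * n + 1
    if N <= p:
        return {}
    # residual = y - model; d resid/d k_i = A_i t e^{-k_i t}, d/dA_i = -e^{-k_i t}
    E = np.exp(-np.outer(t, k))
    J = np.empty((N, p))
    J[:, :n] = amps * t[:, None] * E
    J[:, n:2 * n] = -E
    J[:, -1] = -1.0
    try:
        cov = np.linalg.inv(J.T @ J) * rss / (N - p)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(J.T @ J) * rss / (N - p)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return {
        "k": se[:n].tolist(),
        "A": se[n:2 * n].tolist(),
        "c_inf": float(se[-1]),
    }


def dead_time_amplitude(fit: ExponentialFit, y0: float) -> float:
    """Amplitude of the signal change lost inside the instrument dead time.

    The dead phase is the difference between the fitted model
    extrapolated to time zero and the zero-signal level ``y0`` from a
    loader-free control: A_dead = c_inf + sum(A_i) - y0.  (In the
    reporting convention where phase amplitudes are quoted as positive
    magnitudes this is the usual c' - y0 - A_inc - A_dec bookkeeping;
    here amplitudes are stored with their Eq.-1 signs, rises negative.)
    Stored on the fit.
    """
    a_dead = fit.c_inf + float(np.sum(fit.amplitudes)) - y0
    fit.y0 = float(y0)
    fit.a_dead = float(a_dead)
    return fit.a_dead


def total_amplitude(fit: ExponentialFit, include_dead: bool = True) -> float:
    """Total amplitude A_T = sum of |A_i| over resolved phases, plus
    |A_dead| when requested and available."""
    total = float(np.sum(np.abs(fit.amplitudes))) if fit.phases else 0.0
    if include_dead and fit.a_dead is not None:
        total += abs(fit.a_dead)
    return total


def relative_amplitudes(fit: ExponentialFit) -> np.ndarray:
    """Percent of A_T per resolved phase (dead phase excluded); sums to 100."""
    if not fit.phases:
        raise ValueError("fit has no resolved phases")
    mags = np.abs(fit.amplitudes)
    return 100.0 * mags / mags.sum()


def half_life(k: float) -> float:
    """t_1/2 = ln 2 / k for a first-order process."""
    if k <= 0:
        raise ValueError("rate must be > 0")
    return float(np.log(2.0) / k)


def select_phase_count(trace, max_phases: int = 4):
    """Pick the smallest phase count the data supports.

    Candidate models with 0..max_phases phases are fitted; n is accepted
    when the (n+1)-phase model fails an extra-sum-of-squares F-test at
    alpha = 0.01 or triggers phase collapse.  Returns ``(n, report)``
    where report maps phase count to its fit and test p-value.
    """
    t, y = _as_arrays(trace)
    alpha = 0.01
    report: dict[int, dict] = {}
    fits: dict[int, ExponentialFit] = {}
    collapse: dict[int, bool] = {}
    for n in range(0, max_phases + 1):
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", PhaseCollapseWarning)
            fits[n] = fit_multiexponential((t, y), n)
        collapse[n] = any(isinstance(w.message, PhaseCollapseWarning) for w in caught)
        report[n] = {"fit": fits[n], "phase_collapse": collapse[n], "p_value": None}

    chosen = max_phases
    y_scale = float(np.var(y)) * len(y)
    for n in range(0, max_phases):
        rss_n, rss_n1 = fits[n].rss, fits[n + 1].rss
        if rss_n <= max(1e-28, 1e-18 * max(y_scale, 1e-30)):
            chosen = n  # the n-phase model is already essentially exact
            break
        dof = len(y) - fits[n + 1].n_parameters
        if rss_n1 <= 0 or dof <= 0:
            continue
        F = ((rss_n - rss_n1) / 2.0) / (rss_n1 / dof)
        p_value = float(stats.f.sf(max(F, 0.0), 2, dof))
        report[n + 1]["p_value"] = p_value
        if p_value > alpha or collapse[n + 1]:
            chosen = n
            break
    return chosen, report
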