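"""Deterministic integration of the reaction network and the FRET observable."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .network import ReactionNetwork

RTOL = 1e-8
ATOL = 1e-10


class IntegrationError(RuntimeError):
    pass


@dataclass
class Trajectory:
    """Species concentrations (nM) on a time grid (s, 0 = mixing)."""

    time: np.ndarray
    concentrations: np.ndarray  # shape (n_times, n_species)

    def species_series(self, network: ReactionNetwork, name: str) -> np.ndarray:
        return self.concentrations[:, network.index(name)]

    def to_frame(self, network: ReactionNetwork):
        """Trajectory as a DataFrame: time_s then one column per species."""
        import pandas as pd

        data = {"time_s": self.time}
        for i, s in enumerate(network.species):
            data[s.name] = self.concentrations[:, i]
        return pd.DataFrame(data)

    def to_csv(self, path, network: ReactionNetwork) -> None:
        self.to_frame(network).to_csv(path, index=False)

    def conservation_drift(self, network: ReactionNetwork) -> dict[str, float]:
        """Max relative drift of each conserved total over the grid."""
        drift = {}
        for name, idx in network.conservation.items():
            totals = self.concentrations[:, list(idx)].sum(axis=1)
            ref = totals[0]
            if ref <= 0:
                drift[name] = float(np.max(np.abs(totals)))
            else:
                drift[name] = float(np.max(np.abs(totals - ref)) / ref)
        return drift


def integrate(
    network: ReactionNetwork,
    initial_concentrations: np.ndarray | dict[str, float],
    time_grid: np.ndarray,
) -> Trajectory:
    """Integrate the mass-action ODEs onto ``time_grid``.

    The grid must be strictly increasing and start at 0 (= completion of
    the final mix).  LSODA handles the stiffness introduced by the fast
    effective DNA-binding step.
    """
    if isinstance(initial_concentrations, dict):
        y0 = network.initial_state(initial_concentrations)
    else:
        y0 = np.asarray(initial_concentrations, dtype=float)
        if y0.shape != (network.n_species,):
            raise ValueError("initial concentration vector has wrong length")
    if np.any(y0 < 0):
        raise ValueError("initial concentrations must be >= 0")
    t = np.asarray(time_grid, dtype=float)
    if t.ndim != 1 or len(t) < 2 or t[0] != 0.0 or np.any(np.diff(t) <= 0):
        raise ValueError("time grid must be strictly increasing from 0")

    sol = solve_ivp(
        network.rhs,
        (t[0], t[-1]),
        y0,
        method="LSODA",
        t_eval=t,
        rtol=RTOL,
        atol=ATOL,
    )
    if not sol.success:
        raise IntegrationError(
            f"integrator failed near t = {sol.t[-1] if len(sol.t) else t[0]:.6g} s: "
            f"{sol.message}"
        )
    return Trajectory(time=t, concentrations=sol.y.T.copy())


def steady_state(
    network: ReactionNetwork,
    initial_concentrations: np.ndarray | dict[str, float],
    rel_rate_tol: float = 1e-9,
    max_time: float = 5000.0,
) -> np.ndarray:
    """Relax a composition to steady state (pre-equilibration of a pre-mix).

    Integrates in growing windows until the relative concentration change
    rate max|dc/dt| / max(c) falls below ``rel_rate_tol`` per second.
    """
    if isinstance(initial_concentrations, dict):
        y = network.initial_state(initial_concentrations)
    else:
        y = np.asarray(initial_concentrations, dtype=float).copy()
    scale = max(float(np.max(y)), 1.0)
    elapsed, window = 0.0, 50.0
    while elapsed < max_time:
        grid = np.linspace(0.0, window, 51)
        y = integrate(network, np.clip(y, 0.0, None), grid).concentrations[-1]
        elapsed += window
        window = min(window * 2, 1000.0)
        if np.max(np.abs(network.rhs(0.0, y))) / scale < rel_rate_tol:
            return np.clip(y, 0.0, None)
    raise IntegrationError(
        f"pre-equilibration did not reach steady state within {max_time:.0f} s"
    )


def fret_signal(
    trajectory: Trajectory,
    network: ReactionNetwork,
    scale: float = 0.01,
    baseline: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Scalar FRET observable: baseline + scale * sum_s w_s * c_s(t).

    Only species containing a labeled clamp on DNA have nonzero weight,
    so an unlabeled or clamp-free run yields a flat trace at baseline.
    """
    if trajectory.concentrations.shape[1] != network.n_species:
        raise ValueError("trajectory and network are not species-aligned")
    signal = baseline + scale * trajectory.concentrations @ network.fret_coefficients
    return trajectory.time, signal


def closed_form_sequential(k1: float, k2: float, t) -> tuple:
    """Occupancies of A, B, C in the irreversible chain A -> B -> C.

    Textbook sequential kinetics with unit start in A:
    A = exp(-k1 t); B = k1/(k2-k1) (exp(-k1 t) - exp(-k2 t)); C = 1-A-B.
    Used as the analytic oracle for the numerical integrator.
    """
    if k1 <= 0 or k2 <= 0:
        raise ValueError("rates must be positive")
    if k1 == k2:
        raise ValueError("degenerate case k1 == k2 not supported")
    t = np.asarray(t, dtype=float)
    a = np.exp(-k1 * t)
    b = k1 / (k2 - k1) * (np.exp(-k1 * t) - np.exp(-k2 * t))
    c = 1.0 - a - b
    return a, b, c
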