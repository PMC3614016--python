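"""Declarative stopped-flow experiment designs and synthetic trace generation.

A design describes what sits in each syringe (pre-mix concentrations, nM),
how the streams are mixed (1:1 mixing halves all concentrations), the
instrument dead time, and the sampling schedule.  ``run_design`` turns a
design plus a mechanism parameter set into a noise-free FRET trace;
``add_noise`` applies seeded Gaussian measurement noise.

Conventions emulating the instrument:

* time 0 is the completion of the final mix;
* samples earlier than the dead time are censored (the corresponding
  signal change surfaces as the dead-phase amplitude in fits);
* loading-type schedules collect 5000 points over the initial 10 s and
  3000 points over the remainder; unloading-type schedules collect 1000
  points per 60 s;
* pre-assembled complexes (e.g. clamp loaded onto DNA before an
  unload-trap mix) are equilibrated by integrating the pre-mix to steady
  state;
* a pulse-chase design runs the pulse stage for ``pulse_duration``
  (37 ms) before the chase mix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .network import ReactionNetwork, build_network
from .params import RateParameters
from .simulate import Trajectory, fret_signal, integrate, steady_state

DESIGN_SPECIES = ("rfc", "pcna_labeled", "pcna_unlabeled", "dna", "poldelta")

#: Designs whose observation window is sampled on the dense loading schedule.
_LOADING_SCHEDULE_KINDS = frozenset({"loading", "pulse_chase", "chase_control"})

DEFAULT_SCALE = 0.01      # a.u. per nM of weighted labeled complex
DEFAULT_BASELINE = 0.1    # a.u., the zero-FRET level
DEFAULT_DEAD_TIME = 0.002  # s


class SamplingSchedule(BaseModel):
    """Piecewise-uniform sampling: list of (duration s, point count)."""

    model_config = ConfigDict(extra="forbid")
    segments: list[tuple[float, int]]

    @model_validator(mode="after")
    def _check(self) -> "SamplingSchedule":
        if not self.segments:
            raise ValueError("schedule needs at least one segment")
        for dur, n in self.segments:
            if dur <= 0 or n <= 0:
                raise ValueError("segment durations and point counts must be > 0")
        return self

    @property
    def n_points(self) -> int:
        return sum(n for _, n in self.segments)

    @property
    def total_duration(self) -> float:
        return sum(d for d, _ in self.segments)

    def grid(self) -> np.ndarray:
        """Sample times, excluding t = 0 (each segment samples its right edges)."""
        times, offset = [], 0.0
        for dur, n in self.segments:
            times.append(offset + dur * np.arange(1, n + 1) / n)
            offset += dur
        return np.concatenate(times)


def sampling_schedule(kind: str, total_duration: float) -> SamplingSchedule:
    """The instrument's acquisition schedules.

    ``loading``: 5000 points over the first 10 s, 3000 over the rest
    (8000 points per 60 s trace).  ``unloading``: 1000 points per 60 s.
    """
    if total_duration <= 0:
        raise ValueError("total_duration must be > 0")
    if kind == "loading":
        if total_duration <= 10.0:
            return SamplingSchedule(segments=[(total_duration, 5000)])
        return SamplingSchedule(
            segments=[(10.0, 5000), (total_duration - 10.0, 3000)]
        )
    if kind == "unloading":
        n = max(1, round(1000 * total_duration / 60.0))
        return SamplingSchedule(segments=[(total_duration, n)])
    raise ValueError(f"unknown schedule kind {kind!r}")


class ExperimentDesign(BaseModel):
    """One stopped-flow experiment, in pre-mix (syringe) concentrations."""

    model_config = ConfigDict(extra="forbid")

    kind: str
    syringe_A: dict[str, float]
    syringe_B: dict[str, float] = Field(default_factory=dict)
    syringe_C: Optional[dict[str, float]] = None
    pulse_duration: float = 0.037
    dead_time: float = DEFAULT_DEAD_TIME
    schedule_id: str = "auto"
    end_blocked: bool = True
    total_duration: float = 60.0

    @model_validator(mode="after")
    def _check(self) -> "ExperimentDesign":
        from .network import DESIGN_KINDS

        if self.kind not in DESIGN_KINDS | {"chase_control"}:
            raise ValueError(f"unknown design kind {self.kind!r}")
        for syr in (self.syringe_A, self.syringe_B, self.syringe_C or {}):
            for name, conc in syr.items():
                if name not in DESIGN_SPECIES:
                    raise ValueError(f"unknown species {name!r} in syringe")
                if conc < 0:
                    raise ValueError(f"negative concentration for {name!r}")
        if self.kind in ("pulse_chase", "chase_control") and self.pulse_duration <= 0:
            raise ValueError("pulse_duration must be > 0 for pulse-chase designs")
        if self.dead_time < 0:
            raise ValueError("dead_time must be >= 0")
        if self.total_duration <= self.dead_time:
            raise ValueError("total_duration must exceed dead_time")
        poldelta_allowed = self.kind in ("reload_poldelta", "titration_member")
        has_poldelta = any(
            syr.get("poldelta", 0.0) > 0
            for syr in (self.syringe_A, self.syringe_B, self.syringe_C or {})
        )
        if has_poldelta and not poldelta_allowed:
            raise ValueError(f"poldelta is not allowed in a {self.kind!r} design")
        return self

    def schedule(self) -> SamplingSchedule:
        if self.kind in _LOADING_SCHEDULE_KINDS:
            return sampling_schedule("loading", self.total_duration)
        return sampling_schedule("unloading", self.total_duration)


@dataclass
class CleanTrace:
    """Noise-free trace plus the trajectory/network that produced it."""

    time: np.ndarray
    signal: np.ndarray
    trajectory: Trajectory
    network: ReactionNetwork
    design: ExperimentDesign
    scale: float
    baseline: float

    @property
    def full_scale(self) -> float:
        return float(np.max(self.signal) - np.min(self.signal))


@dataclass
class NoisyTrace:
    time: np.ndarray
    signal: np.ndarray
    metadata: dict = field(default_factory=dict)


def _solution_state(network: ReactionNetwork, conc: dict[str, float],
                    p_fast: float) -> np.ndarray:
    named: dict[str, float] = {}
    for species, value in conc.items():
        if value == 0:
            continue
        if species == "rfc":
            named["rfc_fast_sol"] = named.get("rfc_fast_sol", 0.0) + value * p_fast
            named["rfc_slow_sol"] = named.get("rfc_slow_sol", 0.0) + value * (1 - p_fast)
        elif species == "pcna_labeled":
            named["pcna_lab_sol"] = named.get("pcna_lab_sol", 0.0) + value
        elif species == "pcna_unlabeled":
            named["pcna_unl_sol"] = named.get("pcna_unl_sol", 0.0) + value
        elif species == "dna":
            named["dna"] = named.get("dna", 0.0) + value
        elif species == "poldelta":
            named["poldelta_sol"] = named.get("poldelta_sol", 0.0) + value
    return network.initial_state(named)


def _network_kind(kind: str) -> str:
    # chase_control shares the pulse-chase network (no polymerase branch)
    return "pulse_chase" if kind == "chase_control" else kind


def run_design(
    design: ExperimentDesign,
    params: RateParameters,
    scale: float = DEFAULT_SCALE,
    baseline: float = DEFAULT_BASELINE,
) -> CleanTrace:
    """Execute a design: mix, (pre-equilibrate,) integrate, observe, censor."""
    network = build_network(params, _network_kind(design.kind), design.end_blocked)
    p = params.p_fast
    A = lambda: _solution_state(network, design.syringe_A, p)
    B = lambda: _solution_state(network, design.syringe_B, p)

    if design.kind in ("loading", "unload_trap", "reload", "reload_poldelta",
                       "titration_member"):
        if design.kind == "loading":
            y_pre = A()  # loader and clamp only: solution complex, no dynamics
        else:
            # pre-assembled complex on DNA; leak channels act only during
            # the observed reaction, not the idealized pre-assembly
            y_pre = steady_state(network.without_leaks(), A())
        y0 = 0.5 * y_pre + 0.5 * B()
    elif design.kind in ("pulse_chase", "chase_control"):
        if design.syringe_C is None:
            raise ValueError(f"{design.kind} requires syringe_C (chase stream)")
        y_stage1 = 0.5 * A() + 0.5 * B()
        n_pulse = max(20, int(design.pulse_duration / 1e-3))
        pulse_grid = np.linspace(0.0, design.pulse_duration, n_pulse + 1)
        y_end = integrate(network, y_stage1, pulse_grid).concentrations[-1]
        chase = _solution_state(network, design.syringe_C, p)
        y0 = 0.5 * np.clip(y_end, 0.0, None) + 0.5 * chase
    else:  # pragma: no cover - kinds are validated upstream
        raise ValueError(f"unhandled design kind {design.kind!r}")

    grid = design.schedule().grid()
    grid = grid[grid <= design.total_duration + 1e-12]
    full_grid = np.concatenate([[0.0], grid])
    traj = integrate(network, y0, full_grid)
    t, signal = fret_signal(traj, network, scale=scale, baseline=baseline)
    keep = t >= design.dead_time
    # drop the t = 0 anchor and anything inside the dead time
    keep[0] = False
    return CleanTrace(
        time=t[keep],
        signal=signal[keep],
        trajectory=traj,
        network=network,
        design=design,
        scale=scale,
        baseline=baseline,
    )


def add_noise(trace: CleanTrace | NoisyTrace, sigma: float, seed: int) -> NoisyTrace:
    """Seeded additive zero-mean Gaussian noise on the signal."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    signal = trace.signal + (rng.normal(0.0, sigma, size=len(trace.signal))
                             if sigma > 0 else 0.0)
    meta = {
        "seed": seed,
        "noise_sigma": sigma,
    }
    if isinstance(trace, CleanTrace):
        meta.update(
            design=trace.design.model_dump(),
            scale=trace.scale,
            baseline=trace.baseline,
        )
    return NoisyTrace(time=trace.time.copy(), signal=np.asarray(signal), metadata=meta)


def default_sigma(trace: CleanTrace) -> float:
    """Default noise level: 1% of the clean trace's full-scale amplitude."""
    return 0.01 * trace.full_scale


def simulate_noisy(
    design: ExperimentDesign,
    params: RateParameters,
    seed: int,
    sigma: float | None = None,
    scale: float = DEFAULT_SCALE,
    baseline: float = DEFAULT_BASELINE,
) -> tuple[CleanTrace, NoisyTrace]:
    clean = run_design(design, params, scale=scale, baseline=baseline)
    if sigma is None:
        sigma = default_sigma(clean)
    return clean, add_noise(clean, sigma, seed)


def generate_titration_series(
    base_design: ExperimentDesign,
    varied_species: str,
    values: list[float],
    params: RateParameters,
    sigma: float | None = None,
    seed: int = 0,
) -> list[NoisyTrace]:
    """One noisy trace per titrant value; member seeds are ``seed + index``."""
    if varied_species not in DESIGN_SPECIES:
        raise ValueError(f"unknown species label {varied_species!r}")
    if any(v < 0 for v in values):
        raise ValueError("titration values must be >= 0")
    syringe_names = ["syringe_A", "syringe_B", "syringe_C"]
    target = None
    for name in syringe_names:
        syr = getattr(base_design, name)
        if syr and varied_species in syr:
            target = name
            break
    if target is None:
        target = "syringe_B"
    traces = []
    for i, value in enumerate(values):
        d = base_design.model_dump()
        syr = dict(d[target] or {})
        syr[varied_species] = value
        d[target] = syr
        member = ExperimentDesign(**d)
        _, noisy = simulate_noisy(member, params, seed=seed + i, sigma=sigma)
        noisy.metadata["titration"] = {"species": varied_species, "value": value,
                                       "index": i}
        traces.append(noisy)
    return traces


# ---------------------------------------------------------------------------
# The standard experiment designs, in pre-mix (syringe) concentrations.
# ---------------------------------------------------------------------------

def loading_design(rfc: float = 200.0, pcna_labeled: float = 200.0,
                   dna: float = 200.0, total_duration: float = 60.0,
                   dead_time: float = DEFAULT_DEAD_TIME) -> ExperimentDesign:
    """Loader·clamp complex in one syringe mixed against DNA."""
    return ExperimentDesign(
        kind="loading",
        syringe_A={"rfc": rfc, "pcna_labeled": pcna_labeled},
        syringe_B={"dna": dna},
        total_duration=total_duration,
        dead_time=dead_time,
    )


def pulse_chase_design(rfc: float = 100.0, pcna_labeled: float = 100.0,
                       dna: float = 100.0, chase: float = 2000.0,
                       pulse_duration: float = 0.037,
                       total_duration: float = 60.0) -> ExperimentDesign:
    """37 ms loading pulse, then an excess unlabeled-clamp chase."""
    return ExperimentDesign(
        kind="pulse_chase",
        syringe_A={"rfc": rfc, "pcna_labeled": pcna_labeled},
        syringe_B={"dna": dna},
        syringe_C={"pcna_unlabeled": chase},
        pulse_duration=pulse_duration,
        total_duration=total_duration,
    )


def chase_control_design(rfc: float = 100.0, pcna_labeled: float = 100.0,
                         dna: float = 100.0, chase: float = 2000.0,
                         total_duration: float = 60.0) -> ExperimentDesign:
    """Trap premixed with the loader before the labeled clamp: zero-FRET control."""
    return ExperimentDesign(
        kind="chase_control",
        syringe_A={"rfc": rfc, "pcna_unlabeled": chase},
        syringe_B={"dna": dna},
        syringe_C={"pcna_labeled": pcna_labeled},
        pulse_duration=0.037,
        total_duration=total_duration,
    )


def unload_trap_design(rfc: float = 100.0, pcna_labeled: float = 100.0,
                       dna: float = 200.0, trap: float = 2000.0,
                       total_duration: float = 60.0,
                       end_blocked: bool = True) -> ExperimentDesign:
    """Pre-equilibrated labeled complex mixed against excess unlabeled trap."""
    return ExperimentDesign(
        kind="unload_trap",
        syringe_A={"rfc": rfc, "pcna_labeled": pcna_labeled, "dna": dna},
        syringe_B={"pcna_unlabeled": trap} if trap > 0 else {},
        total_duration=total_duration,
        end_blocked=end_blocked,
    )


def reload_design(rfc: float = 100.0, pcna_unlabeled: float = 100.0,
                  dna: float = 200.0, pcna_labeled: float = 100.0,
                  poldelta: float = 0.0,
                  total_duration: float = 60.0) -> ExperimentDesign:
    """Pre-equilibrated unlabeled complex mixed against labeled clamp
    (optionally plus polymerase)."""
    syringe_B: dict[str, float] = {"pcna_labeled": pcna_labeled}
    kind = "reload"
    if poldelta > 0:
        syringe_B["poldelta"] = poldelta
        kind = "reload_poldelta"
    return ExperimentDesign(
        kind=kind,
        syringe_A={"rfc": rfc, "pcna_unlabeled": pcna_unlabeled, "dna": dna},
        syringe_B=syringe_B,
        total_duration=total_duration,
    )
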