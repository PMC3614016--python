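"""Trace CSV round-trip and run configuration.

Traces are two-column CSV files with header ``time_s,signal_au``, '.'
decimal separator, UTF-8; time is printed with 6 significant digits and
signal with 8.  Configurations are JSON and fail fast on unknown keys.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .designs import ExperimentDesign
from .params import RateParameters

TRACE_COLUMNS = ("time_s", "signal_au")


class TraceError(ValueError):
    pass


class MalformedTraceError(TraceError):
    pass


class EmptyTraceError(TraceError):
    pass


class NonMonotonicTimeError(TraceError):
    def __init__(self, row: int):
        self.row = row
        super().__init__(f"time is not strictly increasing at data row {row}")


def read_trace(path: Union[str, Path]) -> tuple[np.ndarray, np.ndarray]:
    """Read a time/signal trace CSV, validating header and monotonicity."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise EmptyTraceError(f"{path}: file is empty") from None
    except (pd.errors.ParserError, ValueError) as exc:
        raise MalformedTraceError(f"{path}: {exc}") from None
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise MalformedTraceError(f"{path}: missing column(s) {missing}")
    if len(df) == 0:
        raise EmptyTraceError(f"{path}: header only, no samples")
    t = pd.to_numeric(df["time_s"], errors="coerce").to_numpy(dtype=float)
    y = pd.to_numeric(df["signal_au"], errors="coerce").to_numpy(dtype=float)
    bad = np.flatnonzero(np.isnan(t) | np.isnan(y))
    if len(bad):
        raise MalformedTraceError(f"{path}: non-numeric value at data row {bad[0]}")
    steps = np.diff(t)
    non_mono = np.flatnonzero(steps <= 0)
    if len(non_mono):
        raise NonMonotonicTimeError(int(non_mono[0]) + 1)
    return t, y


def write_trace(path: Union[str, Path], time: np.ndarray, signal: np.ndarray) -> None:
    time = np.asarray(time, dtype=float)
    signal = np.asarray(signal, dtype=float)
    if time.shape != signal.shape:
        raise ValueError("time and signal must have the same length")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("time_s,signal_au\n")
        for t, y in zip(time, signal):
            fh.write(f"{t:.6g},{y:.8g}\n")


class RunConfig(BaseModel):
    """Fully resolved configuration of one simulation run."""

    model_config = ConfigDict(extra="forbid")

    params: RateParameters = Field(default_factory=RateParameters)
    design: ExperimentDesign
    sigma: Optional[float] = None       # None: 1% of clean full scale
    seed: int = 0
    scale: float = 0.01
    baseline: float = 0.1
    include_dead: bool = True

    def digest(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path: Union[str, Path]) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        return RunConfig.model_validate_json(fh.read())


def save_config(config: RunConfig, path: Union[str, Path]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(config.model_dump_json(indent=2))
        fh.write("\n")
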