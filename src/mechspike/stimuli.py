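"""Force/current stimulus waveforms and trace file I/O.

A :class:`Trace` is a uniformly sampled time series. Time is never stored
per sample: the time of sample ``k`` is defined to be ``t0 + k * dt``,
which keeps the grid exact over 10^5+ samples at dt = 0.01 ms.

Generators cover the stimulus classes used to characterize tactile
afferents: staircase presses (sustained indentation at growing force),
and sinusoidal / triangular / pulsatile drives.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, TraceFormatError

#: Unit labels a Trace may carry. Derivative units arise from finite_diff.
VALID_UNITS = ("N", "mA", "mV", "", "N/ms", "mA/ms")

#: Force range of the FSR sensor the encoder is designed around, in newtons.
FSR_FORCE_RANGE = (0.2, 20.0)

_UNIT_COLUMN = {"N": "force_N", "mA": "current_mA", "mV": "v_mV"}
_COLUMN_UNIT = {v: k for k, v in _UNIT_COLUMN.items()}


class ForceRangeWarning(UserWarning):
    """Force amplitude outside the FSR's sensitive range (0.2-20 N)."""


@dataclass(frozen=True)
class Trace:
    """Uniformly sampled time series.

    Parameters
    ----------
    values : array-like
        Ordered samples (force in N, current in mA, or potential in mV).
    dt : float
        Sample period in ms, strictly positive.
    t0 : float
        Time of the first sample, ms.
    unit : str
        One of ``VALID_UNITS``.
    """

    values: np.ndarray
    dt: float
    t0: float = 0.0
    unit: str = "mA"

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size < 1:
            raise InvalidArgumentError("a Trace needs a 1-D array of >= 1 samples")
        if not (self.dt > 0):
            raise InvalidArgumentError(f"dt must be > 0, got {self.dt}")
        if self.unit not in VALID_UNITS:
            raise InvalidArgumentError(
                f"unit must be one of {VALID_UNITS}, got {self.unit!r}"
            )
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        """Sample times t0 + k*dt, ms."""
        return self.t0 + self.dt * np.arange(self.values.size)

    @property
    def t_end(self) -> float:
        """End of the observation window (one dt past the last sample), ms."""
        return self.t0 + self.dt * self.values.size

    @property
    def duration(self) -> float:
        return self.dt * self.values.size

    def with_values(self, values: np.ndarray, unit: str | None = None) -> "Trace":
        return replace(self, values=values, unit=self.unit if unit is None else unit)


def _samples_for(duration: float, dt: float) -> int:
    # round half away from zero; durations are positive here
    return int(math.floor(duration / dt + 0.5))


def _warn_force_range(values: np.ndarray) -> None:
    lo, hi = FSR_FORCE_RANGE
    nz = values[values != 0]
    if nz.size and (nz.min() < lo or nz.max() > hi):
        warnings.warn(
            f"force amplitudes outside the FSR sensitive range {lo}-{hi} N; "
            "the model is still defined but a physical sensor would not resolve them",
            ForceRangeWarning,
            stacklevel=3,
        )


def make_staircase(
    levels: Iterable[tuple[float, float]], dt: float, *, t0: float = 0.0, unit: str = "N"
) -> Trace:
    """Piecewise-constant staircase stimulus.

    ``levels`` is an ordered sequence of (amplitude, duration ms) pairs; each
    level occupies round(duration/dt) samples (half rounds away from zero).
    """
    if not (dt > 0):
        raise InvalidArgumentError(f"dt must be > 0, got {dt}")
    levels = list(levels)
    if not levels:
        raise InvalidArgumentError("staircase needs at least one level")
    chunks = []
    for amp, dur in levels:
        if not (dur > 0):
            raise InvalidArgumentError(f"level duration must be > 0, got {dur}")
        chunks.append(np.full(_samples_for(dur, dt), float(amp)))
    values = np.concatenate(chunks)
    if unit == "N":
        _warn_force_range(values)
    return Trace(values=values, dt=dt, t0=t0, unit=unit)


def make_constant(amplitude: float, duration: float, dt: float, *, unit: str = "mA") -> Trace:
    """Constant stimulus of the given amplitude — one-level staircase."""
    return make_staircase([(amplitude, duration)], dt, unit=unit)


def make_periodic(
    shape: str,
    amplitude: float,
    period: float,
    duration: float,
    dt: float,
    *,
    offset: float = 0.0,
    duty: float | None = None,
    t0: float = 0.0,
    unit: str = "mA",
) -> Trace:
    """Sinusoidal, triangular, or pulsatile stimulus.

    Sample k of the sine is ``offset + amplitude*sin(2*pi*k*dt/period)``; the
    triangle is the standard unit triangle wave scaled the same way (zero at
    k = 0, peak at the quarter period); the pulse is ``offset + amplitude``
    for the first ``duty`` fraction of each period and ``offset`` otherwise.
    Peak-to-peak is 2*amplitude for sine/triangle and amplitude for the pulse.
    """
    for name, val in (("period", period), ("duration", duration), ("dt", dt)):
        if not (val > 0):
            raise InvalidArgumentError(f"{name} must be > 0, got {val}")
    n = _samples_for(duration, dt)
    k = np.arange(n)
    ratio = period / dt
    if abs(ratio - round(ratio)) <= 1e-9 * ratio:
        # integer samples per period: exact periodicity by modular arithmetic
        phase = (k % round(ratio)) / round(ratio)
    else:
        phase = (k * dt / period) % 1.0
    if shape == "sine":
        values = offset + amplitude * np.sin(2 * np.pi * phase)
    elif shape == "triangle":
        # unit triangle: 0 -> 1 -> 0 -> -1 over one period
        tri = np.where(
            phase < 0.25, 4 * phase, np.where(phase < 0.75, 2 - 4 * phase, 4 * phase - 4)
        )
        values = offset + amplitude * tri
    elif shape == "pulse":
        if duty is None or not (0 < duty < 1):
            raise InvalidArgumentError(
                f"pulse shape needs a duty fraction in (0, 1), got {duty}"
            )
        values = offset + amplitude * (phase < duty)
    else:
        raise InvalidArgumentError(
            f"shape must be one of 'sine', 'triangle', 'pulse', got {shape!r}"
        )
    if unit == "N":
        _warn_force_range(values)
    return Trace(values=values, dt=dt, t0=t0, unit=unit)


def write_trace(trace: Trace, path) -> None:
    """Write a two-column CSV: time in ms, value; one header line."""
    col = _UNIT_COLUMN.get(trace.unit, "value")
    df = pd.DataFrame({"t_ms": trace.times, col: trace.values})
    df.to_csv(path, index=False)


def read_trace(path, *, unit: str | None = None, rel_tol: float = 1e-6) -> Trace:
    """Read a two-column CSV (time ms, value) into a Trace.

    The header line is optional. The time grid must be uniform within a
    relative tolerance of ``rel_tol`` of the first spacing; the first
    offending data row (1-based, counting the header) is named otherwise.
    """
    text = Path(path).read_text()
    if not text.strip():
        raise TraceFormatError(f"{path}: empty trace file")
    first_line = text.strip().splitlines()[0]
    has_header = False
    try:
        [float(tok) for tok in first_line.split(",")]
    except ValueError:
        has_header = True
    df = pd.read_csv(io.StringIO(text), header=0 if has_header else None)
    if df.shape[1] != 2:
        raise TraceFormatError(f"{path}: expected 2 columns, found {df.shape[1]}")
    if df.shape[0] < 1:
        raise TraceFormatError(f"{path}: no data rows")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    values = df.iloc[:, 1].to_numpy(dtype=float)
    if unit is None:
        unit = _COLUMN_UNIT.get(str(df.columns[1]), "mA") if has_header else "mA"
    if t.size == 1:
        raise TraceFormatError(f"{path}: cannot infer dt from a single row")
    dt = t[1] - t[0]
    if not (dt > 0):
        raise TraceFormatError(f"{path}: non-increasing time at data row 2")
    expected = t[0] + dt * np.arange(t.size)
    bad = np.nonzero(np.abs(t - expected) > rel_tol * abs(dt))[0]
    if bad.size:
        row = int(bad[0]) + 1 + (1 if has_header else 0)
        raise TraceFormatError(
            f"{path}: non-uniform time grid at row {row}: "
            f"t={t[bad[0]]!r}, expected {expected[bad[0]]!r} (dt={dt!r})"
        )
    return Trace(values=values, dt=float(dt), t0=float(t[0]), unit=unit)


def write_spike_times(times: Sequence[float], path) -> None:
    """One-column spike-time CSV (ms)."""
    pd.DataFrame({"spike_t_ms": np.asarray(times, dtype=float)}).to_csv(path, index=False)


def read_spike_times(path) -> np.ndarray:
    df = pd.read_csv(path)
    return df.iloc[:, 0].to_numpy(dtype=float)
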