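"""Spike/burst statistics and trajectory comparison.

Everything used to validate one back-end against another lives here:
interspike-interval (ISI) and interburst-interval (IBI) means/variances,
the truncated relative-error figure of merit, index-paired spike-timing
offsets, and the delay-embedding phase plane v(t + tau) vs v(t).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, UndefinedStatisticError
from .stimuli import Trace

#: Default maximum within-burst ISI, ms. Bursts are defined only by their
#: appearance in the published traces; 20 ms cleanly separates the few-ms
#: intra-burst intervals from the tens-of-ms pauses between bursts.
DEFAULT_MAX_INTRA_ISI = 20.0


@dataclass(frozen=True)
class SpikeTrain:
    """Strictly increasing spike times (ms) within a window [0, t_end)."""

    times: np.ndarray
    t_end: float

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        if t.size and not np.all(np.diff(t) > 0):
            raise InvalidArgumentError("spike times must be strictly increasing")
        if t.size and (t[0] < 0 or t[-1] >= self.t_end):
            raise InvalidArgumentError("spike times must lie in [0, t_end)")
        object.__setattr__(self, "times", t)

    def __len__(self) -> int:
        return self.times.size

    def after(self, t: float) -> "SpikeTrain":
        """Sub-train of spikes at or after time t (same window end)."""
        return SpikeTrain(times=self.times[self.times >= t], t_end=self.t_end)


@dataclass(frozen=True)
class IntervalStats:
    mean: float  # ms
    variance: float  # ms^2, unbiased (n-1) estimator
    n: int  # interval count


def _interval_stats(intervals: np.ndarray, kind: str) -> IntervalStats:
    if intervals.size < 1:
        raise UndefinedStatisticError(f"{kind} stats need at least 2 events")
    if intervals.size < 2:
        raise UndefinedStatisticError(
            f"{kind} variance needs at least 3 events (2 intervals)"
        )
    return IntervalStats(
        mean=float(np.mean(intervals)),
        variance=float(np.var(intervals, ddof=1)),
        n=int(intervals.size),
    )


def isi(train: SpikeTrain) -> np.ndarray:
    """Consecutive spike-time differences, ms."""
    if len(train) < 2:
        raise UndefinedStatisticError("ISIs need at least 2 spikes")
    return np.diff(train.times)


def isi_stats(train: SpikeTrain) -> IntervalStats:
    """Sample mean and unbiased variance of the ISIs (needs >= 3 spikes)."""
    return _interval_stats(np.diff(train.times), "ISI")


def detect_bursts(
    train: SpikeTrain, max_intra_isi: float = DEFAULT_MAX_INTRA_ISI
) -> list[np.ndarray]:
    """Group spikes separated by <= max_intra_isi into bursts.

    Isolated spikes count as one-spike bursts; an empty train gives no
    bursts.
    """
    if not (max_intra_isi > 0):
        raise InvalidArgumentError(f"max_intra_isi must be > 0, got {max_intra_isi}")
    t = train.times
    if t.size == 0:
        return []
    breaks = np.nonzero(np.diff(t) > max_intra_isi)[0] + 1
    return np.split(t, breaks)


def ibi(bursts: list[np.ndarray]) -> np.ndarray:
    """Onset-to-onset differences of consecutive bursts, ms."""
    if len(bursts) < 2:
        raise UndefinedStatisticError("IBIs need at least 2 bursts")
    onsets = np.array([b[0] for b in bursts])
    return np.diff(onsets)


def ibi_stats(bursts: list[np.ndarray]) -> IntervalStats:
    """Sample mean and unbiased variance of the IBIs (needs >= 3 bursts)."""
    if len(bursts) < 2:
        raise UndefinedStatisticError("IBI stats need at least 2 bursts")
    return _interval_stats(ibi(bursts), "IBI")


def steady_state_isi_mean(train: SpikeTrain, discard_fraction: float = 0.5) -> float:
    """Mean ISI after discarding the adaptation transient.

    Only spikes in the last (1 - discard_fraction) of the window enter;
    with the default, intervals are averaged over the second half of the
    run, well past the few-spike adaptation of the regular-spiking regime.
    """
    if not (0 <= discard_fraction < 1):
        raise InvalidArgumentError("discard_fraction must be in [0, 1)")
    sub = train.after(discard_fraction * train.t_end)
    if len(sub) < 2:
        raise UndefinedStatisticError(
            "steady-state ISI needs >= 2 spikes after the discard window"
        )
    return float(np.mean(np.diff(sub.times)))


def relative_error(test_isi: float, ref_isi: float) -> float:
    """|test - ref| / ref, truncated (not rounded) to 3 decimal places.

    Truncation matches the published error column: 0.5/38.5 = 0.012987
    reports as 0.012, where rounding would give 0.013.
    """
    if not (ref_isi > 0):
        raise InvalidArgumentError(f"reference ISI must be > 0, got {ref_isi}")
    err = abs(test_isi - ref_isi) / ref_isi
    return math.floor(err * 1000.0 + 1e-9) / 1000.0


def phase_plane(v_trace: Trace, tau: float = 5.0) -> np.ndarray:
    """Delay embedding: pairs (v(t), v(t + tau)) for every valid sample.

    tau must be a positive integer multiple of the sample period (relative
    tolerance 1e-9). Returns an array of shape (n_samples - tau/dt, 2).
    """
    if not (tau > 0):
        raise InvalidArgumentError(f"tau must be > 0, got {tau}")
    ratio = tau / v_trace.dt
    lag = round(ratio)
    if lag < 1 or abs(ratio - lag) > 1e-9 * max(1.0, ratio):
        raise InvalidArgumentError(
            f"tau = {tau} ms is not a positive multiple of dt = {v_trace.dt} ms"
        )
    v = v_trace.values
    return np.column_stack([v[: v.size - lag], v[lag:]])


@dataclass(frozen=True)
class SpikeTimeComparison:
    """Index-paired spike-timing offsets between two runs of one stimulus."""

    matched: bool
    n_a: int
    n_b: int
    offsets: np.ndarray | None  # b - a per spike index, ms; None on mismatch
    max_abs_offset: float | None

    def __str__(self) -> str:
        if not self.matched:
            return f"spike-count mismatch: {self.n_a} vs {self.n_b}"
        return (
            f"{self.n_a} spikes compared, max |offset| = {self.max_abs_offset:.4f} ms"
        )


def spike_time_diffs(a: SpikeTrain, b: SpikeTrain) -> SpikeTimeComparison:
    """Pair spikes by index and report per-spike offsets and their max.

    Unequal counts yield a mismatch report (matched=False), not an error:
    the comparison is meant for identical stimuli across back-ends, where
    counts agree.
    """
    if len(a) != len(b):
        return SpikeTimeComparison(False, len(a), len(b), None, None)
    offsets = b.times - a.times
    max_abs = float(np.max(np.abs(offsets))) if offsets.size else 0.0
    return SpikeTimeComparison(True, len(a), len(b), offsets, max_abs)


def run_report_row(
    result,
    *,
    amplitude: float | None = None,
    regime: str | None = None,
    max_intra_isi: float = DEFAULT_MAX_INTRA_ISI,
    reference_isi: float | None = None,
) -> dict:
    """One report row: regime, backend, amplitude, ISI/IBI stats, rel. error.

    The machine twin of the published summary tables; statistics that are
    undefined for the run (too few spikes/bursts) are left as NaN.
    """
    train = result.spike_train
    row = {
        "afferent": result.afferent,
        "regime": regime if regime is not None else "",
        "backend": result.backend,
        "amplitude": amplitude if amplitude is not None else np.nan,
        "n_spikes": len(train),
        "isi_mean": np.nan,
        "isi_var": np.nan,
        "ibi_mean": np.nan,
        "ibi_var": np.nan,
        "rel_error": np.nan,
    }
    try:
        stats = isi_stats(train)
        row["isi_mean"], row["isi_var"] = stats.mean, stats.variance
    except UndefinedStatisticError:
        pass
    try:
        bursts = detect_bursts(train, max_intra_isi)
        stats = ibi_stats(bursts)
        row["ibi_mean"], row["ibi_var"] = stats.mean, stats.variance
    except UndefinedStatisticError:
        pass
    if reference_isi is not None and not math.isnan(row["isi_mean"]):
        row["rel_error"] = relative_error(row["isi_mean"], reference_isi)
    return row


def write_report(rows: list[dict], path) -> pd.DataFrame:
    """Write report rows as CSV and return the DataFrame."""
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df
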