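"""Force-to-current transduction: rectify, weight, sum.

The sensor force f(t) and its time derivative f'(t) are each split into
positive and negative rectified parts, giving four non-negative signals.
A weighted sum of the four is the afferent input current I(t) in mA. The
gains K1 (SA-I) and K2 (FA-I) are *not* applied here — they enter the
membrane equation as K1/Cm and K2/Cm inside the neuron module, so this
module is purely the rectify-weight-sum block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidArgumentError
from .stimuli import Trace, _warn_force_range

DERIV_MODES = ("difference", "difference_over_h")


@dataclass(frozen=True)
class TransductionParams:
    """Weights for the four rectified signals plus the shared constants.

    The published design does not print the four weights; the default drives
    the afferent with the positive part of the force only (the FA-I equation
    supplies its own derivative sensitivity), all four remain configurable.
    """

    w_f_pos: float = 1.0
    w_f_neg: float = 0.0
    w_df_pos: float = 0.0
    w_df_neg: float = 0.0
    k1: float = 0.75
    k2: float = 3.0
    cm: float = 1.0
    deriv_mode: str = "difference_over_h"

    def __post_init__(self):
        if not (self.cm > 0):
            raise InvalidArgumentError(f"Cm must be > 0, got {self.cm}")
        for name in ("w_f_pos", "w_f_neg", "w_df_pos", "w_df_neg", "k1", "k2"):
            if not np.isfinite(getattr(self, name)):
                raise InvalidArgumentError(f"{name} must be finite")
        if self.deriv_mode not in DERIV_MODES:
            raise InvalidArgumentError(
                f"deriv_mode must be one of {DERIV_MODES}, got {self.deriv_mode!r}"
            )


def rectify_split(x) -> tuple[np.ndarray, np.ndarray]:
    """Split a signal into positive and negative rectified parts.

    Returns (pos, neg) with pos[k] = max(x[k], 0) and neg[k] = max(-x[k], 0),
    so pos - neg reconstructs x exactly and pos*neg = 0 everywhere.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise InvalidArgumentError("rectify_split requires finite samples")
    return np.maximum(x, 0.0), np.maximum(-x, 0.0)


def finite_diff(trace: Trace, mode: str = "difference") -> Trace:
    """First difference of a trace, left-aligned (d[k] pairs step k -> k+1).

    ``difference`` returns x[k+1] - x[k] (length N-1), the per-step form the
    discrete FA-I circuit consumes verbatim; ``difference_over_h`` divides by
    dt, giving the continuous-time derivative in units per ms.
    """
    if mode not in DERIV_MODES:
        raise InvalidArgumentError(f"unknown deriv mode {mode!r}")
    if len(trace) < 2:
        raise InvalidArgumentError("finite_diff needs a trace with >= 2 samples")
    d = np.diff(trace.values)
    unit = trace.unit
    if mode == "difference_over_h":
        d = d / trace.dt
        unit = {"N": "N/ms", "mA": "mA/ms"}.get(trace.unit, "")
    return Trace(values=d, dt=trace.dt, t0=trace.t0, unit=unit)


def force_to_current(force: Trace, params: TransductionParams | None = None) -> Trace:
    """Weighted sum of the four rectified force/derivative signals, in mA.

    The derivative components are left-aligned and the final (missing) sample
    is padded with 0, so the output shares the input grid sample-for-sample.
    """
    if params is None:
        params = TransductionParams()
    if force.unit == "N":
        _warn_force_range(force.values)
    f_pos, f_neg = rectify_split(force.values)
    current = params.w_f_pos * f_pos + params.w_f_neg * f_neg
    if (params.w_df_pos != 0 or params.w_df_neg != 0) and len(force) >= 2:
        d = finite_diff(force, params.deriv_mode).values
        d = np.append(d, 0.0)
        d_pos, d_neg = rectify_split(d)
        current = current + params.w_df_pos * d_pos + params.w_df_neg * d_neg
    return Trace(values=current, dt=force.dt, t0=force.t0, unit="mA")
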