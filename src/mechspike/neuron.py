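"""Izhikevich dynamics of the SA-I and FA-I afferents.

Two back-ends integrate the same two-variable quadratic model

    dv/dt = 0.04 v^2 + 5 v + 140 - u + drive
    du/dt = a (b v - u),        if v >= Vth: v <- c, u <- u + d

where the drive is (K1/Cm) I(t) for the SA-I (Merkel) afferent and
(K2/Cm) dI/dt for the FA-I (Meissner) afferent:

* ``simulate_rk4`` — classical fourth-order Runge-Kutta at the sample
  step, the double-precision continuous reference;
* ``simulate_euler`` — the forward-Euler discrete circuit at h = dt.
  Its FA-I variant adds (K2/Cm)(I[n+1] - I[n]) *outside* the h factor,
  exactly as the digital circuit computes it (the two forms agree to
  first order since I[n+1] - I[n] = h dI/dt).

Spike scheduling is shared by every back-end (including the fixed-point
emulation): the update is computed first and compared to Vth second; the
spike sample stores the clamp value Vth, the following sample stores the
reset state (c, u + d) — a one-step reset write, as a hardware register
performs it — and integration resumes on the next step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, NamedTuple

import numpy as np

from .errors import InvalidArgumentError, NumericalOverflowError
from .stimuli import Trace, write_spike_times

AFFERENTS = ("SA-I", "FA-I")

#: (a, b, c, d) presets: regular spiking vs bursting discharge.
REGIME_PRESETS = {
    "spiking": (0.02, 0.2, -65.0, 6.0),
    "bursting": (0.02, 0.2, -50.0, 1.5),
}

DEFAULT_H = 0.01  # ms, the discrete circuit's step
DEFAULT_K1 = 0.75
DEFAULT_K2 = 3.0


def normalize_afferent(name: str) -> str:
    key = name.upper().replace("_", "-").replace("SAI", "SA-I").replace("FAI", "FA-I")
    if key not in AFFERENTS:
        raise InvalidArgumentError(f"afferent must be one of {AFFERENTS}, got {name!r}")
    return key


@dataclass(frozen=True)
class NeuronParams:
    """Izhikevich constants.

    a is the recovery time scale (1/ms), b the recovery sensitivity, c the
    reset potential (mV), d the post-spike recovery increment. Vth = 30 mV
    is the spike cut-off; Cm = 1 the membrane constant dividing the gains.
    """

    a: float = 0.02
    b: float = 0.2
    c: float = -65.0
    d: float = 6.0
    vth: float = 30.0
    cm: float = 1.0
    regime: str = "spiking"

    def __post_init__(self):
        if not (self.vth > self.c):
            raise InvalidArgumentError(
                f"Vth ({self.vth}) must exceed the reset potential c ({self.c})"
            )
        if not (self.cm > 0):
            raise InvalidArgumentError(f"Cm must be > 0, got {self.cm}")

    @classmethod
    def preset(cls, regime: str, **overrides) -> "NeuronParams":
        """Parameter set for the ``spiking`` or ``bursting`` regime."""
        try:
            a, b, c, d = REGIME_PRESETS[regime]
        except KeyError:
            raise InvalidArgumentError(
                f"regime must be one of {tuple(REGIME_PRESETS)}, got {regime!r}"
            ) from None
        return cls(a=a, b=b, c=c, d=d, regime=regime, **overrides)


class NeuronState(NamedTuple):
    v: float  # membrane potential, mV
    u: float  # recovery variable, model units


def default_init(params: NeuronParams) -> NeuronState:
    """Subthreshold start v = c, u = b*c (on the recovery nullcline)."""
    return NeuronState(params.c, params.b * params.c)


def euler_step(
    state: NeuronState,
    i_n: float,
    di_n: float,
    params: NeuronParams,
    h: float = DEFAULT_H,
    afferent: str = "SA-I",
    k1: float = DEFAULT_K1,
    k2: float = DEFAULT_K2,
) -> NeuronState:
    """One forward-Euler update; no threshold/reset applied.

    For the SA-I the drive is (k1/cm) * i_n inside the h factor; for the
    FA-I the per-step current difference di_n enters as (k2/cm) * di_n
    added outside the h factor, as the discrete circuit computes it.
    """
    if not (h > 0):
        raise InvalidArgumentError(f"h must be > 0, got {h}")
    afferent = normalize_afferent(afferent)
    v, u = state
    if not (math.isfinite(v) and math.isfinite(u)):
        raise NumericalOverflowError("non-finite state passed to euler_step", step=0)
    acc = 0.04 * (v * v)
    acc = acc + 5.0 * v
    acc = acc + 140.0
    acc = acc - u
    if afferent == "SA-I":
        acc = acc + (k1 / params.cm) * i_n
        vn = v + h * acc
    else:
        vn = v + h * acc
        vn = vn + (k2 / params.cm) * di_n
    r = params.b * v
    r = r - u
    r = params.a * r
    un = u + h * r
    return NeuronState(vn, un)


def apply_reset(state: NeuronState, params: NeuronParams) -> tuple[NeuronState, bool]:
    """Threshold test: if v >= Vth return (c, u + d) and spiked=True."""
    if state.v >= params.vth:
        return NeuronState(params.c, state.u + params.d), True
    return state, False


@dataclass
class SimResult:
    """Output of one simulation run.

    ``spike_times`` are the sample times at which v was clamped to Vth;
    ``overflow_count`` counts saturation events in the fixed-point back-end
    (always 0 for rk4/euler).
    """

    v_trace: Trace
    u_trace: Trace
    spike_times: np.ndarray
    backend: str  # rk4 | euler | fixed
    afferent: str  # SA-I | FA-I
    overflow_count: int = 0

    @property
    def spike_train(self):
        from .analysis import SpikeTrain

        return SpikeTrain(times=self.spike_times, t_end=self.v_trace.t_end)

    def save(self, directory, stem: str = "run") -> dict[str, str]:
        """Write the (time, v, u) trace CSV and the spike-time CSV."""
        import pandas as pd
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        trace_path = directory / f"{stem}_trace.csv"
        pd.DataFrame(
            {
                "t_ms": self.v_trace.times,
                "v_mV": self.v_trace.values,
                "u": self.u_trace.values,
            }
        ).to_csv(trace_path, index=False)
        spikes_path = directory / f"{stem}_spikes.csv"
        write_spike_times(self.spike_times, spikes_path)
        return {"trace": str(trace_path), "spikes": str(spikes_path)}


def _drive_arrays(current: Trace) -> tuple[np.ndarray, np.ndarray]:
    """Input samples and left-aligned per-step differences (last padded 0)."""
    I = current.values
    if I.size >= 2:
        dI = np.append(np.diff(I), 0.0)
    else:
        dI = np.zeros_like(I)
    return I, dI


def _run_loop(
    current: Trace,
    params: NeuronParams,
    afferent: str,
    init: NeuronState,
    backend: str,
    step_fn: Callable[[float, float, float, float], tuple[float, float]],
    reset_fn: Callable[[float], tuple[float, float]],
    vth: float,
) -> SimResult:
    """Shared clamp/reset scheduling around a per-step update function."""
    I, dI = _drive_arrays(current)
    n = I.size
    v_arr = np.empty(n)
    u_arr = np.empty(n)
    v, u = init
    v_arr[0], u_arr[0] = v, u
    spikes: list[float] = []
    t0, dt = current.t0, current.dt
    hold = False
    isfinite = math.isfinite
    for k in range(1, n):
        if hold:  # reset value occupies one sample; v here is exactly c
            v_arr[k], u_arr[k] = v, u
            hold = False
            continue
        vn, un = step_fn(v, u, I[k - 1], dI[k - 1])
        if not (isfinite(vn) and isfinite(un)):
            raise NumericalOverflowError(
                f"state became non-finite at step {k} (t = {t0 + k * dt:.4f} ms)", step=k
            )
        if vn >= vth:
            v_arr[k], u_arr[k] = vth, un  # clamp the stored spike sample
            spikes.append(t0 + k * dt)
            v, u = reset_fn(un)
            hold = True
        else:
            v_arr[k], u_arr[k] = vn, un
            v, u = vn, un
    return SimResult(
        v_trace=Trace(values=v_arr, dt=dt, t0=t0, unit="mV"),
        u_trace=Trace(values=u_arr, dt=dt, t0=t0, unit=""),
        spike_times=np.asarray(spikes),
        backend=backend,
        afferent=afferent,
    )


def simulate_euler(
    current: Trace,
    params: NeuronParams,
    afferent: str = "SA-I",
    init: NeuronState | None = None,
    k1: float = DEFAULT_K1,
    k2: float = DEFAULT_K2,
) -> SimResult:
    """Integrate the discrete circuit equations at h = current.dt."""
    afferent = normalize_afferent(afferent)
    if init is None:
        init = default_init(params)
    h = current.dt
    a, b, cm = params.a, params.b, params.cm
    k1cm = k1 / cm
    k2cm = k2 / cm

    if afferent == "SA-I":

        def step(v, u, i, di):
            acc = 0.04 * (v * v)
            acc = acc + 5.0 * v
            acc = acc + 140.0
            acc = acc - u
            acc = acc + k1cm * i
            vn = v + h * acc
            r = b * v
            r = r - u
            r = a * r
            return vn, u + h * r

    else:

        def step(v, u, i, di):
            acc = 0.04 * (v * v)
            acc = acc + 5.0 * v
            acc = acc + 140.0
            acc = acc - u
            vn = v + h * acc
            vn = vn + k2cm * di
            r = b * v
            r = r - u
            r = a * r
            return vn, u + h * r

    c, d = params.c, params.d
    return _run_loop(
        current, params, afferent, init, "euler", step, lambda u: (c, u + d), params.vth
    )


def simulate_rk4(
    current: Trace,
    params: NeuronParams,
    afferent: str = "SA-I",
    init: NeuronState | None = None,
    k1: float = DEFAULT_K1,
    k2: float = DEFAULT_K2,
) -> SimResult:
    """Classical RK4 on the continuous equations at step dt.

    The drive is held constant within each step: (k1/cm) I[n] for the SA-I,
    (k2/cm) dI/dt with dI/dt = (I[n+1] - I[n])/dt for the FA-I. The reset is
    an event applied at step boundaries only (spike times are reported at
    sample resolution).
    """
    afferent = normalize_afferent(afferent)
    if init is None:
        init = default_init(params)
    h = current.dt
    a, b, cm = params.a, params.b, params.cm
    gain = (k1 if afferent == "SA-I" else k2) / cm
    per_step_di = afferent == "FA-I"

    def step(v, u, i, di):
        drive = gain * (di / h if per_step_di else i)

        def f(vv, uu):
            return 0.04 * vv * vv + 5.0 * vv + 140.0 - uu + drive, a * (b * vv - uu)

        k1v, k1u = f(v, u)
        k2v, k2u = f(v + 0.5 * h * k1v, u + 0.5 * h * k1u)
        k3v, k3u = f(v + 0.5 * h * k2v, u + 0.5 * h * k2u)
        k4v, k4u = f(v + h * k3v, u + h * k3u)
        return (
            v + (h / 6.0) * (k1v + 2.0 * k2v + 2.0 * k3v + k4v),
            u + (h / 6.0) * (k1u + 2.0 * k2u + 2.0 * k3u + k4u),
        )

    c, d = params.c, params.d
    return _run_loop(
        current, params, afferent, init, "rk4", step, lambda u: (c, u + d), params.vth
    )
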