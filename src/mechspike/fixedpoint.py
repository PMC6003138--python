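"""N-bit register arithmetic emulating the digital circuit's datapath.

The hardware solves each state variable in N-bit registers (N = 32 in the
published build). The integer/fraction split, rounding and overflow policy
of that build are not published; the defaults here — Q16.16 (1 sign + 15
integer + 16 fractional bits), truncation toward negative infinity
(arithmetic right-shift semantics) and saturation — are declared emulation
choices mimicking a typical FPGA datapath, not claims about the board.
Q16.16 leaves ample headroom: |v| stays below ~35 mV over -80 mV, and the
largest intermediate, v^2 ~ 4900, fits comfortably in 15 integer bits.

``simulate_euler_fixed`` runs the same control flow as the double-precision
Euler back-end but re-quantizes every intermediate product and sum (per_op
granularity, emulating register-to-register transfers), or just the state
update (per_state, cheaper). With quantization disabled (fmt=None) it is
bit-identical to ``simulate_euler``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InvalidArgumentError
from .neuron import (
    DEFAULT_K1,
    DEFAULT_K2,
    NeuronParams,
    NeuronState,
    SimResult,
    _run_loop,
    default_init,
    normalize_afferent,
)
from .stimuli import Trace

OVERFLOW_POLICIES = ("saturate", "wrap")
ROUNDING_POLICIES = ("truncate", "nearest")
GRANULARITIES = ("per_op", "per_state")


@dataclass(frozen=True)
class FixedFormat:
    """Signed fixed-point register description.

    A real x is stored as the integer code round(x * 2**frac_bits) in a
    ``total_bits``-wide two's-complement register; its value is
    code / 2**frac_bits. Resolution (1 LSB) is 2**-frac_bits.
    """

    total_bits: int = 32
    frac_bits: int = 16
    overflow: str = "saturate"
    rounding: str = "truncate"

    def __post_init__(self):
        if not (1 <= self.frac_bits < self.total_bits):
            raise InvalidArgumentError(
                f"need 1 <= frac_bits < total_bits, got Q{self.total_bits - self.frac_bits}"
                f".{self.frac_bits}"
            )
        if self.overflow not in OVERFLOW_POLICIES:
            raise InvalidArgumentError(f"overflow must be one of {OVERFLOW_POLICIES}")
        if self.rounding not in ROUNDING_POLICIES:
            raise InvalidArgumentError(f"rounding must be one of {ROUNDING_POLICIES}")

    @property
    def eps(self) -> float:
        """Value of one LSB, 2**-frac_bits."""
        return 2.0 ** -self.frac_bits

    @property
    def max_code(self) -> int:
        return (1 << (self.total_bits - 1)) - 1

    @property
    def max_value(self) -> float:
        return self.max_code * self.eps


def to_fixed(x: float, fmt: FixedFormat) -> int:
    """Encode a real as the signed integer register code."""
    code, _ = _encode(x, fmt)
    return code


def from_fixed(code: int, fmt: FixedFormat) -> float:
    """Decode a register code back to its real value."""
    return code * fmt.eps


def _encode(x: float, fmt: FixedFormat) -> tuple[int, bool]:
    scaled = x * (1 << fmt.frac_bits)
    if fmt.rounding == "truncate":
        code = math.floor(scaled)
    else:
        code = math.floor(scaled + 0.5)
    hi = fmt.max_code
    if -hi <= code <= hi:
        return code, False
    if fmt.overflow == "saturate":
        return (hi if code > hi else -hi), True
    span = 1 << fmt.total_bits
    return ((code + (span >> 1)) % span) - (span >> 1), True


def quantize(x: float, fmt: FixedFormat) -> float:
    """Round-trip a real through the register: from_fixed(to_fixed(x))."""
    return to_fixed(x, fmt) * fmt.eps


def simulate_euler_fixed(
    current: Trace,
    params: NeuronParams,
    afferent: str = "SA-I",
    fmt: FixedFormat | None = FixedFormat(),
    init: NeuronState | None = None,
    k1: float = DEFAULT_K1,
    k2: float = DEFAULT_K2,
    granularity: str = "per_op",
) -> SimResult:
    """Forward-Euler circuit with register quantization (backend ``fixed``).

    Identical scheduling to ``simulate_euler``; constants are pre-quantized
    once, input samples pass through the input register, and — at per_op
    granularity — every product and sum is re-quantized. ``fmt=None``
    disables quantization entirely. Saturation events are tallied in
    ``SimResult.overflow_count`` and never abort the run.
    """
    afferent = normalize_afferent(afferent)
    if granularity not in GRANULARITIES:
        raise InvalidArgumentError(f"granularity must be one of {GRANULARITIES}")
    if init is None:
        init = default_init(params)

    overflows = [0]
    if fmt is None:

        def q(x: float) -> float:
            return x

    else:
        scale = float(1 << fmt.frac_bits)
        inv = fmt.eps
        hi = fmt.max_code
        floor = math.floor
        nearest = fmt.rounding == "nearest"
        saturate = fmt.overflow == "saturate"
        span = 1 << fmt.total_bits
        half_span = span >> 1

        def q(x: float) -> float:
            code = floor(x * scale + 0.5) if nearest else floor(x * scale)
            if code > hi or code < -hi:
                overflows[0] += 1
                if saturate:
                    code = hi if code > hi else -hi
                else:
                    code = ((code + half_span) % span) - half_span
            return code * inv

    h = current.dt
    a, b, cm = params.a, params.b, params.cm
    qa, qb = q(a), q(b)
    qh = q(h)
    c04, c5, c140 = q(0.04), q(5.0), q(140.0)
    qk1cm = q(k1 / cm)
    qk2cm = q(k2 / cm)
    qc, qd = q(params.c), q(params.d)

    # input register: quantize samples once; per-step differences are exact
    # in fixed point, so diff after quantization needs no re-quantization
    Iq = np.array([q(x) for x in current.values])
    current_q = Trace(values=Iq, dt=current.dt, t0=current.t0, unit=current.unit)

    sa = afferent == "SA-I"
    if granularity == "per_op":

        def step(v, u, i, di):
            t = q(v * v)
            t = q(c04 * t)
            s = q(t + q(c5 * v))
            s = q(s + c140)
            s = q(s - u)
            if sa:
                s = q(s + q(qk1cm * i))
                vn = q(v + q(qh * s))
            else:
                vn = q(v + q(qh * s))
                vn = q(vn + q(qk2cm * di))
            r = q(q(qb * v) - u)
            r = q(qa * r)
            un = q(u + q(qh * r))
            return vn, un

    else:

        def step(v, u, i, di):
            acc = c04 * (v * v)
            acc = acc + c5 * v
            acc = acc + c140
            acc = acc - u
            if sa:
                acc = acc + qk1cm * i
                vn = v + qh * acc
            else:
                vn = v + qh * acc
                vn = vn + qk2cm * di
            r = qb * v
            r = r - u
            r = qa * r
            un = u + qh * r
            return q(vn), q(un)

    init_q = NeuronState(q(init.v), q(init.u))
    result = _run_loop(
        current_q,
        params,
        afferent,
        init_q,
        "fixed",
        step,
        lambda u: (qc, q(u + qd)),
        params.vth,
    )
    result.overflow_count = overflows[0]
    return result
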