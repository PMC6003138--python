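# Methods

## Model and assumptions

`mechspike` simulates the mechano-neuro transduction chain of two cutaneous
afferent classes. A sensed normal force `f(t)` (N) and its time derivative
`ḟ(t)` (N/ms) are each split into positive and negative rectified parts;
the four signals are weighted and summed into the drive current `I(t)`
(mA). The published design does not print the four weights; the default is
`w_f_pos = 1` with the rest 0 — the SA-I is driven by the pressing force
and the FA-I equation supplies its own derivative sensitivity — and all
four are exposed in config. Whether a physical build applies the
negative-part weights at all is unknowable from the outside (an FSR only
reports non-negative force); the default assumes not.

The neuron is the two-variable quadratic (Izhikevich) model. Its membrane
equation is quadratic in `v`, so for constant drive `I_eff = (K1/Cm)·I`
the resting and threshold equilibria lie at the roots of
`0.04 v² + 4.8 v + 140 + I_eff = 0`; they merge and vanish at
`I_eff = 4` (the rheobase), above which firing is tonic. At `I = 0` the
stable equilibrium is exactly `(v, u) = (−70, −14)`, which the test suite
uses as an analytic stationarity oracle for every back-end.

Parameters (units; defaults):

| name | meaning | default |
|------|---------|---------|
| a (1/ms) | recovery time scale | 0.02 |
| b | recovery sensitivity | 0.2 |
| c (mV) | reset potential | −65 (spiking) / −50 (bursting) |
| d | post-spike recovery increment | 6 (spiking) / 1.5 (bursting) |
| Vth (mV) | spike cut-off | 30 |
| Cm | membrane constant | 1 |
| K1, K2 | SA-I / FA-I drive gains | 0.75, 3 |
| h (ms) | integration / circuit step | 0.01 |

The regime presets switch (c, d) only; both afferent types can run in
either regime.

## Back-ends and numerical choices

* **rk4** — classical fourth-order Runge–Kutta at the sample step, drive
  held constant within a step ((K1/Cm)·I[n] for SA-I, (K2/Cm)·(I[n+1] −
  I[n])/h for FA-I). This is the double-precision continuous reference.
* **euler** — forward Euler at h. The FA-I derivative term is added
  *outside* the h factor as `(K2/Cm)(I[n+1] − I[n])`, which is how the
  digital circuit computes it; the two FA-I forms agree to first order
  because `I[n+1] − I[n] = h·dI/dt`.
* **fixed** — the euler circuit on quantized registers (below).

Shared reset scheduling (all back-ends): the update is computed first and
compared to Vth second. The spike sample stores the clamp value Vth (not
the overshoot), which bounds trace amplitude and makes phase planes
comparable across back-ends; the *next* sample stores the reset state
`(c, u + d)` verbatim — a one-cycle reset write, as a hardware register
performs it — and integration resumes on the following step. This makes
"sample after a spike equals c" an exact invariant at the cost of
lengthening every ISI by exactly one step (0.01 ms), invisible at the
0.1 ms precision of the published tables. The reset is applied at step
boundaries only (no crossing-time interpolation); spike times are sample
times. `u` is stored as computed, never clamped. Initial conditions
default to `v = c, u = b·c`, an exact subthreshold start on the recovery
nullcline. A non-finite state aborts with the offending step index.

## Input convention (labeled amplitude → injected current)

The published amplitude sweep labels its constant inputs 2.4–3 mA, yet
with K1 = 0.75 those amplitudes are below rheobase and could not fire
tonically, so some gain in the measurement chain must sit between the
label and the injected current. Probing the plausible conventions against
the continuous reference: the label as-is and label×K1 are subthreshold;
label×10 fires at 12–15 ms ISIs, far from the reported 38–49 ms. Inverting
the reported ISIs gives an effective drive of 3.295–3.300 × label,
consistent across all four amplitudes — i.e. an injected current of 4.4 ×
label once K1 = 0.75 is applied, and an overall 3.3× scale that matches
the 3.3 V full scale of the target board's analog chain. The package
therefore fixes the convention as the config field `input_gain = 4.4`
(injected `I[n] = input_gain × labeled amplitude`); every sweep report
states the convention used, and `input_gain: 1.0` disables it when the
input already is the injected current. Under this convention the
recomputed ISIs match the published table to ≤ 0.5 % on every row and
back-end.

## Fixed-point emulation

The hardware solves each state variable in N = 32-bit registers but does
not publish the integer/fraction split, rounding or overflow behavior.
Defaults (declared emulation choices, not claims about the board):
Q16.16 — 1 sign + 15 integer + 16 fractional bits — because `|v| ≤ ~35`
and the largest intermediate `v² ≈ 4900` fits with ample headroom;
truncation toward −∞ (arithmetic right-shift, the cheapest datapath);
saturation at ±(2³¹−1) codes. Quantization is applied per arithmetic
operation (register-to-register transfer); a cheaper per-state-update mode
is available. Constants are pre-quantized once; input samples pass through
the input register. Saturation events are tallied, never fatal. With
quantization disabled the fixed back-end is bit-identical to the euler
back-end (the float code mirrors the register dataflow order op for op).

Precision-refinement behavior is characterized with the integer field held
at 16 bits (total = frac + 16): inside a fixed 32-bit register, fraction
widths ≥ 20 leave too few integer bits for `v²` and the run saturates into
garbage — an integer-overflow artifact, not a quantization property — so
the monotone-refinement check varies the fraction at constant integer
headroom, where the ISI error falls monotonically (0.44 → 2×10⁻⁵ from 8 to
24 fractional bits against the double-precision circuit).

## Analysis definitions

ISIs are consecutive spike-time differences; variances are the unbiased
(n−1) sample estimator. Steady-state mean ISI discards the first half of
the observation window, well past the few-spike adaptation transient of
the regular-spiking regime. Bursts group spikes separated by ≤ 20 ms
(exposed as `max_intra_isi`; the published traces define bursts only by
appearance, and 20 ms cleanly separates few-ms intra-burst intervals from
tens-of-ms pauses); IBIs are onset-to-onset differences; isolated spikes
are one-spike bursts. The relative-error figure of merit truncates (not
rounds) to three decimals, reproducing the published error column
(0.5/38.5 = 0.012987 → 0.012). Spike-train comparison pairs spikes by
index — it is meant for runs of the same stimulus across back-ends, where
counts match; mismatched counts produce a report, not an error. The phase
plane is the delay embedding `v(t+τ)` vs `v(t)` with τ = 5 ms by default;
τ must be an integer multiple of dt.

## Synthetic stimuli: what they do and do not emulate

All validation inputs are generated programmatically: constant drives at
the published labeled amplitudes (1000 ms, h = 0.01 ms — the problem sizes
used throughout the tests and the acceptance script), 2 s sustained drives
for the adaptation properties, step-and-hold staircases for FA-I
transience, and sine/triangle/pulse waves. These reproduce the *stimulus
classes* of the published experiments, not their graphically-shown exact
staircase levels; consequently the staircase ISI/IBI summary table is
reproduced qualitatively (the machine-readable report has the same
columns) while the quantitative targets are the printed amplitude-sweep
ISIs and relative errors. Passing tests show the encoder and its digital
emulation are faithful to the model; they say nothing about FSR
nonlinearity, amplifier/filter dynamics, ADC sampling or biological
plausibility, none of which are modeled.

## Known limitations

* The input convention is a probed calibration, not a published constant;
  if the real chain's gain differs, absolute ISIs shift but every relative
  and qualitative result stands.
* The FA-I drive reacts to single-sample current steps; band-limited real
  sensors spread a step over many samples, which lowers the per-step kick
  and raises the effective FA-I threshold.
* The one-cycle reset write briefly ignores the input during the reset
  sample; a stimulus edge landing exactly there (probability ~h/ISI) is
  seen one step late.
* Fixed-point results depend on the declared Q-format defaults; other
  splits/roundings are configurable but not validated against hardware.
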