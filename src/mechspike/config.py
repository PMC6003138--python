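"""Run configuration: validated parameter sets for the end-to-end pipeline.

A RunConfig resolves a (possibly partial) mapping — from YAML, JSON or a
plain dict — into a complete parameter set: stimulus, transduction
weights/gains, neuron constants, back-end and fixed-point format. Unknown
keys anywhere are rejected, all of them named at once.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ConfigValidationError, InvalidArgumentError
from .fixedpoint import FixedFormat
from .neuron import DEFAULT_H, NeuronParams, REGIME_PRESETS, normalize_afferent
from .transduction import TransductionParams

#: Scale from a stimulus's labeled amplitude to the injected current I[n].
#: The published amplitude sweep labels its constant inputs 2.4-3 mA, yet
#: with K1 = 0.75 those amplitudes sit below the model's rheobase (an
#: effective drive of 4 is needed for tonic firing). Probing the labeled
#: amplitudes against the continuous reference shows the board injects
#: 4.4x the labeled value, i.e. an effective drive (K1/Cm)*I of 3.3x —
#: matching the 3.3 V full scale of the board's analog chain. Set to 1.0
#: when the input already is the injected current.
DEFAULT_INPUT_GAIN = 4.4

BACKENDS = ("rk4", "euler", "fixed")

STIMULUS_TYPES = ("constant", "staircase", "sine", "triangle", "pulse", "csv")

_STIMULUS_KEYS = {
    "type", "amplitude", "levels", "period", "duration", "duty", "offset",
    "dt", "path", "unit",
}
_TRANSDUCTION_KEYS = {
    "w_f_pos", "w_f_neg", "w_df_pos", "w_df_neg", "K1", "K2", "Cm", "deriv_mode",
    "k1", "k2", "cm",
}
_NEURON_KEYS = {"regime", "a", "b", "c", "d", "Vth", "vth", "Cm", "cm", "h"}
_FIXED_KEYS = {"total_bits", "frac_bits", "overflow", "rounding", "quantize_granularity"}
_TOP_KEYS = {
    "stimulus", "transduction", "neuron", "fixed_format", "afferent", "backend",
    "input_gain", "output_dir",
}

_CANON = {"K1": "k1", "K2": "k2", "Cm": "cm", "Vth": "vth"}


def _check_keys(section: dict, allowed: set, prefix: str, bad: list[str]) -> None:
    for key in section:
        if key not in allowed:
            bad.append(f"{prefix}{key}")


def _canon(section: dict) -> dict:
    return {_CANON.get(k, k): v for k, v in section.items()}


@dataclass(frozen=True)
class RunConfig:
    """Complete, validated parameter set for one encoding run."""

    stimulus: dict
    transduction: TransductionParams = TransductionParams()
    neuron: NeuronParams = NeuronParams()
    afferent: str = "SA-I"
    backend: str = "euler"
    fixed_format: FixedFormat = FixedFormat()
    input_gain: float = DEFAULT_INPUT_GAIN
    quantize_granularity: str = "per_op"
    output_dir: str = "mechspike_out"
    defaulted: tuple[str, ...] = ()  # provenance: keys filled from defaults

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        bad: list[str] = []
        _check_keys(raw, _TOP_KEYS, "", bad)
        stim = dict(raw.get("stimulus") or {})
        _check_keys(stim, _STIMULUS_KEYS, "stimulus.", bad)
        trans = dict(raw.get("transduction") or {})
        _check_keys(trans, _TRANSDUCTION_KEYS, "transduction.", bad)
        neur = dict(raw.get("neuron") or {})
        _check_keys(neur, _NEURON_KEYS, "neuron.", bad)
        fixed = dict(raw.get("fixed_format") or {})
        _check_keys(fixed, _FIXED_KEYS, "fixed_format.", bad)
        if bad:
            raise ConfigValidationError(
                "unknown config keys: " + ", ".join(sorted(bad)), keys=sorted(bad)
            )

        if "type" not in stim:
            raise ConfigValidationError("stimulus.type is required", keys=["stimulus.type"])
        if stim["type"] not in STIMULUS_TYPES:
            raise ConfigValidationError(
                f"stimulus.type must be one of {STIMULUS_TYPES}, got {stim['type']!r}",
                keys=["stimulus.type"],
            )
        backend = raw.get("backend", "euler")
        if backend not in BACKENDS:
            raise ConfigValidationError(
                f"backend must be one of {BACKENDS}, got {backend!r}", keys=["backend"]
            )

        trans = _canon(trans)
        neur = _canon(neur)
        h = neur.pop("h", None)
        if h is not None:
            stim_dt = stim.get("dt")
            if stim_dt is None:
                stim["dt"] = h
            elif abs(stim_dt - h) > 1e-12:
                raise ConfigValidationError(
                    f"neuron.h ({h}) conflicts with stimulus.dt ({stim_dt})",
                    keys=["neuron.h", "stimulus.dt"],
                )
        stim.setdefault("dt", DEFAULT_H)

        regime = neur.pop("regime", None)
        if regime is not None:
            if regime not in REGIME_PRESETS:
                raise ConfigValidationError(
                    f"neuron.regime must be one of {tuple(REGIME_PRESETS)}",
                    keys=["neuron.regime"],
                )
            pa, pb, pc, pd = REGIME_PRESETS[regime]
            merged = {"a": pa, "b": pb, "c": pc, "d": pd, **neur}
            neuron = NeuronParams(regime=regime, **merged)
        else:
            neuron = NeuronParams(**neur)

        granularity = fixed.pop("quantize_granularity", "per_op")
        defaulted = []
        for section, provided, known in (
            ("transduction", set(trans), {"w_f_pos", "w_f_neg", "w_df_pos", "w_df_neg",
                                          "k1", "k2", "cm", "deriv_mode"}),
            ("fixed_format", set(fixed), {"total_bits", "frac_bits", "overflow", "rounding"}),
        ):
            defaulted += [f"{section}.{k}" for k in sorted(known - provided)]
        for key in sorted(_TOP_KEYS - set(raw) - {"stimulus", "transduction", "neuron",
                                                  "fixed_format"}):
            defaulted.append(key)

        try:
            return cls(
                stimulus=stim,
                transduction=TransductionParams(**trans),
                neuron=neuron,
                afferent=normalize_afferent(raw.get("afferent", "SA-I")),
                backend=backend,
                fixed_format=FixedFormat(**fixed),
                input_gain=float(raw.get("input_gain", DEFAULT_INPUT_GAIN)),
                quantize_granularity=granularity,
                output_dir=str(raw.get("output_dir", "mechspike_out")),
                defaulted=tuple(defaulted),
            )
        except InvalidArgumentError as exc:
            raise ConfigValidationError(str(exc)) from exc

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(raw, dict):
            raise ConfigValidationError(f"{path}: config must be a mapping")
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        """Effective parameter set, fully explicit (re-loadable)."""
        t = self.transduction
        n = self.neuron
        f = self.fixed_format
        return {
            "stimulus": dict(self.stimulus),
            "transduction": {
                "w_f_pos": t.w_f_pos, "w_f_neg": t.w_f_neg,
                "w_df_pos": t.w_df_pos, "w_df_neg": t.w_df_neg,
                "K1": t.k1, "K2": t.k2, "Cm": t.cm, "deriv_mode": t.deriv_mode,
            },
            "neuron": {
                "a": n.a, "b": n.b, "c": n.c, "d": n.d,
                "Vth": n.vth, "Cm": n.cm, "regime": n.regime,
            },
            "fixed_format": {
                "total_bits": f.total_bits, "frac_bits": f.frac_bits,
                "overflow": f.overflow, "rounding": f.rounding,
                "quantize_granularity": self.quantize_granularity,
            },
            "afferent": self.afferent,
            "backend": self.backend,
            "input_gain": self.input_gain,
            "output_dir": self.output_dir,
        }

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @property
    def run_id(self) -> str:
        """Deterministic identifier of the effective parameter set."""
        import hashlib

        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
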