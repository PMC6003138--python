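"""Quick-look figures: membrane traces and phase-plane embeddings."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .analysis import phase_plane
from .neuron import SimResult


def plot_membrane(result: SimResult, path, stimulus=None) -> None:
    """Membrane potential (and optionally the stimulus) vs time."""
    n_panels = 2 if stimulus is not None else 1
    fig, axes = plt.subplots(n_panels, 1, sharex=True, figsize=(8, 2.5 * n_panels))
    axes = np.atleast_1d(axes)
    if stimulus is not None:
        axes[0].plot(stimulus.times, stimulus.values, lw=0.8)
        axes[0].set_ylabel(f"input ({stimulus.unit})")
    ax = axes[-1]
    ax.plot(result.v_trace.times, result.v_trace.values, lw=0.5)
    ax.set_xlabel("t (ms)")
    ax.set_ylabel("v (mV)")
    ax.set_title(f"{result.afferent} / {result.backend}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_phase_plane(result: SimResult, path, tau: float = 5.0) -> None:
    """Delay-embedding scatter v(t + tau) vs v(t)."""
    pairs = phase_plane(result.v_trace, tau)
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(pairs[:, 0], pairs[:, 1], ".", ms=0.5)
    ax.set_xlabel("v(t) (mV)")
    ax.set_ylabel(f"v(t + {tau:g}) (mV)")
    ax.set_title(f"{result.afferent} / {result.backend}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
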