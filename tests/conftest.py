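import numpy as np
import pytest

from mechspike import (
    FixedFormat,
    NeuronParams,
    make_constant,
    simulate_euler,
    simulate_euler_fixed,
    simulate_rk4,
    steady_state_isi_mean,
)
from mechspike.config import DEFAULT_INPUT_GAIN
from mechspike.pipeline import SWEEP_AMPLITUDES


@pytest.fixture(scope="session")
def spiking_params():
    return NeuronParams.preset("spiking")


@pytest.fixture(scope="session")
def bursting_params():
    return NeuronParams.preset("bursting")


@pytest.fixture(scope="session")
def sweep_results(spiking_params):
    """Steady-state ISIs of the labeled-amplitude sweep, all back-ends.

    Computed once per session: 1000 ms constant drives at the four labeled
    amplitudes under the default input convention (injected current =
    4.4 x labeled amplitude).
    """
    out: dict[float, dict[str, float]] = {}
    for amp in SWEEP_AMPLITUDES:
        current = make_constant(amp * DEFAULT_INPUT_GAIN, 1000.0, 0.01)
        out[amp] = {
            "euler": steady_state_isi_mean(
                simulate_euler(current, spiking_params).spike_train
            ),
            "rk4": steady_state_isi_mean(
                simulate_rk4(current, spiking_params).spike_train
            ),
            "fixed": steady_state_isi_mean(
                simulate_euler_fixed(current, spiking_params, fmt=FixedFormat()).spike_train
            ),
        }
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20180608)
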