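import numpy as np
import pytest

from spnsens.design import SessionDesign
from spnsens.synth import DEFAULT_SHAPE, SynthNeuronSpec, gen_event_train, render_trace


@pytest.fixture
def design() -> SessionDesign:
    return SessionDesign()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def quiet_neuron(design):
    """A 0.1 Hz neuron at SNR ~10 with slow drift, plus its ground truth."""
    spec = SynthNeuronSpec(
        neuron_id="q0", rate_pre_hz=0.1, rate_post_hz=0.1,
        noise_sd=0.153, drift_amp=0.3,
    )
    train = gen_event_train(spec, design, 7)
    raw = render_trace(train, spec, design, 8)
    return spec, train, raw
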