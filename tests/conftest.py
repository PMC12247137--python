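import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from somatomode import CalciumSimConfig, Epoch, generate_recording


@pytest.fixture(scope="session")
def small_recording():
    """Low-noise 60-neuron recording with known responder classes."""
    cfg = CalciumSimConfig(
        n_neurons=60,
        class_counts={"both": 15, "only_a": 20, "only_b": 5, "none": 20},
        noise_sd=1.0,
        seed=7,
    )
    return generate_recording(cfg)


@pytest.fixture()
def tiny_epochs():
    return (
        Epoch("pinch", 120.0, 130.0, "mechanical"),
        Epoch("brush", 420.0, 430.0, "mechanical"),
    )
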