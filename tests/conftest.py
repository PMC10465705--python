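import numpy as np
import pytest

from dsbkinetics import GeneratorParams, ScenarioConfig, generate_ensemble


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_params():
    return GeneratorParams()


@pytest.fixture(scope="session")
def mixed_ensemble():
    """30 paired replicas per DSB distance 0-3 at the lowest force."""
    scenarios = [ScenarioConfig(b_d=b) for b in range(4)]
    manifest, traces = generate_ensemble(
        scenarios, 30, GeneratorParams(), seed=424242)
    return scenarios, manifest, traces
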