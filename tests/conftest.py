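import numpy as np
import pytest

from mslfnet import ModelConfig, SynthConfig, generate_sample


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_synth_config():
    """32x32 canvas with one lesion of each class — fast fixture material."""
    return SynthConfig(
        width=32, height=32, fov_radius_fraction=0.45,
        n_lesions_per_class=(1, 1, 1, 1),
        lesion_size_ranges=((1.0, 1.5), (2.0, 3.0), (4.0, 5.5), (2.0, 3.0)),
        n_vessels=1, seed=5)


@pytest.fixture(scope="session")
def tiny_samples(tiny_synth_config):
    return [generate_sample(tiny_synth_config, index=i) for i in range(2)]


@pytest.fixture(scope="session")
def toy_model_config():
    return ModelConfig(input_size=(32, 32), seed=0)


@pytest.fixture(scope="session")
def default_sample():
    return generate_sample(SynthConfig(seed=7))
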