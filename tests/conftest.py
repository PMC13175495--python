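import numpy as np
import pytest

from datgen import phantom, preprocess


@pytest.fixture(scope="session")
def default_spec():
    return phantom.PhantomSpec(seed=7)


@pytest.fixture(scope="session")
def default_atlas(default_spec):
    return phantom.build_atlas(default_spec)


@pytest.fixture(scope="session")
def clean_normal_study():
    """Noise-free normal subject (deterministic, symmetric)."""
    return phantom.simulate_study(
        phantom.PhantomSpec(subject_class="normal", severity=0.0,
                            noise_sd=0.0, seed=3))


@pytest.fixture(scope="session")
def clean_dp_study():
    """Noise-free symmetric DP subject at severity 0.8."""
    return phantom.simulate_study(
        phantom.PhantomSpec(subject_class="DP", severity=0.8, asymmetry=0.0,
                            noise_sd=0.0, seed=3))


@pytest.fixture(scope="session")
def phantom_cfg():
    return preprocess.PreprocessConfig.for_phantom()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
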