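import numpy as np
import pytest

from fcmseg.phantom import PhantomSpec, default_validation_suite, generate_phantom


@pytest.fixture(scope="session")
def suite_specs():
    return default_validation_suite(seed=1)


@pytest.fixture(scope="session")
def clean_bundle(suite_specs):
    return generate_phantom(suite_specs[0])


@pytest.fixture(scope="session")
def noisy_bundle(suite_specs):
    return generate_phantom(suite_specs[1])


@pytest.fixture(scope="session")
def lesioned_bundle(suite_specs):
    return generate_phantom(suite_specs[2])


@pytest.fixture(scope="session")
def small_lesioned_bundle():
    """A fast 40^3 phantom with two lesions for pipeline/CLI tests."""
    spec = PhantomSpec(shape=(40, 40, 40), noise_sigma=0.05, lesion_count=2,
                       lesion_radius_range=(1.5, 2.5), seed=3)
    return generate_phantom(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
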