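import numpy as np
import pytest

from fundusfm.model import BackboneConfig, build_student
from fundusfm.synthetic import SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def tiny_config():
    return BackboneConfig(image_side=64, patch_side=8, embed_dim=32, depth=2, heads=2)


@pytest.fixture(scope="session")
def tiny_model(tiny_config):
    return build_student(tiny_config, seed=1)


@pytest.fixture(scope="session")
def fundus_spec():
    return SyntheticSpec(image_side=64, seed=0)


@pytest.fixture(scope="session")
def small_dataset(fundus_spec):
    """64 patients x 2 images across all five grades."""
    return generate_dataset(fundus_spec, n_patients=64, images_per_patient=2,
                            grade_distribution=(0.2, 0.2, 0.2, 0.2, 0.2), seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
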