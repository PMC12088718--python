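import numpy as np
import pytest

from milcta import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_config():
    """Small cohort configuration used across unit tests (fast to render)."""
    return SyntheticConfig(
        image_height=64,
        image_width=64,
        n_patients=12,
        prevalence=0.5,
        slices_per_patient_range=(4, 8),
        plaque_slices_per_positive=2,
        text_annotation_prob=0.3,
        rng_seed=7,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return generate_cohort(tiny_config)
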