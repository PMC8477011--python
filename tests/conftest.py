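import numpy as np
import pytest

from mklfuse import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A compact three-modality cohort used across tests."""
    cfg = SyntheticConfig(
        n_case=40,
        n_control=40,
        n_female_per_group=16,
        modality_dims={"sMRI": 30, "DTI": 30, "rsfMRI": 20},
        n_informative={"sMRI": 4, "DTI": 4, "rsfMRI": 4},
        effect_size=1.0,
        n_batches=2,
        seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
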