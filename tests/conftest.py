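import numpy as np
import pytest

from connectodist import SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Shared small planted-effect study: 40 regions, 15+15 subjects."""
    spec = SyntheticSpec(
        n_regions=40,
        n_subjects_rest=15,
        n_subjects_task=15,
        planted_edges=((0, 1, 0.6), (2, 3, 0.6), (10, 11, 0.6)),
        T=300,
        seed=11,
    )
    return generate_dataset(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
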