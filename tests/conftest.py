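import numpy as np
import pytest
from hypothesis import settings

from hetdti.synthetic import Bundle, SyntheticConfig, generate_dataset, generate_worked_toys

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toys() -> dict:
    return generate_worked_toys()


#: Small, strongly separable bundle for fast end-to-end unit tests.
TINY = SyntheticConfig(
    n_drugs=18,
    n_targets=24,
    n_diseases=30,
    n_side_effects=24,
    n_communities=2,
    p_in=0.5,
    p_out=0.05,
    protein_length_range=(30, 60),
    seed=11,
)


@pytest.fixture(scope="session")
def tiny_bundle() -> Bundle:
    return generate_dataset(TINY)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
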