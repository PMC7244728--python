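import numpy as np
import pytest

from refractml.basis import build_ldhd_transform
from refractml.cohort import (
    CohortParams,
    MechanismWeights,
    NoiseParams,
    apply_exclusions,
    generate_cohort,
)


@pytest.fixture(scope="session")
def transform():
    return build_ldhd_transform(6)


@pytest.fixture(scope="session")
def small_cohort():
    """A few hundred eyes with default mechanism and noise."""
    return apply_exclusions(generate_cohort(CohortParams(n_patients=250, seed=42)))


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Mechanism off, all noise off, no quantization: subjective == paraxial."""
    params = CohortParams(
        n_patients=120,
        seed=7,
        mechanism=MechanismWeights(0.0, 0.0, 0.0),
        noise=NoiseParams(0.0, 0.0, 0.0, 0.0),
    )
    return apply_exclusions(generate_cohort(params))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
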