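import numpy as np
import pytest

from cartinirs import synthetic_data as sd


@pytest.fixture(scope="session")
def dataset530():
    """Full-cohort synthetic dataset at the study's scale (530 points)."""
    return sd.generate_dataset(sd.PhantomSpec(n_points=530, seed=11))


@pytest.fixture(scope="session")
def dataset80():
    """Small dataset for pipeline plumbing tests."""
    return sd.generate_dataset(
        sd.PhantomSpec(n_points=80, grade_mix=(0.55, 0.3, 0.15, 0.0, 0.0), seed=7)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
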