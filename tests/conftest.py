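import numpy as np
import pytest

from gradalign import CohortSpec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_spec():
    """A reduced cohort for fast structural tests (not the study conditions)."""
    return CohortSpec(n_subjects=10, n_parcels=40, n_latent=12, n_frames=120,
                      seed=5)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec)


def random_orthonormal(rng, m, n):
    """Orthonormal m x n matrix from QR of a Gaussian draw."""
    q, _ = np.linalg.qr(rng.standard_normal((m, n)))
    return q
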