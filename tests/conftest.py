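import numpy as np
import pytest

from fcbasis.core import TWO_PI, AngleBasis, FCMatrix, reconstruct


def random_basis(n_bases, n_regions, seed, full_jitter=False):
    rng = np.random.default_rng(seed)
    phases = rng.uniform(0.0, TWO_PI, (n_bases, n_regions))
    if full_jitter:
        jitters = np.ones((n_bases, n_regions))
    else:
        jitters = rng.uniform(0.0, 1.0, (n_bases, n_regions))
    return AngleBasis(phases=phases, jitters=jitters)


def model_fc(basis):
    """FC matrix realized exactly by the angle-basis model (unit diagonal)."""
    m = reconstruct(basis)
    np.fill_diagonal(m, 1.0)
    return FCMatrix(np.clip(m, -1.0, 1.0))


@pytest.fixture(scope="session")
def small_cohort():
    """One moderate synthetic cohort shared across tests (20 subjects x 3 scans)."""
    from fcbasis.synthesis import CohortSpec, generate_cohort

    return generate_cohort(CohortSpec(n_subjects=20, seed=42))


@pytest.fixture(scope="session")
def small_cohort_decompositions(small_cohort):
    from fcbasis.fitting import FitConfig, fit_many

    return fit_many(small_cohort.fc_matrices, FitConfig(seed=7))
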