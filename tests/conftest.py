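import numpy as np
import pytest

import roamind as rm


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def planted_cohort():
    """One homogeneous individuality dimension, n=456, per-bin SNR 1.5."""
    spec = rm.PopulationSpec(n_individuals=456, seed=1)
    structure = rm.IndividualityStructure(
        archetypes=["homogeneous"], strengths=(1.5,), noise_sd=1.0
    )
    matrix, labels, coeffs = rm.generate_roaming_matrix(spec, structure)
    return matrix, labels, coeffs


@pytest.fixture(scope="session")
def scaled_synthetic_trajectory():
    """Five-stage trajectory with lethargus gaps, durations scaled to 20%."""
    params = rm.KinematicParams().scaled(0.2)
    return params, rm.generate_trajectory(params, seed=5)
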