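import numpy as np
import pandas as pd
import pytest

from shockdtr.preprocess import build_feature_matrix
from shockdtr.synthetic import default_profiles, generate_cohort


@pytest.fixture(scope="session")
def big_cohort():
    """n=5000-patient cohort for Monte-Carlo convergence checks."""
    cfg = default_profiles(n_patients=5000, seed=11)
    cohort, truth = generate_cohort(cfg)
    return cfg, cohort, truth


@pytest.fixture(scope="session")
def small_cohort():
    cfg = default_profiles(n_patients=400, seed=23)
    cohort, truth = generate_cohort(cfg)
    return cfg, cohort, truth


@pytest.fixture(scope="session")
def small_matrix(small_cohort):
    _, cohort, _ = small_cohort
    X, _ = build_feature_matrix(cohort)
    return X


def two_cluster_data(n_per: int = 200, d: int = 3, sep: float = 10.0, seed: int = 0):
    """Two spherical Gaussian clusters separated by `sep` pooled SDs."""
    rng = np.random.default_rng(seed)
    a = rng.standard_normal((n_per, d))
    b = rng.standard_normal((n_per, d))
    b[:, 0] += sep
    return np.vstack([a, b])
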