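import numpy as np
import pytest

from dmnaec.bands import ALPHA, DELTA
from dmnaec.cohort import CohortConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort_config():
    """Scaled-down cohort (few subjects, 60 s at 250 Hz) for structural
    and determinism checks; the coupling structure matches the default."""
    return CohortConfig(n_hc=4, n_scd=4, fs=250.0, duration=60.0, seed=11)


def narrowband_pair(r, fs=200.0, duration=300.0, seed=0, band=ALPHA):
    """Two unit-variance narrowband series with latent correlation r,
    built exactly as the cohort generator builds a coupled pair."""
    from dmnaec.cohort import make_narrowband_noise

    ss = np.random.SeedSequence(seed)
    g = np.random.default_rng(ss)
    n1 = make_narrowband_noise(fs, duration, band, g)
    n2 = make_narrowband_noise(fs, duration, band, g)
    s = make_narrowband_noise(fs, duration, band, g)
    x1 = np.sqrt(1 - r) * n1 + np.sqrt(r) * s
    x2 = np.sqrt(1 - r) * n2 + np.sqrt(r) * s
    return x1, x2


def pair_aec(x1, x2, fs, band=ALPHA):
    """AEC of one precoupled pair via the connectivity module."""
    from dmnaec.connectivity import aec_matrix

    return aec_matrix(np.vstack([x1, x2]), band, fs).values[0, 1]
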