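import numpy as np
import pandas as pd
import pytest

from armuse import SimConfig, default_intensity_model, generate_cohort


@pytest.fixture(scope="session")
def intensity():
    return default_intensity_model()


@pytest.fixture(scope="session")
def small_cohort(intensity):
    """Counts-mode cohort of 6 subjects x 300 s (shared, read-only)."""
    config = SimConfig(n_subjects=6, duration_s=300, seed=7)
    profiles, table = generate_cohort(config, intensity)
    return config, profiles, table


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_mixture_counts(rng, n, prevalence, pos, neg):
    """Labelled counts from two zero-inflated log-normal classes."""
    labels = (rng.random(n) < prevalence).astype(int)
    counts = np.empty(n)
    for val, cell in ((1, pos), (0, neg)):
        m = labels == val
        k = int(m.sum())
        zero = rng.random(k) < cell.zero_mass
        counts[m] = np.where(zero, 0.0,
                             rng.lognormal(cell.log_location, cell.log_scale, k))
    return counts, labels
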