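import numpy as np
import pandas as pd
import pytest

import polyrisk as pr
from polyrisk.data import OUTCOMES


@pytest.fixture(scope="session")
def profile():
    return pr.default_profile()


@pytest.fixture(scope="session")
def small_ds(profile):
    """400-case synthetic dataset with all four outcome classes."""
    return pr.generate_synthetic(profile, 400, seed=11)


@pytest.fixture(scope="session")
def split(small_ds):
    return pr.stratified_split(small_ds, 0.71, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_probs(rng, n):
    """Flat-Dirichlet probability rows (continuous, tie-free a.s.)."""
    return pd.DataFrame(rng.dirichlet(np.ones(4), size=n), columns=list(OUTCOMES))


def balanced_labels(per_class):
    return np.repeat(list(OUTCOMES), per_class)
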