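import warnings

import numpy as np
import pytest

from dynfuse import (
    SyntheticDesign,
    make_ground_truth,
)


@pytest.fixture(autouse=True)
def _quiet_convergence_warnings():
    """Graphical-lasso convergence chatter is irrelevant to the assertions."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*graphical_lasso.*")
        warnings.filterwarnings("ignore", message=".*did not converge.*")
        yield


@pytest.fixture(scope="session")
def small_design():
    return SyntheticDesign(
        n_subjects=60,
        n_snps=120,
        n_icns=8,
        n_timepoints=300,
        k_states=3,
        n_components=3,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_truth(small_design):
    return make_ground_truth(small_design)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
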