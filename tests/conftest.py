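import numpy as np
import pytest

from accumulate.fitting import FitConfig, fit_subject
from accumulate.lba import LBAParams, lba_simulate
from accumulate.tasks import NBACK


TRUE_LBA = LBAParams(
    v_match={"target": 2.6, "lure": 1.6, "novel": 2.2},
    v_mismatch={"target": 0.9, "lure": 1.1, "novel": 0.5},
    A=0.5,
    B={"target_resp": 0.9, "nontarget_resp": 0.9},
    t0=0.3,
    p_gf=0.03,
)


@pytest.fixture(scope="session")
def true_lba_params():
    return TRUE_LBA


@pytest.fixture(scope="session")
def nback_dataset():
    """One simulated n-back subject (200 trials/condition) from known truth."""
    return lba_simulate(TRUE_LBA, NBACK, 200, seed=42, subject_id="s1")


@pytest.fixture(scope="session")
def lba_fit(nback_dataset):
    """A short but real LBA fit, shared across test modules."""
    cfg = FitConfig(burn_in=250, block=150, max_iter=300, seed=5)
    return fit_subject(nback_dataset, "lba", cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
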