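import numpy as np
import pytest

from cytoprof import synthetic as syn


@pytest.fixture(scope="session")
def small_cohort():
    """A compact paired two-arm cohort with the default spiked effects."""
    cfg = syn.default_config(seed=11)
    cfg.n_patients_per_arm = {"treated": 8, "control": 8}
    cfg.paired_fraction = {"treated": 1.0, "control": 1.0}
    cfg.n_controls = 4
    cfg.cells_per_sample_mean = 600
    return syn.generate_cohort(cfg)


@pytest.fixture(scope="session")
def hierarchy():
    return syn.default_gating_hierarchy()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
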