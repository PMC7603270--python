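import warnings

import numpy as np
import pandas as pd
import pytest

import immunorad as ir


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully featured synthetic cohort (T1C only)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ir.simulate_cohort(
            ir.SimulationConfig(n_samples=40, seed=7, modalities=("T1C",)))


@pytest.fixture(scope="session")
def nes_table(small_cohort):
    """NES profiles for the small cohort (seeded)."""
    return ir.profile_cohort(small_cohort.expr_rnaseq, small_cohort.catalog,
                             n_permutations=200, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
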