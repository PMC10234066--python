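import numpy as np
import pandas as pd
import pytest

import cgskit as ck


@pytest.fixture(scope="session")
def panel():
    return ck.default_panel()


@pytest.fixture(scope="session")
def small_genotypes(panel):
    return ck.simulate_genotypes(60, panel, seed=101)


@pytest.fixture(scope="session")
def gxe_cohort():
    """Moderately sized cohort under the default crossover truth."""
    g, table = ck.simulate_gxe_cohort(1589, seed=2024)
    return g, table


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_noiseless_gxe(n=400, b0=100.0, b1=-8.0, b2=0.6, c=3.0, seed=5):
    """Deterministic outcome built exactly from the crossover formula."""
    rng = np.random.default_rng(seed)
    pe = rng.choice(np.arange(1, 6.01, 0.5), size=n)
    cgs = rng.binomial(26, 0.5, size=n).astype(float)
    age = rng.uniform(9, 13, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    truth = ck.GxETruth(b0=b0, b1=b1, b2=b2, c=c, b_age=-0.5, b_sex=1.0, resid_sd=0.0)
    y = ck.simulate_gxe_phenotype(cgs, pe, age, sex, truth, seed=0)
    return y, pe, cgs, age, sex, truth
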