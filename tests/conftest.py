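import numpy as np
import pandas as pd
import pytest

from immunocorr import SimConfig, generate_cohort

COV_COLS = ["age", "sex", "bmi", "medication"]


@pytest.fixture(scope="session")
def default_cohort():
    """Study-scale cohort under default conditions (90 HC / 113 FEP, 48 panel)."""
    return generate_cohort(SimConfig(seed=7))


@pytest.fixture(scope="session")
def clean_cohort():
    """Small, complete (no missing), noise-free cohort for exact-path tests."""
    cfg = SimConfig(
        n_hc=60, n_fep=60, n_panel=10, missing_rate=0.0, noise_sd=0.0,
        corr_jitter=0.0, seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def covariates_of(cohort) -> pd.DataFrame:
    return cohort.covariates[COV_COLS]
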