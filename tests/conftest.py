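import numpy as np
import pandas as pd
import pytest

from vitdmr.synthetic_cohort import generate_scenario


@pytest.fixture(scope="session")
def ckb_cohort() -> pd.DataFrame:
    """One moderate East-Asian-style cohort reused across read-only tests."""
    return generate_scenario("ckb_like", 6000, seed=7)


@pytest.fixture(scope="session")
def cgps_cohort() -> pd.DataFrame:
    return generate_scenario("cgps_like", 6000, seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
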