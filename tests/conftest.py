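import numpy as np
import pandas as pd
import pytest

from inflammadjust.synthetic import default_config, generate_survey


@pytest.fixture(scope="session")
def psc_table() -> pd.DataFrame:
    """A realistic PSC survey with the default confounding structure."""
    return generate_survey(default_config("PSC", n=2000, seed=42))


@pytest.fixture(scope="session")
def wra_table() -> pd.DataFrame:
    return generate_survey(default_config("WRA", n=2000, seed=43))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2026)


def correlated_pair(rng, n, rho, loc=(0.0, 0.0), scale=(1.0, 1.0)):
    """Bivariate normal sample with a chosen correlation (test helper)."""
    cov = [[scale[0] ** 2, rho * scale[0] * scale[1]],
           [rho * scale[0] * scale[1], scale[1] ** 2]]
    xy = rng.multivariate_normal(loc, cov, size=n)
    return xy[:, 0], xy[:, 1]
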