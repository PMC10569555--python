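import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from holdoutselect import fixtures

settings.register_profile("repeatable", derandomize=True)
settings.load_profile("repeatable")
from holdoutselect.data_model import PredictorTable, encode_outcome


@pytest.fixture(scope="session")
def swiss_like():
    return fixtures.swiss_like()


@pytest.fixture(scope="session")
def pima_like():
    return fixtures.pima_like()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_linear():
    """Tiny linear dataset with one strong predictor (x1) and one noise column."""
    rng = np.random.default_rng(7)
    x1 = rng.standard_normal(80)
    x2 = rng.standard_normal(80)
    y = 2.0 + 3.0 * x1 + rng.normal(0, 0.5, 80)
    df = pd.DataFrame({"x1": x1, "x2": x2})
    return PredictorTable.from_dataframe(df), encode_outcome(y, "linear")
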