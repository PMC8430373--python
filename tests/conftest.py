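import numpy as np
import pandas as pd
import pytest

from eqcov import SurveyDesign, default_config, default_truth, generate_survey


@pytest.fixture(scope="session")
def design():
    return SurveyDesign()


@pytest.fixture(scope="session")
def truth():
    return default_truth()


@pytest.fixture(scope="session")
def survey(truth):
    """One deterministic 3-country survey at the default desk scale."""
    return generate_survey(default_config(seed=42), truth)


@pytest.fixture()
def srs_frame():
    """Degenerate design: each record its own PSU, one stratum, equal weights."""

    def make(x: np.ndarray) -> pd.DataFrame:
        n = len(x)
        return pd.DataFrame(
            {
                "x": np.asarray(x, dtype=float),
                "stratum_id": 1,
                "psu_id": np.arange(n),
                "weight": 1.0,
            }
        )

    return make
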