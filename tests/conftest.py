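from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from bleedrisk.config import (
    default_config,
    poppk_model_from_config,
    true_models_from_config,
)
from bleedrisk.poppk import PKParameters, PopPKModel
from bleedrisk.regimens import q2w, q3w


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def pk_model(config) -> PopPKModel:
    """The shipped calibrated population model."""
    return poppk_model_from_config(config)


@pytest.fixture(scope="session")
def typical_params(pk_model) -> PKParameters:
    return pk_model.typical


@pytest.fixture(scope="session")
def constant_cl_params() -> PKParameters:
    """A constant-clearance parameter set for closed-form comparisons."""
    return PKParameters(cl_base=0.016, v1=2.4, v2=1.0, q=0.03, cl_emax=0.0)


@pytest.fixture(scope="session")
def true_models(config):
    return true_models_from_config(config)


@pytest.fixture(scope="session")
def reference_covariates(pk_model) -> dict[str, float]:
    """Every model covariate at its reference value (unit factors)."""
    out: dict[str, float] = {}
    for eff in pk_model.covariate_effects:
        out.setdefault(eff.covariate, eff.reference if eff.form == "power" else 0.0)
    return out


@pytest.fixture(scope="session")
def reference_frame(reference_covariates):
    def make(n: int) -> pd.DataFrame:
        return pd.DataFrame(reference_covariates, index=pd.RangeIndex(n))

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def regimen_1200_q2w():
    return q2w(1200.0)


@pytest.fixture(scope="session")
def regimen_1200_q3w():
    return q3w(1200.0)
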