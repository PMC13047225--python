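import warnings

import numpy as np
import pandas as pd
import pytest

from odesurv.likelihood import SurvivalDataset
from odesurv.simulate import scenario_recovery

# noisy but benign numerical warnings (clamped predictors during optimiser
# exploration, SPD repairs) would otherwise drown test output
warnings.filterwarnings("ignore", message=".*clamped.*")


@pytest.fixture(scope="session")
def recovery_replicate():
    """One n=1000 replicate of the hazard-response scenario (~20% censoring)."""
    data, truth = scenario_recovery(1000, arm="cens20", seed=101)
    return data, truth


@pytest.fixture(scope="session")
def small_replicate():
    """A small replicate for cheap smoke tests."""
    data, truth = scenario_recovery(150, arm="cens20", seed=7)
    return data, truth


@pytest.fixture()
def toy_dataset():
    """Three-subject dataset with a single binary covariate."""
    return SurvivalDataset(
        time=np.array([1.0, 2.0, 3.0]),
        delta=np.array([1, 0, 1]),
        X=pd.DataFrame({"x": [0.0, 1.0, 1.0]}),
    )
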