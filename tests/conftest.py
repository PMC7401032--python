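import numpy as np
import pandas as pd
import pytest

from deftmeta import IPDDataset, SynthConfig, generate_ipd


@pytest.fixture(scope="session")
def default_ds():
    """The generator's default conditions: 10 continuous-outcome trials."""
    return generate_ipd(SynthConfig(), seed=2025)


@pytest.fixture(scope="session")
def agreement_ds():
    """Balanced continuous data at the cross-method comparison size."""
    return generate_ipd(SynthConfig(n_per_trial=500), seed=314)


@pytest.fixture()
def toy_trial():
    """One balanced two-arm trial with a binary covariate, no noise."""
    n = 40
    z = np.tile([0.0, 1.0], n // 2)
    x = np.repeat([0.0, 1.0], n // 2)
    # perfectly balanced z within each arm
    z = np.concatenate([np.tile([0, 1], n // 4), np.tile([0, 1], n // 4)]).astype(float)
    return pd.DataFrame({"trial": "A", "arm": x.astype(int), "z": z,
                         "y": 2.0 * x * z})


def make_ipd(df, outcome_type="continuous", covariates=("z",)):
    return IPDDataset(df, outcome_type, list(covariates))
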