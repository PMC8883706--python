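import logging

import numpy as np
import pandas as pd
import pytest

from distreg import GeneratorConfig, ModelSpec, TrialDataset, gen_trial

# fit logging is exercised implicitly; keep test output quiet
logging.getLogger("distreg").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def normal_trial():
    """Small homoscedastic-normal trial with a log-normal baseline."""
    rng = np.random.default_rng(42)
    n = 400
    df = pd.DataFrame({
        "treatment": rng.integers(0, 2, n),
        "baseline": rng.lognormal(np.log(0.65), 0.25, n),
    })
    df["response"] = (0.7 + 0.3 * np.log(df["baseline"])
                      - 0.1 * df["treatment"] + rng.normal(0, 0.15, n))
    return TrialDataset(df)


@pytest.fixture(scope="session")
def bct_trial():
    """One trial generated from the extended Box-Cox-t coefficient set."""
    cfg = GeneratorConfig.from_coefset("mrproadm_extended_bct", n=2000)
    return gen_trial(cfg, seed=101)


@pytest.fixture(scope="session")
def bct_template():
    return ModelSpec(mu=("treatment", "log(baseline)"),
                     sigma=("treatment", "log(baseline)"))
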