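import numpy as np
import pandas as pd
import pytest

import ssbtax as st


@pytest.fixture(scope="session")
def inputs() -> st.ModelInputs:
    """Published parameter set: baseline consumption, elasticities,
    densities, conversion factor, default heights/BMI/pyramid."""
    return st.ModelInputs()


@pytest.fixture(scope="session")
def syn_config() -> st.SyntheticConfig:
    return st.SyntheticConfig(seed=7)


@pytest.fixture(scope="session")
def bmi_survey(syn_config) -> pd.DataFrame:
    return st.generate_bmi_survey(syn_config)


@pytest.fixture(scope="session")
def consumption_records(syn_config) -> pd.DataFrame:
    return st.generate_consumption_survey(syn_config, 20_000)


@pytest.fixture()
def tiny_consumption_records() -> pd.DataFrame:
    """Two 20-year-olds: one daily SSB drinker, one abstainer."""
    return pd.DataFrame({
        "age": [20.0, 21.0],
        "milk_category": ["none", "none"],
        "juice_category": ["none", "none"],
        "ssb_frequency": ["every day", "none"],
    })
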