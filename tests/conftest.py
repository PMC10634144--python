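import pandas as pd
import pytest

from heatmir import synthetic_data as sd


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale study configuration used across integration tests."""
    return sd.SyntheticConfig(seed=7)


@pytest.fixture(scope="session")
def study(small_config):
    return sd.generate_study(small_config)


@pytest.fixture(scope="session")
def library_totals(small_config):
    return pd.Series(
        float(small_config.library_depth), index=small_config.sample_names
    )
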