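import pandas as pd
import pytest
from hypothesis import settings as hypothesis_settings

from ipdflux import design, ipd, synthetic

hypothesis_settings.register_profile(
    "deterministic", derandomize=True, deadline=None, database=None
)
hypothesis_settings.load_profile("deterministic")
from ipdflux.pipeline import analysis_frame


@pytest.fixture(scope="session")
def sampled_design_df() -> pd.DataFrame:
    return design.sampled_design(seed=0)


@pytest.fixture(scope="session")
def default_bundle(sampled_design_df) -> dict:
    """One default synthetic dataset (all pools), shared across tests."""
    return synthetic.generate_dataset(sampled_design_df, seed=11)


@pytest.fixture(scope="session")
def rates_frame(default_bundle) -> pd.DataFrame:
    rates = ipd.estimate_rates_table(default_bundle["ipd_raw"])
    return analysis_frame(
        rates, default_bundle["native_pools"], default_bundle["covariates"]
    )
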