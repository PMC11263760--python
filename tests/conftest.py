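import numpy as np
import pandas as pd
import pytest

from akiwatch import AkiCriteria, SiteSimConfig, generate_site


@pytest.fixture(scope="session")
def small_bundle():
    """A compact single-drug site used by several modules' tests."""
    cfg = SiteSimConfig(site_id="SH", n_patients=220, seed=11,
                        drug_mix={"vancomycin": 1.0}, aki_frac=0.3)
    return generate_site(cfg)


@pytest.fixture(scope="session")
def small_cohort(small_bundle):
    from akiwatch import apply_eligibility

    return apply_eligibility(small_bundle, "vancomycin", AkiCriteria())


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def scr_series(days, values, origin="2015-06-01"):
    """Date-indexed SCr series at day offsets from an origin date."""
    origin = pd.Timestamp(origin)
    idx = origin + pd.to_timedelta(list(days), unit="D")
    return pd.Series(list(values), index=idx), origin
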