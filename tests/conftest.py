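import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from themeclust.data_io import IndicatorTable, ThemeSpec, load_membership_fixture
from themeclust.synthetic import SyntheticConfig, generate

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture():
    """The packaged three-theme cluster membership lists."""
    return load_membership_fixture()


@pytest.fixture(scope="session")
def worst_sets(fixture):
    """The three highest-risk (label 3) membership sets."""
    return {t: fixture.cluster(t, 3) for t in ("NAD", "HAD", "HALE")}


@pytest.fixture
def toy_table():
    """A tiny two-theme table with one missing cell."""
    values = pd.DataFrame(
        {
            "a1": [1.0, 2.0, 3.0, 4.0],
            "a2": [10.0, 20.0, np.nan, 40.0],
            "b1": [5.0, 5.0, 6.0, 7.0],
        },
        index=pd.Index(["Togo", "Benin", "Ghana", "Mali"], name="country"),
    )
    themes = (ThemeSpec("A", ("a1", "a2")), ThemeSpec("B", ("b1",)))
    return IndicatorTable(values=values, themes=themes)


@pytest.fixture(scope="session")
def planted_dataset():
    """A well-separated synthetic dataset with full cross-theme concordance."""
    return generate(
        SyntheticConfig(n_countries=150, tier_separation=6.0, discordance=0.0, seed=42)
    )
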