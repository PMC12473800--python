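import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from sedrisk.reference_data import (
    builtin_dose_response,
    builtin_exposure_profiles,
    builtin_references,
    builtin_toxic_response_factors,
)
from sedrisk.sample_io import SampleTable
from sedrisk.synthetic_data import default_cunas_spec, generate, generate_worked_fixture

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def ucc():
    """Taylor & McLennan upper-continental-crust baseline."""
    return builtin_references()[0]


@pytest.fixture(scope="session")
def shale():
    """Turekian & Wedepohl average-shale baseline."""
    return builtin_references()[1]


@pytest.fixture(scope="session")
def toxicity():
    return builtin_toxic_response_factors()


@pytest.fixture(scope="session")
def profiles():
    child, adult = builtin_exposure_profiles()
    return {"child": child, "adult": adult}


@pytest.fixture(scope="session")
def adult(profiles):
    return profiles["adult"]


@pytest.fixture(scope="session")
def dose_response():
    return builtin_dose_response()


@pytest.fixture(scope="session")
def survey():
    """A seeded synthetic survey: 6 sites x 2 months x 2 replicates."""
    return generate(default_cunas_spec(replicates_per_site=2, seed=123))


@pytest.fixture()
def worked_table():
    return generate_worked_fixture()


def make_table(rows) -> SampleTable:
    """Helper: build a SampleTable from (site, zone, {element: value}) rows."""
    records = []
    for i, (site, zone, conc) in enumerate(rows):
        records.append(
            {"site": site, "zone": zone, "month": "February", "replicate": 1, **conc}
        )
    return SampleTable(pd.DataFrame(records))
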