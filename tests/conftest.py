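import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# Projected test CRSs: one meter-based (built-in EPSG) and one foot-based WKT.
METER_CRS = "EPSG:32616"
FOOT_CRS = (
    'PROJCS["Local foot grid",GEOGCS["WGS 84",DATUM["WGS_1984",'
    'SPHEROID["WGS 84",6378137,298.257223563]],PRIMEM["Greenwich",0],'
    'UNIT["degree",0.0174532925199433]],'
    'PROJECTION["Transverse_Mercator"],UNIT["foot",0.3048]]'
)


@pytest.fixture
def yield_trial_case():
    from plotgrid.examples import yield_trial

    return yield_trial()


@pytest.fixture
def nursery_cases():
    from plotgrid.examples import plant_row_nurseries

    return plant_row_nurseries()


@pytest.fixture
def foot_crs():
    return FOOT_CRS


@pytest.fixture
def meter_crs():
    return METER_CRS
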