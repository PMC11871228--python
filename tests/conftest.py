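import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from plumemix import StationRecord, bundled_endmembers
from plumemix.synthetic_data import ScenarioConfig, generate_cruise

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def spring_ems():
    return bundled_endmembers("spring")


@pytest.fixture(scope="session")
def summer_ems():
    return bundled_endmembers("summer")


@pytest.fixture(scope="session")
def spring_cruise():
    """One default synthetic spring cruise (stations, truth), seed 1."""
    return generate_cruise(ScenarioConfig(season="spring", seed=1))


def frame_to_records(df):
    return [StationRecord(**row._asdict()) for row in df.itertuples(index=False)]


@pytest.fixture(scope="session")
def spring_records(spring_cruise):
    return frame_to_records(spring_cruise[0])


def random_simplex(rng, n=1):
    """Uniform points on the 3-simplex."""
    x = rng.dirichlet(np.ones(3), size=n)
    return x[0] if n == 1 else x
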