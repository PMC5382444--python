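import numpy as np
import pandas as pd
import pytest

from ozsesmod import SimulationConfig, generate_study


def make_config(**overrides) -> SimulationConfig:
    """A small three-city configuration used across tests (1 year, 20 ZCTAs)."""
    base = dict(
        cities=("A", "B", "C"),
        zctas_per_city=(20, 20, 20),
        study_periods={
            "A": ("2002-01-01", "2002-12-31"),
            "B": ("2002-01-01", "2002-12-31"),
            "C": ("2002-01-01", "2002-12-31"),
        },
        seed=1234,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def tiny_study():
    return generate_study(make_config())


@pytest.fixture
def rng():
    return np.random.default_rng(99)


def city_exposure(study, city):
    """Build the ExposureSeries of one city of a generated study."""
    from ozsesmod import build_exposure_series

    field = study.exposure_grid[study.exposure_grid["cell"].str.startswith(city)]
    ov = study.overlap[study.overlap["cell"].str.startswith(city)]
    met = study.met[study.met["city"] == city]
    return build_exposure_series(field, ov, met)
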