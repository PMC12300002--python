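import datetime as dt

import pytest

from herdtk import (
    FarmScenario,
    FeedLot,
    Field,
    GrowthParams,
    IntakeParams,
    LactationParams,
    SynthSpec,
    TransferParams,
    default_tk_params,
    generate_farm,
)
from herdtk.scenario_io import (
    FeedingInterval,
    LifeHistory,
    SimulationSettings,
    WaterExposure,
    WaterSegment,
    WeatherSeries,
)
from herdtk.synthetic_data import _synthetic_weather

import numpy as np


@pytest.fixture(scope="session")
def default_spec() -> SynthSpec:
    return SynthSpec(seed=11)


@pytest.fixture(scope="session")
def default_scenario(default_spec) -> FarmScenario:
    return generate_farm(default_spec)


def make_minimal_scenario(soil_pfos: float = 10.0, tf: float = 0.1) -> FarmScenario:
    """One hay field, one non-nursing animal, one 365-day stored-feed year."""
    birth = dt.date(2020, 1, 1)
    end = dt.date(2020, 12, 30)
    lh = LifeHistory(
        birth_date=birth,
        weaning_date=birth,
        end_date=end,
        intervals=[FeedingInterval(start=birth, end=end, mode="stored", crop_year=2019)],
    )
    rng = np.random.default_rng(0)
    return FarmScenario(
        analytes=["PFOS"],
        fields=[
            Field(field_id="F1", acres=10.0, use="hay", soil_conc={"PFOS": soil_pfos})
        ],
        feed_lots=[
            FeedLot(lot_id="L1", field_id="F1", harvest_year=2019, cut=1, bale_count=100)
        ],
        grazing=[],
        water=WaterExposure(
            segments=[WaterSegment(start=birth, end=end, conc={"PFOS": 1.3})]
        ),
        weather=_synthetic_weather(birth, end, rng),
        life_history=lh,
        transfer_params=TransferParams(tf={"PFOS": tf}),
        tk_params=default_tk_params(),
        growth_params=GrowthParams(),
        lactation_params=LactationParams(),
        intake_params=IntakeParams(),
        settings=SimulationSettings(n_draws=5, seed=0),
    )


@pytest.fixture()
def minimal_scenario() -> FarmScenario:
    return make_minimal_scenario()
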