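"""Synthetic farm scenarios with known ground truth.

The generator emulates a self-contained northern-New-England beef farm
whose hay land carries legacy biosolids contamination while its pastures
do not: a several-fold spread of per-field soil levels (PFOS ~8-20 ng/g
and PFDA ~65-111 ng/g on biosolids fields; pastures below ~1 and ~3 ng/g
with values under the detection limit reported as 0), an annual calendar
alternating roughly six months of stored-feed winters with six months of
grazing summers, calving in early June, weaning in November, and either
slaughter at ~24 months or live sale at ~18 months.  Soil heterogeneity is
lognormal within each field class; measurement noise on biomonitoring is
multiplicative lognormal.  Everything is driven by one seed.
"""

from __future__ import annotations

import datetime as dt
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field as PField

from .datasets import default_tk_params
from .feed_exposure import TransferParams
from .intake_physiology import GrowthParams, IntakeParams, LactationParams
from .poptk import TKParams, mean_draw, simulate_animal
from .scenario_io import (
    FarmScenario,
    FeedLot,
    FeedingInterval,
    Field,
    GrazingInterval,
    LifeHistory,
    SimulationSettings,
    WaterExposure,
    WaterSegment,
    WeatherSeries,
    write_scenario,
)

__all__ = [
    "SynthSpec",
    "generate_farm",
    "generate_biomonitoring",
    "accumulation_depuration_template",
    "depuration_study",
]

# farm season boundaries (month, day)
GRAZING_START = (5, 15)
GRAZING_END = (10, 31)


class SynthSpec(BaseModel):
    """Declarative description of the synthetic farm."""

    model_config = ConfigDict(arbitrary_types_allowed=True)

    seed: int = 0
    analytes: list[str] = PField(default_factory=lambda: ["PFOS", "PFDA"])
    n_biosolids_hay_fields: int = PField(default=7, ge=1)
    n_pasture_fields: int = PField(default=6, ge=1)
    include_dual_field: bool = True  # a biosolids hay field also grazed in fall
    fall_grazing_on_dual_field: bool = False  # 6-week fall rotation, off by default
    soil_range_biosolids: dict[str, tuple[float, float]] = PField(
        default_factory=lambda: {"PFOS": (8.2, 19.8), "PFDA": (65.2, 111.0)}
    )
    soil_range_clean: dict[str, tuple[float, float]] = PField(
        default_factory=lambda: {"PFOS": (0.0, 1.0), "PFDA": (0.0, 2.8)}
    )
    soil_mdl: dict[str, float] = PField(
        default_factory=lambda: {"PFOS": 0.2, "PFDA": 0.1}
    )
    tf: dict[str, float] = PField(default_factory=lambda: {"PFOS": 0.1, "PFDA": 0.022})
    second_cut_multiplier: dict[str, float] = PField(
        default_factory=lambda: {"PFOS": 2.7, "PFDA": 2.1}
    )
    bales_per_acre: float = PField(default=25.0, gt=0)
    second_cut_share: float = PField(default=0.10, ge=0, lt=1)
    n_second_cut_fields: int = PField(default=2, ge=0)
    water_conc: dict[str, float] = PField(
        default_factory=lambda: {"PFOS": 1.3, "PFDA": 0.0}
    )
    filter_date: dt.date = dt.date(2022, 2, 1)
    birth_date: dt.date = dt.date(2020, 6, 1)
    lifespan_months: int = PField(default=24)
    dam_age_years: int = PField(default=5, ge=2)
    true_tk: Optional[dict[str, TKParams]] = None
    maternal_transfer: float = 0.5
    intake_cv: float = PField(default=0.30, ge=0)
    n_draws: int = PField(default=100, ge=1)
    noise_cv: float = PField(default=0.10, ge=0)

    def tk(self) -> dict[str, TKParams]:
        return self.true_tk or default_tk_params(self.maternal_transfer)


def _season_date(year: int, md: tuple[int, int]) -> dt.date:
    return dt.date(year, *md)


def accumulation_depuration_template(
    birth_date: dt.date, months: int = 24, weaning_date: dt.date | None = None
) -> LifeHistory:
    """Life history following the farm's annual calendar.

    Summer grazing from birth through October, weaning on 1 November,
    stored feed through mid-May, then alternating seasons.  ``months=24``
    ends with slaughter on 30 April after the second winter (exactly two
    stored-feed winters); ``months=18`` ends with live sale on 31 October
    after the second summer (one winter).
    """
    if months == 24:
        end = dt.date(birth_date.year + 2, 4, 30)
    elif months == 18:
        end = _season_date(birth_date.year + 1, GRAZING_END)
    else:
        raise ValueError("lifespan template supports 18 or 24 months")
    if weaning_date is None:
        weaning_date = dt.date(birth_date.year, 11, 1)
    if not (birth_date < weaning_date <= end):
        raise ValueError("weaning date must fall between birth and endpoint")

    intervals = []
    cursor = birth_date
    while cursor <= end:
        year = cursor.year
        g_end = _season_date(year, GRAZING_END)
        if cursor <= g_end and cursor >= _season_date(year, GRAZING_START) or cursor == birth_date:
            stop = min(g_end, end)
            intervals.append(FeedingInterval(start=cursor, end=stop, mode="pasture"))
            cursor = stop + dt.timedelta(days=1)
        else:
            stop = min(dt.date(year + 1 if cursor.month >= 7 else year, 5, 14), end)
            intervals.append(
                FeedingInterval(start=cursor, end=stop, mode="stored")
            )
            cursor = stop + dt.timedelta(days=1)
    return LifeHistory(
        birth_date=birth_date, weaning_date=weaning_date, end_date=end, intervals=intervals
    )


def _adult_life_history(birth_date: dt.date, end: dt.date) -> LifeHistory:
    """Breeding-stock calendar: same seasons, no nursing phase."""
    intervals = []
    cursor = birth_date
    while cursor <= end:
        year = cursor.year
        g_end = _season_date(year, GRAZING_END)
        if (
            _season_date(year, GRAZING_START) <= cursor <= g_end
            or cursor == birth_date
        ):
            stop = min(g_end, end)
            intervals.append(FeedingInterval(start=cursor, end=stop, mode="pasture"))
        else:
            stop = min(dt.date(year + 1 if cursor.month >= 7 else year, 5, 14), end)
            intervals.append(FeedingInterval(start=cursor, end=stop, mode="stored"))
        cursor = stop + dt.timedelta(days=1)
    return LifeHistory(
        birth_date=birth_date, weaning_date=birth_date, end_date=end, intervals=intervals
    )


def _draw_soil(rng: np.random.Generator, lo: float, hi: float, mdl: float) -> float:
    """Lognormal soil draw confined to [lo, hi]; values below the MDL are 0."""
    if lo > 0:
        median, sigma = float(np.sqrt(lo * hi)), 0.35
    else:  # non-detect-prone class: centre low with a wide spread
        median, sigma = 0.35 * hi, 0.6
    for _ in range(200):
        v = float(median * np.exp(rng.normal(0.0, sigma)))
        if lo <= v <= hi:
            break
    else:
        v = float(np.clip(v, lo, hi))
    return 0.0 if v < mdl else round(v, 2)


def _synthetic_weather(start: dt.date, end: dt.date, rng: np.random.Generator) -> WeatherSeries:
    idx = pd.date_range(start, end, freq="D")
    doy = idx.dayofyear.to_numpy()
    tmean = 7.0 - 14.0 * np.cos(2 * np.pi * (doy - 15) / 365.25) + rng.normal(0, 3.0, len(idx))
    precip = rng.gamma(0.8, 4.0, len(idx)).round(1)
    frame = pd.DataFrame({"tmean_c": tmean.round(1), "precip_mm": precip}, index=idx)
    return WeatherSeries(frame=frame)


def generate_farm(spec: SynthSpec, out_dir=None) -> FarmScenario:
    """Build (and optionally write) a complete validated farm scenario."""
    rng = np.random.default_rng(spec.seed)

    fields: list[Field] = []
    fid = 1
    for _ in range(spec.n_biosolids_hay_fields):
        soil = {
            a: _draw_soil(rng, *spec.soil_range_biosolids[a], spec.soil_mdl[a])
            for a in spec.analytes
        }
        fields.append(
            Field(
                field_id=f"F{fid}",
                acres=float(rng.integers(5, 21)),
                use="hay",
                soil_conc=soil,
                biosolids_history=True,
            )
        )
        fid += 1
    dual_id = None
    if spec.include_dual_field:
        soil = {
            a: _draw_soil(rng, *spec.soil_range_biosolids[a], spec.soil_mdl[a])
            for a in spec.analytes
        }
        dual_id = f"F{fid}"
        fields.append(
            Field(field_id=dual_id, acres=14.0, use="dual", soil_conc=soil, biosolids_history=True)
        )
        fid += 1
    pasture_ids = []
    for _ in range(spec.n_pasture_fields):
        soil = {
            a: _draw_soil(rng, *spec.soil_range_clean[a], spec.soil_mdl[a])
            for a in spec.analytes
        }
        pid = f"F{fid}"
        pasture_ids.append(pid)
        fields.append(
            Field(field_id=pid, acres=float(rng.integers(5, 26)), use="pasture", soil_conc=soil)
        )
        fid += 1

    calf = accumulation_depuration_template(spec.birth_date, spec.lifespan_months)
    dam_birth = dt.date(spec.birth_date.year - spec.dam_age_years, 6, 1)
    dam = _adult_life_history(dam_birth, calf.end_date)

    crop_years = range(dam_birth.year, calf.end_date.year + 1)
    hay_fields = [f for f in fields if f.use in ("hay", "dual")]
    second_cut_fields = hay_fields[: spec.n_second_cut_fields]
    lots: list[FeedLot] = []
    for year in crop_years:
        for f in hay_fields:
            bales = int(round(f.acres * spec.bales_per_acre))
            second = (
                int(round(bales * spec.second_cut_share))
                if f in second_cut_fields
                else 0
            )
            lots.append(
                FeedLot(
                    lot_id=f"{f.field_id}-{year}-c1",
                    field_id=f.field_id,
                    harvest_year=year,
                    cut=1,
                    bale_count=bales - second,
                )
            )
            if second:
                lots.append(
                    FeedLot(
                        lot_id=f"{f.field_id}-{year}-c2",
                        field_id=f.field_id,
                        harvest_year=year,
                        cut=2,
                        bale_count=second,
                    )
                )

    total_pasture_acres = sum(
        f.acres for f in fields if f.field_id in pasture_ids
    )
    allocation = {
        pid: round(
            next(f.acres for f in fields if f.field_id == pid) / total_pasture_acres, 6
        )
        for pid in pasture_ids
    }
    # normalise rounding drift
    drift = 1.0 - sum(allocation.values())
    allocation[pasture_ids[0]] = round(allocation[pasture_ids[0]] + drift, 6)

    grazing: list[GrazingInterval] = []
    for year in range(dam_birth.year, calf.end_date.year + 1):
        start = _season_date(year, GRAZING_START)
        end = _season_date(year, GRAZING_END)
        if start > calf.end_date:
            break
        grazing.append(GrazingInterval(start=start, end=end, allocation=allocation))
    if spec.fall_grazing_on_dual_field and dual_id is not None:
        grazing.append(
            GrazingInterval(
                start=dt.date(spec.birth_date.year, 9, 15),
                end=dt.date(spec.birth_date.year, 10, 31),
                allocation={dual_id: 1.0},
            )
        )

    wx_start = dt.date(dam_birth.year, 1, 1)
    wx_end = dt.date(calf.end_date.year, 12, 31)
    water_segments = []
    if spec.filter_date > wx_start:
        water_segments.append(
            WaterSegment(
                start=wx_start,
                end=min(spec.filter_date - dt.timedelta(days=1), wx_end),
                conc=dict(spec.water_conc),
            )
        )
    if spec.filter_date <= wx_end:
        water_segments.append(
            WaterSegment(
                start=max(spec.filter_date, wx_start),
                end=wx_end,
                conc={a: 0.0 for a in spec.analytes},
            )
        )

    scenario = FarmScenario(
        analytes=list(spec.analytes),
        fields=fields,
        feed_lots=lots,
        grazing=grazing,
        water=WaterExposure(segments=water_segments),
        weather=_synthetic_weather(wx_start, wx_end, rng),
        life_history=calf,
        dam_life_history=dam,
        transfer_params=TransferParams(
            tf=dict(spec.tf), second_cut_multiplier=dict(spec.second_cut_multiplier)
        ),
        tk_params=spec.tk(),
        growth_params=GrowthParams(),
        lactation_params=LactationParams(),
        intake_params=IntakeParams(intake_cv=spec.intake_cv),
        settings=SimulationSettings(
            n_draws=spec.n_draws, seed=spec.seed, intake_cv=spec.intake_cv
        ),
    )
    if out_dir is not None:
        write_scenario(scenario, out_dir)
    return scenario


def generate_biomonitoring(
    scenario: FarmScenario,
    sampling_dates: list[dt.date],
    n_animals: int = 8,
    noise_cv: float = 0.10,
    seed: int = 0,
    analytes: list[str] | None = None,
    matrices: tuple[str, ...] = ("serum", "muscle"),
    true_params: dict[str, TKParams] | None = None,
) -> pd.DataFrame:
    """Lognormal-noised biomonitoring records around the known-parameter
    deterministic trajectory.

    Each animal shares the mean-parameter trajectory (muscle is exactly
    PM x serum before noising) and receives independent multiplicative
    lognormal noise with unit mean and coefficient of variation
    ``noise_cv`` per record.
    """
    from .dose_engine import build_dam_milk_series

    rng = np.random.default_rng(seed)
    params = true_params or scenario.tk_params
    analytes = analytes or scenario.analytes
    sigma = float(np.sqrt(np.log1p(noise_cv**2)))
    lh = scenario.life_history
    for d in sampling_dates:
        if not (lh.birth_date <= d <= lh.end_date):
            raise ValueError(f"sampling date {d} outside the simulated life history")

    rows = []
    for analyte in analytes:
        draw = mean_draw(params[analyte])
        milk_conc = None
        if lh.weaning_date > lh.birth_date:
            milk_conc = build_dam_milk_series(scenario, analyte)["milk_ng_ml"]
        traj = simulate_animal(scenario, analyte, draw, milk_conc=milk_conc)
        for d in sampling_dates:
            day = traj.loc[pd.Timestamp(d)]
            truth = {"serum": day["serum_ng_ml"], "muscle": day["muscle_ng_g"]}
            for animal in range(1, n_animals + 1):
                for matrix in matrices:
                    noise = (
                        float(np.exp(rng.normal(-0.5 * sigma**2, sigma)))
                        if noise_cv > 0
                        else 1.0
                    )
                    rows.append(
                        {
                            "animal_id": f"A{animal:02d}",
                            "date": d,
                            "matrix": matrix,
                            "analyte": analyte,
                            "conc": truth[matrix] * noise,
                        }
                    )
    return pd.DataFrame(rows)


def depuration_study(
    spec: SynthSpec | None = None,
    n_animals: int = 8,
    n_timepoints: int = 5,
    spacing_days: int = 28,
    noise_cv: float = 0.10,
    seed: int = 0,
    analyte: str = "PFOS",
) -> tuple[pd.DataFrame, FarmScenario, list[dt.date]]:
    """A clean-feed depuration experiment with known kinetics.

    The default 24-month scenario is modified so the second winter switches
    to uncontaminated purchased feed on 1 January (a zero-dose phase: the
    well is filtered from the same date), and adult-aged animals are
    serially sampled through the clean window.  Returns the noised serum
    records, the scenario, and the sampling dates.
    """
    spec = spec or SynthSpec()
    spec = spec.model_copy(deep=True)
    clean_start = dt.date(spec.birth_date.year + 2, 1, 1)
    spec.filter_date = min(spec.filter_date, clean_start)
    scenario = generate_farm(spec)

    lh = scenario.life_history
    new_intervals = []
    for iv in lh.intervals:
        if iv.mode == "stored" and iv.start < clean_start <= iv.end:
            new_intervals.append(
                FeedingInterval(
                    start=iv.start, end=clean_start - dt.timedelta(days=1), mode="stored"
                )
            )
            new_intervals.append(
                FeedingInterval(start=clean_start, end=iv.end, mode="clean")
            )
        else:
            new_intervals.append(iv)
    scenario = scenario.model_copy(
        update={
            "life_history": LifeHistory(
                birth_date=lh.birth_date,
                weaning_date=lh.weaning_date,
                end_date=lh.end_date,
                intervals=new_intervals,
            )
        }
    )
    dates = [clean_start + dt.timedelta(days=spacing_days * i) for i in range(n_timepoints)]
    records = generate_biomonitoring(
        scenario,
        dates,
        n_animals=n_animals,
        noise_cv=noise_cv,
        seed=seed,
        analytes=[analyte],
        matrices=("serum",),
    )
    return records, scenario, dates
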