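"""Body weight, dry-matter intake, water intake and soil ingestion.

Growth follows a Brody curve, BW(t) = W_inf - (W_inf - W_0) e^{-kt}; any
monotone curve approaching the mature weight would serve, and the form is a
declared modelling choice (the underlying study cites but does not print
its growth equations).  Milk yield of the dam follows a Wood lactation
curve adjusted for breed peak yield:

    MY(t) = A (t+14)^b exp(-c (t+14)) YP / 10      [kg milk/day]

with defaults (A=1.69, b=0.57, c=0.009/day, YP=8.16 kg/day) placing peak
yield near day 48 post calving.  A nursing calf's forage intake balances
its milk intake against its energy demand,

    DMI_F = max(0, (0.0783 BW - 4.87 DMI_M) / DE_F)   [kg dw/day]

where DMI_M is milk dry-matter intake (milk is 13 % dry matter) and DE_F
the forage digestible energy (2.895 Mcal/kg).  After weaning, dry-matter
intake defaults to a fixed fraction of body weight.  Incidental soil
ingestion while grazing is a fixed fraction (4 %) of forage dry-matter
intake.
"""

from __future__ import annotations

from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field as PField, model_validator

if TYPE_CHECKING:  # pragma: no cover
    from .scenario_io import FarmScenario, LifeHistory

__all__ = [
    "GrowthParams",
    "LactationParams",
    "IntakeParams",
    "body_weight",
    "milk_yield",
    "calf_milk_dmi",
    "calf_forage_dmi",
    "post_weaning_dmi",
    "water_intake",
    "soil_ingestion",
    "build_body_states",
]


class GrowthParams(BaseModel):
    birth_weight_kg: float = PField(default=40.0, gt=0)
    mature_weight_kg: float = PField(default=600.0, gt=0)
    rate_per_day: float = PField(default=0.004, gt=0)
    form: str = "brody"

    @model_validator(mode="after")
    def _check(self) -> "GrowthParams":
        if self.birth_weight_kg >= self.mature_weight_kg:
            raise ValueError("birth weight must be below mature weight")
        if self.form != "brody":
            raise ValueError(f"unknown growth-curve form {self.form!r}")
        return self


class LactationParams(BaseModel):
    peak_yield_kg_day: float = PField(default=8.16, gt=0)  # YP, breed-adjusted
    wood_a: float = PField(default=1.69, gt=0)
    wood_b: float = PField(default=0.57, gt=0)
    wood_c_per_day: float = PField(default=0.009, gt=0)
    milk_dm_fraction: float = PField(default=0.13, gt=0, le=1)

    @model_validator(mode="after")
    def _check(self) -> "LactationParams":
        peak_day = self.wood_b / self.wood_c_per_day - 14.0
        if not (0 < peak_day < 365):
            raise ValueError(f"implied lactation peak day {peak_day:.1f} outside (0, 365)")
        return self


class IntakeParams(BaseModel):
    de_forage_mcal_kg: float = PField(default=2.895, gt=0)
    dmi_fraction_of_bw: float = PField(default=0.025, ge=0)
    water_l_per_kg_bw: float = PField(default=0.08, ge=0)
    water_temp_coeff_l_per_c: float = PField(default=0.0, ge=0)
    water_temp_ref_c: float = 15.0
    soil_ingestion_fraction: float = PField(default=0.04, ge=0, le=0.2)
    intake_cv: float = PField(default=0.30, ge=0)


def body_weight(age_days, params: GrowthParams):
    """Brody body weight (kg) at a given age in days (scalar or array)."""
    t = np.asarray(age_days, dtype=float)
    w0, winf, k = params.birth_weight_kg, params.mature_weight_kg, params.rate_per_day
    bw = winf - (winf - w0) * np.exp(-k * t)
    return float(bw) if np.isscalar(age_days) else bw


def milk_yield(t_days_post_calving, params: LactationParams):
    """Wood-curve dam milk yield (kg/day) at t days post calving."""
    t = np.asarray(t_days_post_calving, dtype=float)
    a, b, c, yp = (
        params.wood_a,
        params.wood_b,
        params.wood_c_per_day,
        params.peak_yield_kg_day,
    )
    my = a * (t + 14.0) ** b * np.exp(-c * (t + 14.0)) * yp / 10.0
    return float(my) if np.isscalar(t_days_post_calving) else my


def calf_milk_dmi(milk_kg_day, milk_dm_fraction: float = 0.13):
    """Milk dry-matter intake (kg dw/day) from whole-milk intake."""
    return milk_kg_day * milk_dm_fraction


def calf_forage_dmi(bw_kg, dmi_milk, de_forage: float = 2.895):
    """Nursing-calf forage intake (kg dw/day), clamped at 0."""
    raw = (0.0783 * np.asarray(bw_kg, dtype=float) - 4.87 * np.asarray(dmi_milk, dtype=float)) / de_forage
    out = np.maximum(raw, 0.0)
    return float(out) if np.isscalar(bw_kg) and np.isscalar(dmi_milk) else out


def post_weaning_dmi(bw_kg, fraction: float = 0.025):
    """Post-weaning dry-matter intake (kg dw/day), proportional to BW."""
    return np.asarray(bw_kg, dtype=float) * fraction if not np.isscalar(bw_kg) else bw_kg * fraction


def water_intake(bw_kg, tmean_c, params: IntakeParams):
    """Drinking-water intake (L/day): affine in BW with an optional warm-
    weather term above the reference temperature."""
    base = params.water_l_per_kg_bw * np.asarray(bw_kg, dtype=float)
    warm = params.water_temp_coeff_l_per_c * np.maximum(
        0.0, np.asarray(tmean_c, dtype=float) - params.water_temp_ref_c
    )
    out = base + warm
    return float(out) if np.isscalar(bw_kg) and np.isscalar(tmean_c) else out


def soil_ingestion(dmi_forage_grazing, fraction: float = 0.04):
    """Incidental soil ingestion (kg/day) while grazing."""
    return dmi_forage_grazing * fraction


def build_body_states(
    scenario: "FarmScenario", life_history: "LifeHistory | None" = None
) -> pd.DataFrame:
    """Per-day physiological state for one animal.

    Columns: bw_kg, dmi_milk_kg, dmi_forage_kg, water_l, soil_kg, grazing,
    mode.  ``dmi_forage_kg`` is the total non-milk dry-matter intake and
    applies to pasture forage on grazing days and to stored/clean feed
    otherwise.  Milk intake is zero from the weaning date onward (hard
    switch); soil ingestion occurs only on grazing days.
    """
    lh = life_history if life_history is not None else scenario.life_history
    gp, lp, ip = scenario.growth_params, scenario.lactation_params, scenario.intake_params
    dates = lh.dates
    age = np.arange(len(dates), dtype=float)
    bw = body_weight(age, gp)

    mode = lh.mode_series().to_numpy()
    nursing = dates < pd.Timestamp(lh.weaning_date)

    my = milk_yield(age, lp)
    dmi_milk = np.where(nursing, calf_milk_dmi(my, lp.milk_dm_fraction), 0.0)
    milk_kg = np.where(nursing, my, 0.0)

    dmi_forage = np.where(
        nursing,
        calf_forage_dmi(bw, dmi_milk, ip.de_forage_mcal_kg),
        post_weaning_dmi(bw, ip.dmi_fraction_of_bw),
    )

    wx = scenario.weather.frame["tmean_c"].reindex(dates).to_numpy()
    water = water_intake(bw, wx, ip)

    grazing = np.isin(mode, ("pasture", "supplemental"))
    soil = np.where(grazing, soil_ingestion(dmi_forage, ip.soil_ingestion_fraction), 0.0)

    return pd.DataFrame(
        {
            "bw_kg": bw,
            "milk_kg": milk_kg,
            "dmi_milk_kg": dmi_milk,
            "dmi_forage_kg": dmi_forage,
            "water_l": water,
            "soil_kg": soil,
            "grazing": grazing,
            "mode": mode,
        },
        index=dates,
    )
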