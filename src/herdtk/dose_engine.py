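"""Per-day absorbed dose assembly (ng/day) by exposure pathway.

Each simulated day's total dose is the sum of five components:

    dose_feed    = feed_conc [ng/g]   x stored-feed DMI [kg] x 1000
    dose_pasture = forage_conc [ng/g] x grazing DMI [kg]     x 1000
    dose_soil    = soil_conc [ng/g]   x soil ingested [kg]   x 1000
    dose_water   = water_conc [ng/L]  x water intake [L]
    dose_milk    = milk_conc [ng/mL]  x milk intake [kg]     x 1000

(1 ng/mL milk is treated as 1 ng/g on a mass basis, kg ~ L.)  The absorbed
dose equals the administered dose: the one-compartment description carries
no bioavailability term.  Between-animal intake variability enters as one
multiplicative factor per animal for all ingesta (feed, pasture, soil,
milk) and one for water, drawn from a truncated normal with mean 1.
"""

from __future__ import annotations

from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .feed_exposure import feed_conc_timeline, pasture_forage_conc

if TYPE_CHECKING:  # pragma: no cover
    from .scenario_io import FarmScenario, LifeHistory

__all__ = [
    "build_exposure_frame",
    "build_dose_series",
    "daily_dose",
    "intake_perturbation",
    "build_dam_milk_series",
    "DOSE_COMPONENTS",
]

DOSE_COMPONENTS = ("dose_feed", "dose_pasture", "dose_soil", "dose_water", "dose_milk")


class PathwayError(ValueError):
    """A concentration needed on an active exposure pathway is missing."""


def build_exposure_frame(
    scenario: "FarmScenario",
    analyte: str,
    life_history: "LifeHistory | None" = None,
    feed_conc: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-day concentrations on every pathway for one animal.

    Columns: feed_conc (ng/g, stored/clean/supplemental days), pasture_conc
    (ng/g), soil_conc (ng/g, grazing-allocation-weighted), water_ngL.
    ``feed_conc`` overrides the computed stored-feed timeline (used by
    management feed plans).
    """
    lh = life_history if life_history is not None else scenario.life_history
    dates = lh.dates
    mode = lh.mode_series()

    feed = (
        feed_conc.reindex(dates).fillna(0.0)
        if feed_conc is not None
        else feed_conc_timeline(scenario, analyte, lh)
    )

    pasture = pd.Series(0.0, index=dates)
    soil = pd.Series(0.0, index=dates)
    on_pasture = mode.isin(["pasture", "supplemental"])
    covered = pd.Series(False, index=dates)
    for gi in scenario.grazing:
        sl = slice(str(gi.start), str(gi.end))
        pconc = 0.0
        sconc = 0.0
        for fid, frac in gi.allocation.items():
            field = scenario.field_by_id(fid)
            pconc += frac * pasture_forage_conc(
                field, scenario.transfer_params, analyte, as_second_cut=(field.use == "dual")
            )
            sconc += frac * field.soil_conc[analyte]
        pasture.loc[sl] = pconc
        soil.loc[sl] = sconc
        covered.loc[sl] = True

    uncovered = on_pasture & ~covered
    if uncovered.any():
        day = uncovered.idxmax()
        raise PathwayError(
            f"grazing day {day.date()} has no grazing interval resolving the "
            "pasture/soil pathway"
        )

    water = scenario.water.series(dates, analyte)
    return pd.DataFrame(
        {"feed_conc": feed, "pasture_conc": pasture, "soil_conc": soil, "water_ngL": water}
    )


def build_dose_series(
    body: pd.DataFrame,
    exposure: pd.DataFrame,
    milk_conc: pd.Series | None = None,
    feed_factor: float = 1.0,
    water_factor: float = 1.0,
) -> pd.DataFrame:
    """Assemble the per-day dose decomposition (ng/day).

    ``body`` comes from :func:`herdtk.intake_physiology.build_body_states`
    and ``exposure`` from :func:`build_exposure_frame`; ``milk_conc`` is the
    dam milk concentration series (ng/mL) on nursing days.
    """
    idx = body.index
    grazing = body["mode"].to_numpy() == "pasture"
    fed = np.isin(body["mode"].to_numpy(), ("stored", "clean", "supplemental"))
    dmi = body["dmi_forage_kg"].to_numpy()

    dose_feed = np.where(fed, exposure["feed_conc"].to_numpy() * dmi * 1000.0, 0.0)
    dose_pasture = np.where(grazing, exposure["pasture_conc"].to_numpy() * dmi * 1000.0, 0.0)
    dose_soil = exposure["soil_conc"].to_numpy() * body["soil_kg"].to_numpy() * 1000.0
    dose_water = exposure["water_ngL"].to_numpy() * body["water_l"].to_numpy()

    milk_kg = body["milk_kg"].to_numpy()
    if milk_kg.any():
        if milk_conc is None:
            raise PathwayError(
                "animal nurses but no dam milk concentration series was supplied"
            )
        mc = milk_conc.reindex(idx).fillna(0.0).to_numpy()
        dose_milk = mc * milk_kg * 1000.0
    else:
        dose_milk = np.zeros(len(idx))

    out = pd.DataFrame(
        {
            "dose_feed": dose_feed * feed_factor,
            "dose_pasture": dose_pasture * feed_factor,
            "dose_soil": dose_soil * feed_factor,
            "dose_water": dose_water * water_factor,
            "dose_milk": dose_milk * feed_factor,
        },
        index=idx,
    )
    out["dose_total"] = out[list(DOSE_COMPONENTS)].sum(axis=1)
    return out


def daily_dose(
    dmi_stored_kg: float = 0.0,
    dmi_grazing_kg: float = 0.0,
    soil_kg: float = 0.0,
    water_l: float = 0.0,
    milk_kg: float = 0.0,
    feed_conc: float = 0.0,
    pasture_conc: float = 0.0,
    soil_conc: float = 0.0,
    water_ngL: float = 0.0,
    milk_conc: float = 0.0,
) -> dict[str, float]:
    """Single-day dose decomposition (ng/day) from intakes and concentrations."""
    row = {
        "dose_feed": feed_conc * dmi_stored_kg * 1000.0,
        "dose_pasture": pasture_conc * dmi_grazing_kg * 1000.0,
        "dose_soil": soil_conc * soil_kg * 1000.0,
        "dose_water": water_ngL * water_l,
        "dose_milk": milk_conc * milk_kg * 1000.0,
    }
    row["dose_total"] = sum(row.values())
    return row


def intake_perturbation(
    n: int, cv: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-animal multiplicative intake factors for feed and water.

    One (feed, water) factor pair per simulated animal, constant across its
    days, drawn from Normal(1, cv) truncated below at 0.1.  ``cv = 0``
    returns exact ones.
    """
    if cv < 0:
        raise ValueError("intake cv must be >= 0")
    if cv == 0:
        return np.ones(n), np.ones(n)
    feed = np.clip(rng.normal(1.0, cv, size=n), 0.1, None)
    water = np.clip(rng.normal(1.0, cv, size=n), 0.1, None)
    return feed, water


def build_dam_milk_series(scenario: "FarmScenario", analyte: str) -> pd.DataFrame:
    """Deterministic (mean-parameter) dam run: serum and milk per day.

    Milk concentration is Pmilk x dam serum on every day.  The same series
    feeds the milk pathway of every stochastic calf draw.
    """
    from .poptk import mean_draw, simulate_animal  # runtime import: cycle guard

    if scenario.dam_life_history is None:
        raise PathwayError("scenario has no dam life history but the calf nurses")
    draw = mean_draw(scenario.tk_params[analyte])
    traj = simulate_animal(
        scenario, analyte, draw, life_history=scenario.dam_life_history
    )
    return traj[["serum_ng_ml", "milk_ng_ml"]].rename(
        columns={"serum_ng_ml": "dam_serum_ng_ml", "milk_ng_ml": "milk_ng_ml"}
    )
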