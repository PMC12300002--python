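"""Farm-management interventions and their economics.

Because the kinetics are linear and first order, a dose delivered earlier
decays for longer before the sale or slaughter date: feeding the
highest-concentration bales first and the cleanest last always minimises
terminal tissue levels among permutations of the same inventory.  The
module builds such feed plans under bale-inventory constraints, re-runs
the population model for management variants (clean purchased feed,
prioritised feeding in the first or second winter), and compares net
revenue between holding to slaughter and selling live at auction.
"""

from __future__ import annotations

import datetime as dt
from typing import TYPE_CHECKING, Iterable

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field as PField

from .datasets import ACTION_LEVELS
from .feed_exposure import lot_feed_conc
from .intake_physiology import build_body_states
from .poptk import Ensemble, simulate_ensemble
from .scenario_io import FeedingInterval, LifeHistory

if TYPE_CHECKING:  # pragma: no cover
    from .scenario_io import FarmScenario, FeedLot

__all__ = [
    "EconConfig",
    "FeedPlan",
    "prioritize_feed",
    "simulate_management",
    "meat_weight",
    "net_revenue",
    "MANAGEMENT_VARIANTS",
]

MANAGEMENT_VARIANTS = (
    "baseline",
    "clean_feed",
    "prioritized_first_winter",
    "prioritized_second_winter",
)


class EconConfig(BaseModel):
    hanging_fraction: float = PField(default=0.63, gt=0, lt=1)
    bone_fraction_of_hanging: float = PField(default=0.175, gt=0, lt=1)
    retail_price_per_lb: float | None = None
    auction_price_per_lb: float | None = None
    feed_cost: float = 0.0
    grain_cost: float = 0.0
    grain_fraction_finishing: float = PField(default=0.175, ge=0, lt=1)
    bale_dm_kg: float = PField(default=400.0, gt=0)
    clean_feed_days: int = PField(default=120, ge=1)


class FeedPlan:
    """Day-by-day assignment of feed lots to a demand series."""

    def __init__(self, schedule: pd.DataFrame, conc_series: pd.Series):
        #: columns: date, lot_id, kg, conc_ng_g
        self.schedule = schedule
        #: per-day mass-weighted feed concentration (ng/g dw)
        self.conc_series = conc_series

    def total_fed_kg(self) -> float:
        return float(self.schedule["kg"].sum())

    def kg_by_lot(self) -> pd.Series:
        return self.schedule.groupby("lot_id")["kg"].sum()


def prioritize_feed(
    lots: Iterable["FeedLot"],
    fields: dict,
    params,
    daily_demand: pd.Series,
    analyte: str,
    bale_dm_kg: float = 400.0,
) -> FeedPlan:
    """Highest-concentration-first feed plan meeting a daily demand.

    Lots are ordered by expected concentration descending (ties broken by
    lot_id) and fed out sequentially; each lot supplies
    ``bale_count x bale_dm_kg`` of dry matter.  Insufficient total feed is
    an error reporting the shortfall.
    """
    lots = list(lots)
    supply = {l.lot_id: l.bale_count * bale_dm_kg for l in lots}
    demand_total = float(daily_demand.sum())
    shortfall = demand_total - sum(supply.values())
    if shortfall > 1e-9:
        raise ValueError(
            f"insufficient feed: demand {demand_total:.0f} kg exceeds supply by "
            f"{shortfall:.0f} kg"
        )
    conc = {
        l.lot_id: lot_feed_conc(l, fields[l.field_id], params, analyte) for l in lots
    }
    order = sorted(lots, key=lambda l: (-conc[l.lot_id], l.lot_id))

    rows = []
    day_conc = pd.Series(0.0, index=daily_demand.index)
    queue = [(l.lot_id, supply[l.lot_id]) for l in order if supply[l.lot_id] > 0]
    qi = 0
    for date, need in daily_demand.items():
        need = float(need)
        weighted = 0.0
        while need > 1e-12:
            lot_id, avail = queue[qi]
            take = min(need, avail)
            rows.append({"date": date, "lot_id": lot_id, "kg": take, "conc_ng_g": conc[lot_id]})
            weighted += take * conc[lot_id]
            need -= take
            avail -= take
            if avail <= 1e-12:
                qi += 1
                if qi >= len(queue) and need > 1e-12:
                    raise ValueError("feed exhausted before demand met")
            else:
                queue[qi] = (lot_id, avail)
        total = float(daily_demand.loc[date])
        day_conc.loc[date] = weighted / total if total > 0 else 0.0
    return FeedPlan(pd.DataFrame(rows), day_conc)


def _winter_intervals(lh: LifeHistory) -> list[FeedingInterval]:
    return [iv for iv in lh.intervals if iv.mode == "stored"]


def _with_clean_tail(scenario: "FarmScenario", clean_days: int) -> "FarmScenario":
    """Convert the final ``clean_days`` stored-feed days to purchased clean feed."""
    lh = scenario.life_history
    winters = _winter_intervals(lh)
    if not winters:
        raise ValueError("no stored-feed interval to substitute with clean feed")
    last = winters[-1]
    clean_start = max(last.start, last.end - dt.timedelta(days=clean_days - 1))
    new_intervals = []
    for iv in lh.intervals:
        if iv is last and clean_start > iv.start:
            new_intervals.append(
                FeedingInterval(
                    start=iv.start,
                    end=clean_start - dt.timedelta(days=1),
                    mode="stored",
                    crop_year=iv.crop_year,
                )
            )
            new_intervals.append(FeedingInterval(start=clean_start, end=iv.end, mode="clean"))
        elif iv is last:
            new_intervals.append(FeedingInterval(start=iv.start, end=iv.end, mode="clean"))
        else:
            new_intervals.append(iv)
    return scenario.model_copy(
        update={
            "life_history": LifeHistory(
                birth_date=lh.birth_date,
                weaning_date=lh.weaning_date,
                end_date=lh.end_date,
                intervals=new_intervals,
            )
        }
    )


def _prioritized_feed_series(
    scenario: "FarmScenario", winter_index: int, analyte: str, bale_dm_kg: float
) -> pd.Series:
    """Per-day feed concentrations for one winter under the
    highest-first plan; other stored days keep the default timeline."""
    from .feed_exposure import feed_conc_timeline

    lh = scenario.life_history
    winters = _winter_intervals(lh)
    if winter_index >= len(winters):
        raise ValueError(
            f"scenario has {len(winters)} stored-feed winters; index {winter_index} invalid"
        )
    target = winters[winter_index]
    body = build_body_states(scenario)
    demand = body["dmi_forage_kg"].loc[str(target.start) : str(target.end)]
    lots = scenario.lots_for(target.effective_crop_year())
    fields = {f.field_id: f for f in scenario.fields}
    plan = prioritize_feed(
        lots, fields, scenario.transfer_params, demand, analyte, bale_dm_kg
    )
    base = feed_conc_timeline(scenario, analyte)
    base.loc[str(target.start) : str(target.end)] = plan.conc_series
    return base


def simulate_management(
    scenario: "FarmScenario",
    variant: str,
    analyte: str,
    n: int | None = None,
    seed: int | None = None,
    econ: EconConfig | None = None,
) -> tuple[Ensemble, pd.DataFrame]:
    """Run one management variant; returns the ensemble and a threshold
    report (fraction of draws below each muscle action level at the
    endpoint date).
    """
    econ = econ or EconConfig()
    if variant not in MANAGEMENT_VARIANTS:
        raise ValueError(f"unknown management variant {variant!r}")
    feed_conc = None
    sim_scenario = scenario
    if variant == "clean_feed":
        sim_scenario = _with_clean_tail(scenario, econ.clean_feed_days)
    elif variant == "prioritized_first_winter":
        feed_conc = _prioritized_feed_series(scenario, 0, analyte, econ.bale_dm_kg)
    elif variant == "prioritized_second_winter":
        feed_conc = _prioritized_feed_series(scenario, 1, analyte, econ.bale_dm_kg)

    ens = simulate_ensemble(sim_scenario, analyte, n=n, seed=seed, feed_conc=feed_conc)
    end = scenario.life_history.end_date
    terminal_muscle = ens.at(end, matrix="muscle")
    rows = []
    for label, threshold in ACTION_LEVELS.get((analyte, "muscle"), {}).items():
        rows.append(
            {
                "variant": variant,
                "analyte": analyte,
                "threshold_label": label,
                "threshold_ng_g": threshold,
                "date": end,
                "fraction_below": float((terminal_muscle <= threshold).mean()),
            }
        )
    return ens, pd.DataFrame(rows)


def meat_weight(live_weight_lb: float, econ: EconConfig | None = None) -> float:
    """Sellable meat (lb): live weight x hanging fraction x (1 - bone
    fraction of hanging weight)."""
    econ = econ or EconConfig()
    if live_weight_lb <= 0:
        raise ValueError("live weight must be positive")
    return live_weight_lb * econ.hanging_fraction * (1.0 - econ.bone_fraction_of_hanging)


def net_revenue(option: str, live_weight_lb: float, econ: EconConfig) -> float:
    """Net revenue per animal for one marketing option.

    ``slaughter``: meat weight x retail price - feed cost - grain cost.
    ``auction``: live weight x auction price.
    """
    if option == "slaughter":
        if econ.retail_price_per_lb is None:
            raise ValueError("retail_price_per_lb not configured")
        return (
            meat_weight(live_weight_lb, econ) * econ.retail_price_per_lb
            - econ.feed_cost
            - econ.grain_cost
        )
    if option == "auction":
        if econ.auction_price_per_lb is None:
            raise ValueError("auction_price_per_lb not configured")
        return live_weight_lb * econ.auction_price_per_lb
    raise ValueError(f"unknown option {option!r}")
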