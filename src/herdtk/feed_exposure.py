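"""PFAS concentrations in stored feed and pasture forage.

Feed concentrations come from either (a) measured hay concentrations when a
lot was sampled, or (b) the field's composite soil concentration times a
site-specific soil-to-plant transfer factor, with a cut-specific multiplier
for second cuttings (plant uptake is higher in regrowth: 2.7-fold for PFOS
and 2.1-fold for PFDA by default).  A crop year's average feed level is the
bale-count-weighted mean over its lots.
"""

from __future__ import annotations

from typing import TYPE_CHECKING, Iterable

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field as PField, model_validator

if TYPE_CHECKING:  # pragma: no cover - import cycle guard
    from .scenario_io import FarmScenario, Field, FeedLot

__all__ = [
    "TransferParams",
    "lot_feed_conc",
    "weighted_feed_conc",
    "pasture_forage_conc",
    "feed_conc_timeline",
]


class TransferParams(BaseModel):
    """Soil-to-plant transfer factors per analyte (first cut) and the
    second-cut uptake multipliers."""

    tf: dict[str, float]
    second_cut_multiplier: dict[str, float] = PField(
        default_factory=lambda: {"PFOS": 2.7, "PFDA": 2.1}
    )

    @model_validator(mode="after")
    def _check(self) -> "TransferParams":
        for analyte, v in self.tf.items():
            if not v > 0:
                raise ValueError(f"transfer factor for {analyte} must be > 0")
        for analyte, v in self.second_cut_multiplier.items():
            if v < 1:
                raise ValueError(f"second-cut multiplier for {analyte} must be >= 1")
        return self

    def multiplier(self, analyte: str) -> float:
        return self.second_cut_multiplier.get(analyte, 1.0)


def _soil_conc(field: "Field", analyte: str) -> float:
    try:
        return field.soil_conc[analyte]
    except KeyError:
        raise KeyError(
            f"field {field.field_id!r} has no soil concentration for {analyte!r}"
        ) from None


def lot_feed_conc(
    lot: "FeedLot", field: "Field", params: TransferParams, analyte: str
) -> float:
    """Estimated or measured concentration (ng/g dw) of one hay lot.

    A measured concentration always overrides the soil-transfer estimate;
    transfer factors are not consulted in that case.
    """
    if analyte in lot.measured_conc:
        return lot.measured_conc[analyte]
    soil = _soil_conc(field, analyte)
    tf = params.tf.get(analyte)
    if tf is None:
        raise KeyError(f"no transfer factor configured for {analyte!r}")
    mult = params.multiplier(analyte) if lot.cut == 2 else 1.0
    return soil * tf * mult


def weighted_feed_conc(
    lots: Iterable["FeedLot"],
    fields: dict[str, "Field"],
    params: TransferParams,
    analyte: str,
) -> float:
    """Bale-fraction-weighted average concentration over a set of lots."""
    lots = list(lots)
    total = sum(l.bale_count for l in lots)
    if total <= 0:
        raise ValueError("weighted feed concentration undefined: zero total bales")
    return float(
        sum(
            lot_feed_conc(l, fields[l.field_id], params, analyte) * l.bale_count
            for l in lots
        )
        / total
    )


def pasture_forage_conc(
    field: "Field", params: TransferParams, analyte: str, as_second_cut: bool = False
) -> float:
    """Forage concentration on a pasture (ng/g dw).

    Dual-use hay fields grazed after a cutting are flagged ``as_second_cut``
    and use the adjusted second-cut transfer factor.
    """
    soil = _soil_conc(field, analyte)
    tf = params.tf.get(analyte)
    if tf is None:
        raise KeyError(f"no transfer factor configured for {analyte!r}")
    mult = params.multiplier(analyte) if as_second_cut else 1.0
    return soil * tf * mult


def feed_conc_timeline(
    scenario: "FarmScenario", analyte: str, life_history=None
) -> pd.Series:
    """Per-day stored-feed concentration (ng/g dw) over the animal's life.

    Stored-feed days carry the crop year's weighted first- or second-cut
    average according to the scenario's feeding order (default: second cut
    fed first, for a number of days equal to its bale share of the winter).
    Clean-feed days carry the configured clean-feed concentration (default
    0).  Supplemental episodes carry their override, falling back to the
    crop-year first-cut average.  Days with no stored feed are 0.
    """
    lh = life_history if life_history is not None else scenario.life_history
    fields = {f.field_id: f for f in scenario.fields}
    out = pd.Series(0.0, index=lh.dates)

    for iv in lh.intervals:
        if iv.mode == "pasture":
            continue
        sl = out.loc[str(iv.start) : str(iv.end)]
        n_days = len(sl)
        if iv.mode == "clean":
            conc = (iv.conc_override or {}).get(
                analyte, scenario.clean_feed_conc.get(analyte, 0.0)
            )
            out.loc[str(iv.start) : str(iv.end)] = conc
            continue
        crop_year = iv.effective_crop_year()
        if iv.mode == "supplemental":
            if iv.conc_override and analyte in iv.conc_override:
                conc = iv.conc_override[analyte]
            else:
                lots = scenario.lots_for(crop_year, cut=1) or scenario.lots_for(crop_year)
                if not lots:
                    raise ValueError(
                        f"supplemental episode {iv.start}..{iv.end} has no crop-year "
                        f"{crop_year} lots and no concentration override"
                    )
                conc = weighted_feed_conc(lots, fields, scenario.transfer_params, analyte)
            out.loc[str(iv.start) : str(iv.end)] = conc
            continue

        # stored-feed interval
        if iv.conc_override and analyte in iv.conc_override:
            out.loc[str(iv.start) : str(iv.end)] = iv.conc_override[analyte]
            continue
        lots_all = scenario.lots_for(crop_year)
        if not any(l.bale_count > 0 for l in lots_all):
            raise ValueError(
                f"stored-feed interval {iv.start}..{iv.end} has no feed lots for "
                f"crop year {crop_year}"
            )
        total_bales = sum(l.bale_count for l in lots_all)
        values = np.empty(n_days)
        pos = 0
        order = scenario.feeding_order
        for step_i, entry in enumerate(order):
            if pos >= n_days:
                break
            lots_cut = [l for l in lots_all if l.cut == entry.cut and l.bale_count > 0]
            if not lots_cut:
                continue
            share = sum(l.bale_count for l in lots_cut) / total_bales
            if entry.days == "rest" or step_i == len(order) - 1:
                span = n_days - pos
            elif entry.days == "by_share":
                span = int(round(share * n_days))
            else:
                span = int(entry.days)
            span = min(span, n_days - pos)
            if span <= 0:
                continue
            conc = weighted_feed_conc(lots_cut, fields, scenario.transfer_params, analyte)
            values[pos : pos + span] = conc
            pos += span
        if pos < n_days:
            # remaining days fall back to the whole-crop weighted average
            conc = weighted_feed_conc(
                [l for l in lots_all if l.bale_count > 0],
                fields,
                scenario.transfer_params,
                analyte,
            )
            values[pos:] = conc
        out.loc[str(iv.start) : str(iv.end)] = values
    return out
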