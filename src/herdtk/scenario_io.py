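"""Farm-scenario data model, tabular I/O, and validation.

A :class:`FarmScenario` is the complete declarative description of a farm
simulation: fields and their soil concentrations, the hay-bale inventory,
grazing and feeding calendars, drinking-water history, weather, the life
history of the simulated animal (and optionally its dam), and every model
parameter block.  All concentrations are fixed at this boundary: soil, feed
and muscle in ng/g dry weight, serum/plasma/milk in ng/mL, water in ng/L.
Dates are ISO calendar dates; the simulation clock is daily with day 0 equal
to the birth date, and all intervals are closed on both ends.
"""

from __future__ import annotations

import datetime as dt
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field as PField, field_validator, model_validator

from .feed_exposure import TransferParams
from .intake_physiology import GrowthParams, IntakeParams, LactationParams
from .poptk import TKParams

__all__ = [
    "Field",
    "FeedLot",
    "GrazingInterval",
    "WaterExposure",
    "WeatherSeries",
    "FeedingInterval",
    "LifeHistory",
    "SimulationSettings",
    "FarmScenario",
    "ScenarioValidationError",
    "load_scenario",
    "write_scenario",
    "nondetect_policy",
    "read_biomonitoring",
]

MATRICES = ("serum", "plasma", "muscle")
FeedingMode = Literal["pasture", "stored", "clean", "supplemental"]


class ScenarioValidationError(ValueError):
    """A scenario is structurally parseable but semantically invalid."""


class Field(BaseModel):
    """A farm field with a composite soil concentration per analyte."""

    field_id: str
    acres: float = PField(gt=0)
    use: Literal["pasture", "hay", "dual"]
    soil_conc: dict[str, float]
    biosolids_history: bool = False

    @field_validator("soil_conc")
    @classmethod
    def _non_negative(cls, v: dict[str, float]) -> dict[str, float]:
        for analyte, conc in v.items():
            if conc < 0:
                raise ValueError(f"soil concentration for {analyte} is negative")
        return v


class FeedLot(BaseModel):
    """Bales harvested from one field in one crop year and cutting."""

    lot_id: str
    field_id: str
    harvest_year: int
    cut: Literal[1, 2]
    bale_count: int = PField(ge=0)
    measured_conc: dict[str, float] = PField(default_factory=dict)
    dm_fraction: float = PField(default=0.88, gt=0, le=1)

    @field_validator("measured_conc")
    @classmethod
    def _non_negative(cls, v: dict[str, float]) -> dict[str, float]:
        for analyte, conc in v.items():
            if conc < 0:
                raise ValueError(f"measured concentration for {analyte} is negative")
        return v


class GrazingInterval(BaseModel):
    """A closed date interval spent on one or more pastures.

    ``allocation`` maps field_id to the fraction of grazing time spent on
    that field; the fractions must sum to 1.
    """

    start: dt.date
    end: dt.date
    allocation: dict[str, float]

    @model_validator(mode="after")
    def _check(self) -> "GrazingInterval":
        if self.start > self.end:
            raise ValueError(f"grazing interval start {self.start} after end {self.end}")
        total = sum(self.allocation.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"grazing allocation sums to {total}, expected 1")
        return self


class WaterSegment(BaseModel):
    start: dt.date
    end: dt.date
    conc: dict[str, float]

    @model_validator(mode="after")
    def _check(self) -> "WaterSegment":
        if self.start > self.end:
            raise ValueError("water segment start after end")
        for analyte, c in self.conc.items():
            if c < 0:
                raise ValueError(f"water concentration for {analyte} is negative")
        return self


class WaterExposure(BaseModel):
    """Ordered, non-overlapping drinking-water concentration segments."""

    segments: list[WaterSegment] = PField(default_factory=list)

    @model_validator(mode="after")
    def _check_overlap(self) -> "WaterExposure":
        segs = sorted(self.segments, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"water segments overlap: {a.start}..{a.end} and {b.start}..{b.end}"
                )
        self.segments = segs
        return self

    def series(self, index: pd.DatetimeIndex, analyte: str) -> pd.Series:
        """Per-day water concentration (ng/L); days with no segment are 0."""
        out = pd.Series(0.0, index=index)
        for seg in self.segments:
            out.loc[str(seg.start) : str(seg.end)] = seg.conc.get(analyte, 0.0)
        return out


class WeatherSeries(BaseModel):
    """Daily weather records (mean temperature degC, precipitation mm)."""

    model_config = ConfigDict(arbitrary_types_allowed=True)

    frame: pd.DataFrame  # index: DatetimeIndex; columns: tmean_c, precip_mm
    max_gap_fill_days: int = 7

    @model_validator(mode="after")
    def _validate_frame(self) -> "WeatherSeries":
        df = self.frame
        if not isinstance(df.index, pd.DatetimeIndex):
            raise ValueError("weather frame must be indexed by date")
        for col in ("tmean_c", "precip_mm"):
            if col not in df.columns:
                raise ValueError(f"weather frame missing column {col!r}")
        df = df.sort_index()
        full = pd.date_range(df.index[0], df.index[-1], freq="D")
        reindexed = df.reindex(full)
        gap = reindexed["tmean_c"].isna()
        if gap.any():
            run = gap.groupby((~gap).cumsum()).cumsum()
            worst = int(run.max())
            if worst > self.max_gap_fill_days:
                first = run.idxmax()
                raise ValueError(
                    f"weather gap of {worst} days ending {first.date()} exceeds the "
                    f"{self.max_gap_fill_days}-day forward-fill limit"
                )
            reindexed = reindexed.ffill()
        object.__setattr__(self, "frame", reindexed)
        return self

    def covers(self, start: dt.date, end: dt.date) -> bool:
        return self.frame.index[0].date() <= start and self.frame.index[-1].date() >= end


class FeedingInterval(BaseModel):
    """A closed interval with one primary feeding mode.

    ``crop_year`` pins the hay crop consumed on stored-feed days; when
    omitted it defaults to the harvest preceding the interval (the start
    year if the interval begins in July or later, else the year before).
    ``conc_override`` replaces the computed feed concentration, used for
    supplemental-hay episodes and explicit clean-feed residual levels.
    """

    start: dt.date
    end: dt.date
    mode: FeedingMode
    crop_year: Optional[int] = None
    conc_override: Optional[dict[str, float]] = None

    @model_validator(mode="after")
    def _check(self) -> "FeedingInterval":
        if self.start > self.end:
            raise ValueError(f"feeding interval start {self.start} after end {self.end}")
        return self

    def effective_crop_year(self) -> int:
        if self.crop_year is not None:
            return self.crop_year
        return self.start.year if self.start.month >= 7 else self.start.year - 1


class LifeHistory(BaseModel):
    """Birth-to-endpoint feeding calendar for one animal.

    Every day from birth to end must be covered by exactly one feeding
    interval.  Days before ``weaning_date`` additionally carry nursing
    (milk) intake on top of the primary mode.
    """

    birth_date: dt.date
    weaning_date: dt.date
    end_date: dt.date
    intervals: list[FeedingInterval]

    @model_validator(mode="after")
    def _check(self) -> "LifeHistory":
        if not (self.birth_date <= self.weaning_date <= self.end_date):
            raise ValueError("dates must satisfy birth <= weaning <= end")
        if not self.intervals:
            raise ValueError("life history has no feeding intervals")
        ivs = sorted(self.intervals, key=lambda iv: iv.start)
        if ivs[0].start != self.birth_date:
            raise ValueError(
                f"first feeding interval starts {ivs[0].start}, expected birth {self.birth_date}"
            )
        for a, b in zip(ivs, ivs[1:]):
            expected = a.end + dt.timedelta(days=1)
            if b.start != expected:
                raise ValueError(
                    f"feeding-calendar gap or overlap: interval ending {a.end} "
                    f"followed by interval starting {b.start}"
                )
        if ivs[-1].end != self.end_date:
            raise ValueError(
                f"last feeding interval ends {ivs[-1].end}, expected end {self.end_date}"
            )
        self.intervals = ivs
        return self

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.birth_date, self.end_date, freq="D")

    @property
    def n_days(self) -> int:
        return (self.end_date - self.birth_date).days + 1

    def mode_series(self) -> pd.Series:
        """Per-day primary feeding mode."""
        out = pd.Series("", index=self.dates, dtype=object)
        for iv in self.intervals:
            out.loc[str(iv.start) : str(iv.end)] = iv.mode
        return out

    def stored_intervals(self) -> list[FeedingInterval]:
        return [iv for iv in self.intervals if iv.mode == "stored"]

    def grazing_intervals(self) -> list[FeedingInterval]:
        return [iv for iv in self.intervals if iv.mode == "pasture"]


class FeedingOrderEntry(BaseModel):
    """One step of the within-winter feeding order (which cut, how long).

    ``days`` may be an integer day count, ``"by_share"`` (the cut's bale
    share of the crop, scaled to the interval length) or ``"rest"``.
    """

    cut: Literal[1, 2]
    days: int | Literal["by_share", "rest"] = "by_share"


class SimulationSettings(BaseModel):
    n_draws: int = PField(default=100, ge=1)
    seed: int = 0
    intake_cv: float = PField(default=0.30, ge=0)


class FarmScenario(BaseModel):
    model_config = ConfigDict(arbitrary_types_allowed=True)

    analytes: list[str]
    fields: list[Field]
    feed_lots: list[FeedLot]
    grazing: list[GrazingInterval]
    water: WaterExposure
    weather: WeatherSeries
    life_history: LifeHistory
    dam_life_history: Optional[LifeHistory] = None
    transfer_params: TransferParams
    tk_params: dict[str, TKParams]
    growth_params: GrowthParams
    lactation_params: LactationParams
    intake_params: IntakeParams
    feeding_order: list[FeedingOrderEntry] = PField(
        default_factory=lambda: [FeedingOrderEntry(cut=2, days="by_share"), FeedingOrderEntry(cut=1, days="rest")]
    )
    clean_feed_conc: dict[str, float] = PField(default_factory=dict)
    settings: SimulationSettings = PField(default_factory=SimulationSettings)

    @model_validator(mode="after")
    def _cross_validate(self) -> "FarmScenario":
        field_ids = {f.field_id for f in self.fields}
        for lot in self.feed_lots:
            if lot.field_id not in field_ids:
                raise ScenarioValidationError(
                    f"feed lot {lot.lot_id!r} references unknown field {lot.field_id!r}"
                )
        for gi in self.grazing:
            for fid in gi.allocation:
                if fid not in field_ids:
                    raise ScenarioValidationError(
                        f"grazing interval {gi.start}..{gi.end} references unknown field {fid!r}"
                    )
        for analyte in self.analytes:
            if analyte not in self.tk_params:
                raise ScenarioValidationError(f"no TK parameters for analyte {analyte!r}")
            for f in self.fields:
                if analyte not in f.soil_conc:
                    raise ScenarioValidationError(
                        f"field {f.field_id!r} has no soil concentration for {analyte!r} "
                        "(enter 0 for a non-detect)"
                    )
        for lh, label in ((self.life_history, "life history"), (self.dam_life_history, "dam life history")):
            if lh is None:
                continue
            if not self.weather.covers(lh.birth_date, lh.end_date):
                raise ScenarioValidationError(
                    f"weather coverage {self.weather.frame.index[0].date()}.."
                    f"{self.weather.frame.index[-1].date()} does not span the {label} "
                    f"{lh.birth_date}..{lh.end_date}"
                )
        if (
            self.life_history.weaning_date > self.life_history.birth_date
            and self.dam_life_history is None
        ):
            raise ScenarioValidationError(
                "the animal nurses (weaning after birth) but no dam life history is defined"
            )
        if self.dam_life_history is not None:
            dam, calf = self.dam_life_history, self.life_history
            if dam.birth_date > calf.birth_date or dam.end_date < calf.weaning_date:
                raise ScenarioValidationError(
                    "dam life history must span the calf's birth and nursing window"
                )
        return self

    def lots_for(self, crop_year: int, cut: int | None = None) -> list[FeedLot]:
        lots = [l for l in self.feed_lots if l.harvest_year == crop_year]
        if cut is not None:
            lots = [l for l in lots if l.cut == cut]
        return lots

    def field_by_id(self, field_id: str) -> Field:
        for f in self.fields:
            if f.field_id == field_id:
                return f
        raise KeyError(field_id)


def nondetect_policy(
    raw_value: float | None,
    mdl: float | None = None,
    policy: Literal["zero", "half_mdl", "mdl"] = "zero",
) -> float:
    """Substitute a reported non-detect with a deterministic value.

    ``raw_value`` is the reported concentration, or None for a non-detect.
    Detected values pass through unchanged regardless of policy.
    """
    if raw_value is not None:
        return float(raw_value)
    if policy == "zero":
        return 0.0
    if mdl is None:
        raise ValueError(f"non-detect with no detection limit cannot use policy {policy!r}")
    return 0.5 * mdl if policy == "half_mdl" else float(mdl)


# ---------------------------------------------------------------------------
# Tabular I/O.  Header names are part of the contract:
#   fields.csv:       field_id,acres,use,biosolids,analyte,soil_ng_g
#   feed_lots.csv:    lot_id,field_id,year,cut,bales,analyte,measured_ng_g,dm_fraction
#   grazing.csv:      start,end,field_id,allocation
#   water.csv:        start,end,analyte,ng_L
#   weather.csv:      date,tmean_c,precip_mm
#   biomonitoring.csv: animal_id,date,matrix,analyte,conc
# ---------------------------------------------------------------------------


def _read_fields(path: Path) -> list[Field]:
    df = pd.read_csv(path)
    out = []
    for (fid,), grp in df.groupby(["field_id"], sort=False):
        first = grp.iloc[0]
        out.append(
            Field(
                field_id=str(fid),
                acres=float(first["acres"]),
                use=str(first["use"]),
                biosolids_history=bool(first["biosolids"]),
                soil_conc={str(r["analyte"]): float(r["soil_ng_g"]) for _, r in grp.iterrows()},
            )
        )
    return out


def _read_feed_lots(path: Path) -> list[FeedLot]:
    df = pd.read_csv(path)
    out = []
    for (lid,), grp in df.groupby(["lot_id"], sort=False):
        first = grp.iloc[0]
        measured = {
            str(r["analyte"]): float(r["measured_ng_g"])
            for _, r in grp.iterrows()
            if pd.notna(r["measured_ng_g"])
        }
        out.append(
            FeedLot(
                lot_id=str(lid),
                field_id=str(first["field_id"]),
                harvest_year=int(first["year"]),
                cut=int(first["cut"]),
                bale_count=int(first["bales"]),
                measured_conc=measured,
                dm_fraction=float(first["dm_fraction"]),
            )
        )
    return out


def _read_grazing(path: Path) -> list[GrazingInterval]:
    df = pd.read_csv(path, parse_dates=["start", "end"])
    out = []
    for (start, end), grp in df.groupby(["start", "end"], sort=True):
        out.append(
            GrazingInterval(
                start=start.date(),
                end=end.date(),
                allocation={str(r["field_id"]): float(r["allocation"]) for _, r in grp.iterrows()},
            )
        )
    return out


def _read_water(path: Path) -> WaterExposure:
    df = pd.read_csv(path, parse_dates=["start", "end"])
    segs = []
    for (start, end), grp in df.groupby(["start", "end"], sort=True):
        segs.append(
            WaterSegment(
                start=start.date(),
                end=end.date(),
                conc={str(r["analyte"]): float(r["ng_L"]) for _, r in grp.iterrows()},
            )
        )
    return WaterExposure(segments=segs)


def _read_weather(path: Path) -> WeatherSeries:
    df = pd.read_csv(path, parse_dates=["date"]).set_index("date")
    return WeatherSeries(frame=df[["tmean_c", "precip_mm"]])


def read_biomonitoring(path: Path | str) -> pd.DataFrame:
    """Read biomonitoring records into a tidy frame.

    Columns: animal_id, date, matrix (serum/plasma/muscle), analyte, conc
    (ng/mL for serum and plasma, ng/g for muscle).
    """
    df = pd.read_csv(path, parse_dates=["date"])
    required = {"animal_id", "date", "matrix", "analyte", "conc"}
    missing = required - set(df.columns)
    if missing:
        raise ScenarioValidationError(f"biomonitoring file missing columns {sorted(missing)}")
    bad = set(df["matrix"]) - set(MATRICES)
    if bad:
        raise ScenarioValidationError(f"unknown biomonitoring matrices {sorted(bad)}")
    if (df["conc"] < 0).any():
        raise ScenarioValidationError("negative biomonitoring concentration")
    return df


def _life_history_from_dict(d: dict) -> LifeHistory:
    intervals = [
        FeedingInterval(
            start=_as_date(iv["start"]),
            end=_as_date(iv["end"]),
            mode=iv["mode"],
            crop_year=iv.get("crop_year"),
            conc_override=iv.get("conc_override"),
        )
        for iv in d["intervals"]
    ]
    return LifeHistory(
        birth_date=_as_date(d["birth_date"]),
        weaning_date=_as_date(d["weaning_date"]),
        end_date=_as_date(d["end_date"]),
        intervals=intervals,
    )


def _as_date(v) -> dt.date:
    if isinstance(v, dt.date):
        return v
    return dt.date.fromisoformat(str(v))


def load_scenario(config_path: Path | str, data_dir: Path | str | None = None) -> FarmScenario:
    """Load and fully validate a scenario from its config file.

    ``config_path`` is a YAML file; CSVs are resolved relative to
    ``data_dir`` (default: the config file's directory).
    """
    config_path = Path(config_path)
    if not config_path.exists():
        raise FileNotFoundError(config_path)
    base = Path(data_dir) if data_dir is not None else config_path.parent
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)

    files = cfg.get("files", {})

    def _p(key: str, default: str) -> Path:
        p = base / files.get(key, default)
        if not p.exists():
            raise FileNotFoundError(p)
        return p

    tk = {
        analyte: TKParams.model_validate(block) for analyte, block in cfg["tk"].items()
    }
    try:
        return FarmScenario(
            analytes=list(cfg["analytes"]),
            fields=_read_fields(_p("fields", "fields.csv")),
            feed_lots=_read_feed_lots(_p("feed_lots", "feed_lots.csv")),
            grazing=_read_grazing(_p("grazing", "grazing.csv")),
            water=_read_water(_p("water", "water.csv")),
            weather=_read_weather(_p("weather", "weather.csv")),
            life_history=_life_history_from_dict(cfg["life_history"]),
            dam_life_history=(
                _life_history_from_dict(cfg["dam_life_history"])
                if cfg.get("dam_life_history")
                else None
            ),
            transfer_params=TransferParams.model_validate(cfg["transfer"]),
            tk_params=tk,
            growth_params=GrowthParams.model_validate(cfg.get("growth", {})),
            lactation_params=LactationParams.model_validate(cfg.get("lactation", {})),
            intake_params=IntakeParams.model_validate(cfg.get("intake", {})),
            feeding_order=[
                FeedingOrderEntry.model_validate(e) for e in cfg.get("feeding_order", [])
            ]
            or [FeedingOrderEntry(cut=2, days="by_share"), FeedingOrderEntry(cut=1, days="rest")],
            clean_feed_conc=cfg.get("clean_feed_conc", {}),
            settings=SimulationSettings.model_validate(cfg.get("simulation", {})),
        )
    except ScenarioValidationError:
        raise
    except ValueError as exc:  # pydantic wraps our messages; re-raise typed
        raise ScenarioValidationError(str(exc)) from exc


def _life_history_to_dict(lh: LifeHistory) -> dict:
    return {
        "birth_date": str(lh.birth_date),
        "weaning_date": str(lh.weaning_date),
        "end_date": str(lh.end_date),
        "intervals": [
            {
                "start": str(iv.start),
                "end": str(iv.end),
                "mode": iv.mode,
                **({"crop_year": iv.crop_year} if iv.crop_year is not None else {}),
                **({"conc_override": iv.conc_override} if iv.conc_override else {}),
            }
            for iv in lh.intervals
        ],
    }


def write_scenario(scenario: FarmScenario, out_dir: Path | str) -> Path:
    """Write the full CSV/config bundle; returns the config path.

    ``load_scenario(write_scenario(s))`` reproduces an equivalent scenario.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    rows = [
        {
            "field_id": f.field_id,
            "acres": f.acres,
            "use": f.use,
            "biosolids": f.biosolids_history,
            "analyte": analyte,
            "soil_ng_g": conc,
        }
        for f in scenario.fields
        for analyte, conc in f.soil_conc.items()
    ]
    pd.DataFrame(rows).to_csv(out / "fields.csv", index=False)

    rows = []
    for lot in scenario.feed_lots:
        analytes = set(scenario.analytes) | set(lot.measured_conc)
        for analyte in sorted(analytes):
            rows.append(
                {
                    "lot_id": lot.lot_id,
                    "field_id": lot.field_id,
                    "year": lot.harvest_year,
                    "cut": lot.cut,
                    "bales": lot.bale_count,
                    "analyte": analyte,
                    "measured_ng_g": lot.measured_conc.get(analyte, ""),
                    "dm_fraction": lot.dm_fraction,
                }
            )
    pd.DataFrame(rows).to_csv(out / "feed_lots.csv", index=False)

    rows = [
        {"start": gi.start, "end": gi.end, "field_id": fid, "allocation": frac}
        for gi in scenario.grazing
        for fid, frac in gi.allocation.items()
    ]
    pd.DataFrame(rows).to_csv(out / "grazing.csv", index=False)

    rows = [
        {"start": seg.start, "end": seg.end, "analyte": analyte, "ng_L": conc}
        for seg in scenario.water.segments
        for analyte, conc in seg.conc.items()
    ]
    pd.DataFrame(rows, columns=["start", "end", "analyte", "ng_L"]).to_csv(
        out / "water.csv", index=False
    )

    wx = scenario.weather.frame.reset_index().rename(columns={"index": "date"})
    wx.columns = ["date", "tmean_c", "precip_mm"]
    wx["date"] = wx["date"].dt.date
    wx.to_csv(out / "weather.csv", index=False)

    cfg = {
        "analytes": scenario.analytes,
        "files": {
            "fields": "fields.csv",
            "feed_lots": "feed_lots.csv",
            "grazing": "grazing.csv",
            "water": "water.csv",
            "weather": "weather.csv",
        },
        "transfer": scenario.transfer_params.model_dump(),
        "tk": {a: p.model_dump() for a, p in scenario.tk_params.items()},
        "growth": scenario.growth_params.model_dump(),
        "lactation": scenario.lactation_params.model_dump(),
        "intake": scenario.intake_params.model_dump(),
        "life_history": _life_history_to_dict(scenario.life_history),
        "dam_life_history": (
            _life_history_to_dict(scenario.dam_life_history)
            if scenario.dam_life_history
            else None
        ),
        "feeding_order": [e.model_dump() for e in scenario.feeding_order],
        "clean_feed_conc": scenario.clean_feed_conc,
        "simulation": scenario.settings.model_dump(),
    }
    config_path = out / "scenario.yaml"
    with open(config_path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return config_path
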