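"""Model evaluation against biomonitoring.

Agreement statistics follow the field study's conventions: the percentage
error 100 (modeled - measured) / measured between the ensemble mean and the
measured mean on the same calendar day, the mean absolute percentage error
(MAPE) across comparisons, and the fold ratio max(m/o, o/m).  Plasma
records are harmonised to serum equivalents with fixed serum/plasma ratios
before comparison.  Muscle/serum partition coefficients are meta-analysed
across paired datasets.  Action-level exceedance is the fraction of
ensemble draws above a tissue threshold on a given day.
"""

from __future__ import annotations

import math
from typing import TYPE_CHECKING, Iterable

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field as PField

from .datasets import ACTION_LEVELS, SERUM_PLASMA_RATIOS

if TYPE_CHECKING:  # pragma: no cover
    from .poptk import Ensemble

__all__ = [
    "EvaluationConfig",
    "plasma_to_serum",
    "percentage_error",
    "mape",
    "fold_ratio",
    "exceedance_fraction",
    "meta_pm",
    "evaluate_scenario",
    "fit_dt50_loglinear",
    "seasonal_signature",
]


class EvaluationConfig(BaseModel):
    action_levels: dict = PField(default_factory=lambda: dict(ACTION_LEVELS))
    plasma_to_serum_ratios: dict[str, float] = PField(
        default_factory=lambda: dict(SERUM_PLASMA_RATIOS)
    )


def plasma_to_serum(conc: float, analyte: str, config: EvaluationConfig | None = None) -> float:
    """Convert a plasma concentration to its serum equivalent."""
    ratios = (config or EvaluationConfig()).plasma_to_serum_ratios
    if analyte not in ratios:
        raise KeyError(f"no serum/plasma ratio configured for {analyte!r}")
    if conc < 0:
        raise ValueError("concentration must be >= 0")
    return conc * ratios[analyte]


def percentage_error(modeled_mean: float, measured_mean: float) -> float:
    """Signed percentage error of the modeled mean, in percent."""
    if measured_mean <= 0:
        raise ValueError("percentage error undefined for measured mean <= 0")
    return 100.0 * (modeled_mean - measured_mean) / measured_mean


def mape(errors: Iterable[float]) -> float:
    """Mean absolute percentage error of a set of percentage errors."""
    errs = list(errors)
    if not errs:
        raise ValueError("mape of an empty list")
    return float(np.mean(np.abs(errs)))


def fold_ratio(modeled_mean: float, measured_mean: float) -> float:
    """Symmetric fold difference, always >= 1."""
    if modeled_mean <= 0 or measured_mean <= 0:
        raise ValueError("fold ratio requires positive inputs")
    r = modeled_mean / measured_mean
    return max(r, 1.0 / r)


def exceedance_fraction(
    ensemble: "Ensemble", matrix: str, threshold: float, date
) -> float:
    """Fraction of ensemble draws strictly above a threshold on one day."""
    vals = ensemble.at(date, matrix=matrix)
    return float((vals > threshold).mean())


def meta_pm(
    datasets: dict[str, pd.DataFrame],
    analyte: str | None = None,
    weights: str = "n",
    config: EvaluationConfig | None = None,
) -> dict:
    """Meta-analysis of tissue/serum partition coefficients.

    ``datasets`` maps a source label to a frame of paired records with
    columns ``tissue`` and ``serum`` (and optionally ``matrix``: rows with
    matrix == 'plasma' are converted to serum equivalents first; this
    requires ``analyte``).  Per-pair ratios tissue/serum are averaged per
    dataset; the meta-mean is the dataset-size-weighted mean of dataset
    means (``weights='equal'`` for a plain average), and the SD is the
    between-dataset spread.  Pairs with zero serum are excluded and
    counted.
    """
    means, ns = [], []
    excluded = 0
    for label, df in datasets.items():
        serum = df["serum"].astype(float).copy()
        if "matrix" in df.columns:
            is_plasma = df["matrix"] == "plasma"
            if is_plasma.any():
                if analyte is None:
                    raise ValueError("plasma records present: analyte required for conversion")
                serum[is_plasma] = [
                    plasma_to_serum(v, analyte, config) for v in serum[is_plasma]
                ]
        tissue = df["tissue"].astype(float)
        ok = serum > 0
        excluded += int((~ok).sum())
        if ok.sum() == 0:
            continue
        ratios = tissue[ok] / serum[ok]
        means.append(float(ratios.mean()))
        ns.append(int(ok.sum()))
    if not means:
        raise ValueError("no usable tissue/serum pairs")
    w = np.array(ns, dtype=float) if weights == "n" else np.ones(len(means))
    meta_mean = float(np.average(means, weights=w))
    between_sd = float(np.std(means, ddof=1)) if len(means) > 1 else 0.0
    return {
        "meta_mean": meta_mean,
        "between_sd": between_sd,
        "dataset_means": dict(zip(datasets.keys(), means)),
        "n_pairs": int(sum(ns)),
        "n_excluded": excluded,
    }


def evaluate_scenario(
    ensembles: "dict[str, Ensemble] | Ensemble",
    biomonitoring: pd.DataFrame,
    config: EvaluationConfig | None = None,
    scenario_label: str = "scenario",
) -> pd.DataFrame:
    """Compare ensembles to biomonitoring records, one row per
    (date, analyte, matrix) group.

    Plasma records are converted to serum equivalents and pooled with the
    same-day serum records; the ``plasma_converted`` column flags groups
    where the conversion was applied.  Matching is same-calendar-day
    against the ensemble member values; a sampling date outside the
    simulated range is an error.
    """
    from .poptk import Ensemble  # noqa: F401  (typing only)

    config = config or EvaluationConfig()
    if not isinstance(ensembles, dict):
        ensembles = {ensembles.analyte: ensembles}

    df = biomonitoring.copy()
    df["date"] = pd.to_datetime(df["date"])
    df["plasma_converted"] = df["matrix"] == "plasma"
    df.loc[df["plasma_converted"], "conc"] = [
        plasma_to_serum(v, a, config)
        for v, a in zip(
            df.loc[df["plasma_converted"], "conc"],
            df.loc[df["plasma_converted"], "analyte"],
        )
    ]
    df.loc[df["matrix"] == "plasma", "matrix"] = "serum"

    rows = []
    for (date, analyte, matrix), grp in df.groupby(["date", "analyte", "matrix"]):
        if analyte not in ensembles:
            continue
        ens = ensembles[analyte]
        try:
            modeled = ens.at(date, matrix=matrix)
        except KeyError:
            raise ValueError(
                f"biomonitoring date {pd.Timestamp(date).date()} is outside the "
                "simulated range"
            ) from None
        measured = grp["conc"].to_numpy(dtype=float)
        mmean = float(measured.mean())
        row = {
            "scenario": scenario_label,
            "date": pd.Timestamp(date).date(),
            "analyte": analyte,
            "matrix": matrix,
            "n": len(measured),
            "measured_mean": mmean,
            "measured_sd": float(measured.std(ddof=1)) if len(measured) > 1 else math.nan,
            "modeled_mean": float(modeled.mean()),
            "modeled_sd": float(modeled.std(ddof=1)) if len(modeled) > 1 else math.nan,
            "modeled_min": float(modeled.min()),
            "modeled_max": float(modeled.max()),
            "plasma_converted": bool(grp["plasma_converted"].any()),
        }
        row["pct_error"] = percentage_error(row["modeled_mean"], mmean) if mmean > 0 else math.nan
        row["fold_ratio"] = fold_ratio(row["modeled_mean"], mmean) if mmean > 0 else math.nan
        rows.append(row)
    report = pd.DataFrame(rows)
    if not report.empty:
        report["pct_error_display"] = report["pct_error"].round().astype("Int64")
    return report


def fit_dt50_loglinear(records: pd.DataFrame) -> dict:
    """Estimate an elimination half-life from depuration biomonitoring.

    ``records`` needs columns ``date`` and ``conc`` (one matrix, one
    analyte, zero-exposure phase).  A pooled log-linear regression
    ln(conc) ~ day gives slope -k and DT50 = ln 2 / k.
    """
    df = records.copy()
    df = df[df["conc"] > 0]
    if len(df) < 3:
        raise ValueError("need at least 3 positive records to fit a half-life")
    day = (pd.to_datetime(df["date"]) - pd.to_datetime(df["date"]).min()).dt.days.to_numpy()
    y = np.log(df["conc"].to_numpy(dtype=float))
    slope, intercept = np.polyfit(day, y, 1)
    if slope >= 0:
        raise ValueError("no decline in the data: half-life not estimable")
    k = -slope
    return {"k_per_day": float(k), "dt50_days": float(np.log(2.0) / k), "log_intercept": float(intercept)}


def seasonal_signature(
    ensemble: "Ensemble", life_history, matrix: str = "serum"
) -> pd.DataFrame:
    """Per-draw accumulation/depuration diagnostics.

    For each draw: the day of the trajectory maximum, whether it falls in a
    stored-feed window, and whether every stored-feed (winter) window shows
    net accumulation (end above start) while every grazing (summer) window
    shows net depuration (end below start).
    """
    dates = ensemble.dates
    in_stored = np.zeros(len(dates), dtype=bool)
    windows = {"stored": [], "pasture": []}
    for iv in life_history.intervals:
        mask = (dates >= pd.Timestamp(iv.start)) & (dates <= pd.Timestamp(iv.end))
        if iv.mode == "stored":
            in_stored |= mask
            windows["stored"].append(mask)
        elif iv.mode == "pasture":
            windows["pasture"].append(mask)

    vals = ensemble.values(matrix)
    rows = []
    for i in range(ensemble.n_draws):
        v = vals[i]
        imax = int(np.argmax(v))

        def _net(mask_list, sign):
            ok = True
            for m in mask_list:
                if not m.any():
                    continue
                idx = np.flatnonzero(m)
                if sign * (v[idx[-1]] - v[idx[0]]) <= 0:
                    ok = False
            return ok

        rows.append(
            {
                "draw_id": i,
                "max_date": dates[imax].date(),
                "max_value": float(v[imax]),
                "max_in_stored_window": bool(in_stored[imax]),
                "winters_accumulate": _net(windows["stored"], +1),
                "summers_depurate": _net(windows["pasture"], -1),
            }
        )
    return pd.DataFrame(rows)
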