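"""Trajectory figures: simulation traces, median, biomonitoring overlay,
and action-level reference lines."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .datasets import ACTION_LEVELS
from .poptk import Ensemble

__all__ = ["plot_ensemble"]

_UNITS = {"serum": "ng/mL", "muscle": "ng/g", "milk": "ng/mL"}


def plot_ensemble(
    ensemble: Ensemble,
    matrix: str = "muscle",
    biomonitoring: pd.DataFrame | None = None,
    action_levels: dict | None = None,
    ax=None,
):
    """One figure per matrix/analyte: all member traces, the per-day
    median, measured points if given, and horizontal threshold lines where
    they exist for the analyte/matrix (none are drawn otherwise)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(9, 4.5))
    vals = ensemble.values(matrix)
    ax.plot(ensemble.dates, vals.T, color="steelblue", alpha=0.15, lw=0.6)
    ax.plot(ensemble.dates, np.median(vals, axis=0), color="black", lw=1.5, label="median")

    if biomonitoring is not None and len(biomonitoring):
        sel = biomonitoring[
            (biomonitoring["matrix"] == matrix)
            & (biomonitoring["analyte"] == ensemble.analyte)
        ]
        if len(sel):
            ax.plot(
                pd.to_datetime(sel["date"]),
                sel["conc"],
                "^",
                color="crimson",
                ms=6,
                label="measured",
            )

    levels = (
        action_levels
        if action_levels is not None
        else ACTION_LEVELS.get((ensemble.analyte, matrix), {})
    )
    styles = {"maine_beef": "--", "eu_max": "-", "usda_screen": ":"}
    for label, threshold in levels.items():
        ax.axhline(threshold, ls=styles.get(label, "-."), color="dimgray", lw=1,
                   label=f"{label} ({threshold:g})")

    ax.set_ylabel(f"{ensemble.analyte} {matrix} ({_UNITS.get(matrix, '')})")
    ax.set_xlabel("date")
    ax.legend(loc="upper right", fontsize=8)
    return ax
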