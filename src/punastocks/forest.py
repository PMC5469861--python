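"""Per-plot stand-structure metrics for forest inventories.

A tree inventory is a DataFrame with one row per stem (>=10 cm
circumference at 130 cm): ``plot_id``, ``habitat``, ``species``,
``status`` ("live" or "deadwood"), ``dbh_cm``, ``height_m``.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .errors import DomainError

logger = logging.getLogger(__name__)

#: minimum qualifying dbh: stem circumference > 10 cm at breast height
MIN_DBH_CM = 10.0 / math.pi

TREE_COLUMNS = ["plot_id", "habitat", "species", "status", "dbh_cm", "height_m"]


def tree_basal_area(dbh_cm, mode: str = "metric"):
    """Cross-sectional stem area from diameter at breast height.

    ``metric`` returns pi * (dbh/200)^2 in m^2 for dbh in cm.
    ``as_printed`` returns pi * (dbh/2)^2 / 144, the US-customary
    (inches^2 -> feet^2) form kept for fidelity with the source formula;
    it is dimensionally inconsistent with metric per-hectare reporting
    and is never the default.
    """
    dbh = np.asarray(dbh_cm, dtype=float)
    if np.any(dbh < 0):
        raise DomainError("dbh must be non-negative")
    if mode == "metric":
        out = np.pi * (dbh / 200.0) ** 2
    elif mode == "as_printed":
        out = np.pi * (dbh / 2.0) ** 2 / 144.0
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(out) if out.ndim == 0 else out


def filter_inventory(trees: pd.DataFrame) -> pd.DataFrame:
    """Drop stems below the 10 cm circumference threshold, logging the count."""
    keep = trees["dbh_cm"] > MIN_DBH_CM
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.info("excluded %d stem(s) below the %.3f cm dbh threshold",
                    n_excluded, MIN_DBH_CM)
    return trees.loc[keep]


def stand_summary(trees: pd.DataFrame, plot_area_m2: float = 100.0,
                  mode: str = "metric") -> dict:
    """Stand-structure summary for the stems of a single plot.

    Basal areas are summed and scaled to m^2 ha^-1; stem density to
    stems ha^-1.  Mean dbh and height are reported both over all stems
    (live + deadwood) and over live stems only, since published per-plot
    means do not state which convention they use.  An empty plot yields
    zeros for the extensive quantities and NaN for the means.
    """
    if plot_area_m2 <= 0:
        raise DomainError("plot area must be positive")
    ha_factor = 10_000.0 / plot_area_m2
    if len(trees) == 0:
        return {
            "stand_basal_area_m2_ha": 0.0, "stem_density_ha": 0.0,
            "mean_dbh_cm": float("nan"), "mean_height_m": float("nan"),
            "mean_dbh_live_cm": float("nan"), "mean_height_live_m": float("nan"),
            "max_height_m": float("nan"), "deadwood_proportion": float("nan"),
            "n_stems": 0,
        }
    ba = tree_basal_area(trees["dbh_cm"], mode=mode)
    live = trees["status"] == "live"
    return {
        "stand_basal_area_m2_ha": float(np.sum(ba)) * ha_factor,
        "stem_density_ha": len(trees) * ha_factor,
        "mean_dbh_cm": float(trees["dbh_cm"].mean()),
        "mean_height_m": float(trees["height_m"].mean()),
        "mean_dbh_live_cm": float(trees.loc[live, "dbh_cm"].mean()),
        "mean_height_live_m": float(trees.loc[live, "height_m"].mean()),
        "max_height_m": float(trees["height_m"].max()),
        "deadwood_proportion": float((~live).mean()),
        "n_stems": len(trees),
    }


def summarize_plots(inventory: pd.DataFrame, plot_area_m2: float = 100.0,
                    mode: str = "metric") -> pd.DataFrame:
    """Per-plot stand summaries for a whole inventory (one row per plot)."""
    rows = []
    for pid, trees in inventory.groupby("plot_id", sort=True):
        row = {"plot_id": pid}
        if "habitat" in trees.columns:
            row["habitat"] = trees["habitat"].iloc[0]
        row.update(stand_summary(trees, plot_area_m2, mode))
        rows.append(row)
    return pd.DataFrame(rows)
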