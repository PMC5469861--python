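"""Aboveground tree carbon from dbh/height allometry.

The allometry chain is: dbh at 130 cm -> bole diameter at 50 cm via a
linear calibration, then dry biomass per tree (kg) from a log10
allometric model in tree height (m) and bole diameter (cm), then carbon
at an assumed fraction of dry mass (default 50%).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .errors import DomainError

logger = logging.getLogger(__name__)

# bole-diameter calibration: d50 = A * dbh + B  (cm)
D50_SLOPE = 1.1613
D50_INTERCEPT = 0.4628

# biomass = B0 + BH * log10(height m) + BD * log10(d50 cm), kg dry mass
BIOMASS_INTERCEPT = -16.51
BIOMASS_HEIGHT_COEF = 40.26
BIOMASS_DIAMETER_COEF = 9.30

DEFAULT_CARBON_FRACTION = 0.5


def dbh_to_d50(dbh_cm):
    """Bole diameter at 50 cm height from dbh (both cm)."""
    dbh = np.asarray(dbh_cm, dtype=float)
    if np.any(dbh < 0):
        raise DomainError("dbh must be non-negative")
    out = D50_SLOPE * dbh + D50_INTERCEPT
    return float(out) if out.ndim == 0 else out


def tree_biomass(height_m, d50_cm, scale: float = 1.0):
    """Aboveground dry biomass per tree, kg.

    Negative predictions (small trees outside the calibration range of
    the allometry) are floored at zero; a warning reports how many.
    ``scale`` rescales the output unit should a different mass unit be
    required.
    """
    h = np.asarray(height_m, dtype=float)
    d = np.asarray(d50_cm, dtype=float)
    if np.any(h <= 0) or np.any(d <= 0):
        raise DomainError("height and d50 must be positive")
    raw = (BIOMASS_INTERCEPT
           + BIOMASS_HEIGHT_COEF * np.log10(h)
           + BIOMASS_DIAMETER_COEF * np.log10(d))
    n_neg = int(np.sum(np.atleast_1d(raw) < 0))
    if n_neg:
        warnings.warn(f"{n_neg} tree(s) with negative allometric biomass "
                      "floored at 0", stacklevel=2)
    out = np.maximum(raw, 0.0) * scale
    return float(out) if out.ndim == 0 else out


def tree_carbon_table(inventory: pd.DataFrame,
                      carbon_fraction: float = DEFAULT_CARBON_FRACTION) -> pd.DataFrame:
    """Per-tree d50, biomass (kg) and carbon (kg C) appended to an inventory."""
    out = inventory.copy()
    out["d50_cm"] = dbh_to_d50(out["dbh_cm"])
    out["biomass_kg"] = tree_biomass(out["height_m"], out["d50_cm"])
    out["carbon_kg"] = carbon_fraction * out["biomass_kg"]
    return out


def plot_tree_carbon(trees: pd.DataFrame, plot_area_m2: float = 100.0,
                     carbon_fraction: float = DEFAULT_CARBON_FRACTION,
                     include_deadwood: bool = False) -> float:
    """Aboveground tree carbon stock of one plot, kg C m^-2.

    Live trees only by default; standing deadwood can be included but
    carries no assumption about decay-stage mass loss.
    """
    if plot_area_m2 <= 0:
        raise DomainError("plot area must be positive")
    if len(trees) == 0:
        return 0.0
    sel = trees if include_deadwood else trees[trees["status"] == "live"]
    if len(sel) == 0:
        return 0.0
    biomass = tree_biomass(sel["height_m"], dbh_to_d50(sel["dbh_cm"]))
    return float(np.sum(biomass)) * carbon_fraction / plot_area_m2


def summarize_plot_carbon(inventory: pd.DataFrame, plot_area_m2: float = 100.0,
                          carbon_fraction: float = DEFAULT_CARBON_FRACTION,
                          include_deadwood: bool = False) -> pd.DataFrame:
    """Per-plot tree carbon stocks (kg C m^-2), one row per plot."""
    rows = []
    for pid, trees in inventory.groupby("plot_id", sort=True):
        row = {"plot_id": pid}
        if "habitat" in trees.columns:
            row["habitat"] = trees["habitat"].iloc[0]
        row["tree_carbon_kg_m2"] = plot_tree_carbon(
            trees, plot_area_m2, carbon_fraction, include_deadwood)
        rows.append(row)
    return pd.DataFrame(rows)
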