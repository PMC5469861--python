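"""Habitat stock summaries and actual-vs-potential landscape carbon budgets.

The landscape is split into zonal-inaccessible, zonal-accessible and
azonal area fractions.  Under the *actual* scenario each accessibility
class carries its own observed forest/grassland split and per-m^2 habitat
stocks.  Under the *potential* (pre-impact) scenario all zonal area is
assigned the forest/grassland split and per-m^2 stocks observed in
inaccessible areas — a static extrapolation from the pristine relicts.
Azonal area (rock, moraine, bog, ...) carries zero stock in both
scenarios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError

logger = logging.getLogger(__name__)

HABITATS = ("inaccessible forest", "inaccessible grassland",
            "accessible forest", "accessible grassland")
POOLS = ("tree", "root", "soil")
STAT_NAMES = ("min", "q1", "mean", "q3", "max")


@dataclass(frozen=True)
class LandscapeAreas:
    """Mapped landscape composition.

    Fractions partition the mapped area into zonal-inaccessible,
    zonal-accessible and azonal classes (sum to 1); forest fractions give
    the forest share of the zonal area within each accessibility class.
    """
    total_mapped_area_m2: float
    zonal_inaccessible_fraction: float
    zonal_accessible_fraction: float
    azonal_fraction: float
    forest_fraction_inaccessible: float
    forest_fraction_accessible: float

    def __post_init__(self):
        if self.total_mapped_area_m2 <= 0:
            raise ConfigurationError("total_mapped_area_m2 must be positive")
        fracs = {
            "zonal_inaccessible_fraction": self.zonal_inaccessible_fraction,
            "zonal_accessible_fraction": self.zonal_accessible_fraction,
            "azonal_fraction": self.azonal_fraction,
            "forest_fraction_inaccessible": self.forest_fraction_inaccessible,
            "forest_fraction_accessible": self.forest_fraction_accessible,
        }
        for name, value in fracs.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        s = (self.zonal_inaccessible_fraction + self.zonal_accessible_fraction
             + self.azonal_fraction)
        if abs(s - 1.0) > 1e-9:
            raise ConfigurationError(
                f"landscape fractions must sum to 1 (got {s})")


def summarize_habitat_stocks(per_plot: pd.DataFrame) -> pd.DataFrame:
    """Five-number-plus-mean summary per habitat x carbon pool.

    ``per_plot`` needs columns ``habitat``, ``pool`` and
    ``stock_kg_m2``; empty habitat x pool groups are simply absent from
    the output (with a debug log), mirroring field campaigns where not
    every pool is measured in every habitat.
    """
    rows = []
    for (habitat, pool), grp in per_plot.groupby(["habitat", "pool"], sort=True):
        v = grp["stock_kg_m2"].to_numpy(dtype=float)
        if len(v) == 0:
            logger.warning("empty group %s/%s omitted", habitat, pool)
            continue
        rows.append({
            "habitat": habitat, "pool": pool,
            "min": float(np.min(v)),
            "q1": float(np.quantile(v, 0.25)),
            "mean": float(np.mean(v)),
            "q3": float(np.quantile(v, 0.75)),
            "max": float(np.max(v)),
            "n_plots": len(v),
        })
    return pd.DataFrame(rows)


def _cell(summaries: pd.DataFrame, habitat: str, pool: str, statistic: str) -> float:
    sel = summaries[(summaries["habitat"] == habitat) & (summaries["pool"] == pool)]
    if len(sel) == 0:
        raise DomainError(f"missing stock summary for {habitat!r} x {pool!r}")
    return float(sel[statistic].iloc[0])


def landscape_stock(areas: LandscapeAreas, summaries: pd.DataFrame,
                    scenario: str = "actual", statistic: str = "mean",
                    potential_stocks: str = "inaccessible") -> pd.Series:
    """Per-pool landscape carbon stock (kg C over the mapped area).

    ``scenario="actual"`` splits each accessibility class's zonal area by
    its own forest fraction and applies that class's habitat stocks.
    ``scenario="potential"`` applies the inaccessible forest fraction —
    and, by default, inaccessible habitat stocks — to all zonal area
    (``potential_stocks="accessible"`` is available as a sensitivity
    variant).  Azonal area contributes zero.
    """
    if statistic not in STAT_NAMES:
        raise ValueError(f"statistic must be one of {STAT_NAMES}")
    total = areas.total_mapped_area_m2
    area_in = total * areas.zonal_inaccessible_fraction
    area_ac = total * areas.zonal_accessible_fraction

    def class_stock(pool: str, area: float, forest_fraction: float, acc: str) -> float:
        forest = _cell(summaries, f"{acc} forest", pool, statistic)
        grass = _cell(summaries, f"{acc} grassland", pool, statistic)
        return area * (forest_fraction * forest + (1 - forest_fraction) * grass)

    out = {}
    for pool in POOLS:
        if scenario == "actual":
            out[pool] = (
                class_stock(pool, area_in, areas.forest_fraction_inaccessible,
                            "inaccessible")
                + class_stock(pool, area_ac, areas.forest_fraction_accessible,
                              "accessible"))
        elif scenario == "potential":
            out[pool] = class_stock(
                pool, area_in + area_ac, areas.forest_fraction_inaccessible,
                potential_stocks)
        else:
            raise ValueError(f"unknown scenario {scenario!r}")
    return pd.Series(out, name=f"{scenario}_{statistic}_kg")


@dataclass
class ScenarioResult:
    """Actual and potential landscape stocks per pool, with percent changes.

    ``percent_change = 100 * (actual - potential) / potential``; a
    decrease under human impact is negative.
    """
    table: pd.DataFrame = field(repr=False)
    forest_cover_loss_percent: float = float("nan")

    def change(self, pool: str) -> float:
        return float(self.table.set_index("pool").loc[pool, "percent_change"])


def scenario_change(actual: pd.Series, potential: pd.Series,
                    forest_cover_loss_percent: float = float("nan")) -> ScenarioResult:
    """Percent change per pool and for the pooled total."""
    pools = list(actual.index)
    rows = []
    for pool in pools + ["total"]:
        a = float(actual.sum()) if pool == "total" else float(actual[pool])
        p = float(potential.sum()) if pool == "total" else float(potential[pool])
        if p > 0:
            change = 100.0 * (a - p) / p
        else:
            logger.warning("zero potential stock for pool %r: change undefined", pool)
            change = float("nan")
        rows.append({"pool": pool, "actual_kg": a, "potential_kg": p,
                     "percent_change": change})
    return ScenarioResult(pd.DataFrame(rows), forest_cover_loss_percent)


def forest_cover_loss(areas: LandscapeAreas) -> float:
    """Percent of inaccessible-reference forest cover absent from accessible land.

    100 * (1 - forest_fraction_accessible / forest_fraction_inaccessible).
    """
    if areas.forest_fraction_inaccessible <= 0:
        raise DomainError("forest_fraction_inaccessible must be positive")
    return 100.0 * (1.0 - areas.forest_fraction_accessible
                    / areas.forest_fraction_inaccessible)
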