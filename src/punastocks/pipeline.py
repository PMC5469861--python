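"""End-to-end assembly: simulated (or loaded) inputs -> per-plot stocks ->
habitat summaries -> actual-vs-potential landscape scenario."""

from __future__ import annotations

import pandas as pd

from . import scenario as sc
from . import soil, trees
from .synthetic import GRASSLAND_HABITATS, SimConfig, simulate_all


def per_plot_stocks(inventory: pd.DataFrame, soil_layers: pd.DataFrame,
                    plot_area_m2: float = 100.0,
                    carbon_fraction: float = 0.5) -> pd.DataFrame:
    """Tidy per-plot carbon stocks (habitat, pool, stock in kg C m^-2).

    Tree stocks come from the forest inventory (live trees); root and
    soil stocks from the profile table.  Grassland habitats carry an
    explicit zero tree stock per soil-profile location, since treeless
    plots are observations of zero, not missing data.
    """
    tree = trees.summarize_plot_carbon(inventory, plot_area_m2,
                                       carbon_fraction)
    rows = [
        {"habitat": r.habitat, "pool": "tree", "stock_kg_m2": r.tree_carbon_kg_m2}
        for r in tree.itertuples()
    ]
    profiles = soil.summarize_profiles(soil_layers, carbon_fraction)
    for r in profiles.itertuples():
        rows.append({"habitat": r.habitat, "pool": "soil",
                     "stock_kg_m2": r.soc_stock_kg_m2})
        rows.append({"habitat": r.habitat, "pool": "root",
                     "stock_kg_m2": r.root_carbon_kg_m2})
        if r.habitat in GRASSLAND_HABITATS:
            rows.append({"habitat": r.habitat, "pool": "tree",
                         "stock_kg_m2": 0.0})
    return pd.DataFrame(rows)


def run_scenario(config: SimConfig, statistic: str = "mean"):
    """Simulate a study system and compute the landscape carbon scenario.

    Returns ``(summaries, result)``: the habitat x pool stock summary
    table and the :class:`~punastocks.scenario.ScenarioResult` with
    per-pool and total percent changes plus the forest-cover loss.
    """
    sim = simulate_all(config)
    stocks = per_plot_stocks(sim["inventory"], sim["soil_layers"])
    summaries = sc.summarize_habitat_stocks(stocks)
    areas = sim["areas"]
    actual = sc.landscape_stock(areas, summaries, "actual", statistic)
    potential = sc.landscape_stock(areas, summaries, "potential", statistic)
    result = sc.scenario_change(actual, potential, sc.forest_cover_loss(areas))
    return summaries, result
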