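import numpy as np
import pandas as pd
import pytest

from punastocks import SimConfig


def cation_columns(base_saturation_pct: float, ecec: float = 10.0) -> dict:
    """Exchangeable-cation columns realising a given base saturation."""
    bases = base_saturation_pct / 100.0 * ecec
    acids = ecec - bases
    return {
        "exch_ca": 0.6 * bases, "exch_mg": 0.25 * bases,
        "exch_k": 0.1 * bases, "exch_na": 0.05 * bases,
        "exch_al": 0.7 * acids, "exch_fe": 0.1 * acids,
        "exch_mn": 0.05 * acids, "exch_h": 0.15 * acids,
    }


def make_layers(specs, profile_id="P1", habitat="inaccessible forest",
                vegetation="forest"):
    """Layer table from a list of per-layer override dicts.

    Each spec needs at least top/bottom; everything else defaults to a
    rock-poor, carbon-rich, base-rich dark layer.
    """
    rows = []
    for i, spec in enumerate(specs):
        row = {
            "profile_id": profile_id, "habitat": habitat,
            "vegetation": vegetation, "layer_index": i,
            "volume_cm3": 1000.0, "fine_earth_g": 800.0, "rock_g": 200.0,
            "carbon_pct": 5.0, "nitrogen_pct": 0.4, "ph_cacl2": 4.5,
            **cation_columns(60.0),
            "munsell_value": 2, "munsell_chroma": 2,
            "root_subsample_soil_g": 20.0, "root_subsample_root_g": 0.2,
        }
        row.update(spec)
        rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture
def small_config():
    return SimConfig(seed=42, plots_per_habitat=5,
                     soil_profiles_per_habitat=6,
                     community_plots_per_habitat=8)


@pytest.fixture
def rng():
    return np.random.default_rng(20250930)
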