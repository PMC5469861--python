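"""Synthetic study-system generator.

Generates the four pipeline inputs — forest inventories, soil-profile
layer samples, plot x species community tables with species attributes,
and landscape area fractions — with the habitat contrasts of a
high-Andean forest/grassland mosaic split into human-accessible and
inaccessible (pristine) land:

* inaccessible forest has more stems, larger/taller trees and far more
  standing deadwood than accessible forest;
* grassland soils carry more soil organic carbon per area than forest
  soils but a lower base saturation (more acidic, Umbrisol-dominated);
* undescribed plant species concentrate in inaccessible plots,
  introduced aliens in accessible plots, widespread grazing/burning
  adapted generalists dominate accessible plots.

Every generator derives its own random stream from the single top-level
seed, so tables are reproducible independently of generation order, and
ground truth (per-profile stocks, WRB class, configured effects) is
returned alongside the tables for parameter-recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .scenario import LandscapeAreas
from .soil import LAYER_COLUMNS

#: standard sampling depth increments (cm); the last increment runs to
#: whatever depth continuous rock is met at
DEPTH_INCREMENTS_CM = (0.0, 5.0, 10.0, 20.0, 30.0, 40.0)

FOREST_HABITATS = ("inaccessible forest", "accessible forest")
GRASSLAND_HABITATS = ("inaccessible grassland", "accessible grassland")
ALL_HABITATS = FOREST_HABITATS + GRASSLAND_HABITATS

# fixed sub-stream identifiers (never reuse across generators)
_STREAM_FOREST, _STREAM_SOIL, _STREAM_COMMUNITY = 11, 22, 33


@dataclass
class HabitatEffects:
    """Habitat-level generator parameters.

    Tree parameters apply only to forest habitats; soil and herb-layer
    parameters to all.  ``soc_scale`` multiplies the baseline carbon
    concentration, ``base_saturation_shift`` moves the base-saturation
    target (percentage points) within its soil-class band, and
    ``root_density`` is root dry mass per fine-earth dry mass (g g^-1).
    """
    stems_per_plot: float = 0.0
    dbh_median_cm: float = 15.0
    height_scale: float = 1.2
    deadwood_fraction: float = 0.05
    herb_height_cm: float = 20.0
    soc_scale: float = 1.0
    base_saturation_shift: float = 0.0
    root_density: float = 0.005


@dataclass
class SpeciesPool:
    n_undescribed: int = 40
    n_introduced: int = 15
    n_native_widespread: int = 80


@dataclass
class TraitArchetypes:
    """Two opposed trait syndromes: grazing/burning-adapted vs not.

    Species near the adapted archetype (widespread natives, introduced
    aliens) carry its trait pattern with per-trait flip noise; undescribed
    pristine-habitat species carry the opposite pattern.
    """
    n_traits: int = 32
    n_ordinal: int = 4       # first traits on a 0-3 ordinal scale
    flip_probability: float = 0.15


@dataclass
class LandscapeConfig:
    """Mapped-area composition; defaults follow the study landscape
    (1.1% zonal-inaccessible / 56.9% zonal-accessible / 42.0% azonal,
    70% vs 7.5% forest cover)."""
    total_mapped_area_m2: float = 1.3266e11
    zonal_inaccessible_fraction: float = 0.011
    zonal_accessible_fraction: float = 0.569
    azonal_fraction: float = 0.420
    forest_fraction_inaccessible: float = 0.70
    forest_fraction_accessible: float = 0.075


def _default_habitat_effects() -> dict:
    return {
        "inaccessible forest": HabitatEffects(
            stems_per_plot=70, dbh_median_cm=18.0, height_scale=1.25,
            deadwood_fraction=0.30, herb_height_cm=35.0,
            soc_scale=1.0, base_saturation_shift=0.0, root_density=0.008),
        "accessible forest": HabitatEffects(
            stems_per_plot=35, dbh_median_cm=14.0, height_scale=1.10,
            deadwood_fraction=0.05, herb_height_cm=12.0,
            soc_scale=1.0, base_saturation_shift=0.0, root_density=0.008),
        "inaccessible grassland": HabitatEffects(
            herb_height_cm=30.0, soc_scale=1.25, base_saturation_shift=-3.0,
            root_density=0.002),
        "accessible grassland": HabitatEffects(
            herb_height_cm=10.0, soc_scale=1.25, base_saturation_shift=-3.0,
            root_density=0.002),
    }


# WRB class mix per vegetation type: forest soils mostly base-rich
# Phaeozems, grassland soils mostly acidic Umbrisols, shallow Leptosols
# on both.
_CLASS_PROBS = {
    "forest": {"Phaeozem": 0.75, "Umbrisol": 0.15, "Mollic Leptosol": 0.10,
               "Leptosol": 0.0},
    "grassland": {"Phaeozem": 0.18, "Umbrisol": 0.65, "Mollic Leptosol": 0.12,
                  "Leptosol": 0.05},
}
_HIGH_BS_CLASSES = ("Phaeozem", "Mollic Leptosol")
_SHALLOW_CLASSES = ("Mollic Leptosol", "Leptosol")


@dataclass
class SimConfig:
    """Top-level simulation configuration (one seed, all tables)."""
    seed: int = 0
    n_sites: int = 8
    plots_per_habitat: int = 24          # 10 x 10 m forest-inventory plots
    soil_profiles_per_habitat: int = 12
    community_plots_per_habitat: int = 30  # 2 x 2 m vegetation plots
    habitat_effects: dict = field(default_factory=_default_habitat_effects)
    species_pool: SpeciesPool = field(default_factory=SpeciesPool)
    trait_archetypes: TraitArchetypes = field(default_factory=TraitArchetypes)
    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)

    def validate(self) -> "SimConfig":
        counts = {"n_sites": self.n_sites,
                  "plots_per_habitat": self.plots_per_habitat,
                  "soil_profiles_per_habitat": self.soil_profiles_per_habitat,
                  "community_plots_per_habitat": self.community_plots_per_habitat}
        for name, v in counts.items():
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ConfigurationError(f"{name} must be a non-negative integer")
        for name in ("n_undescribed", "n_introduced", "n_native_widespread"):
            if getattr(self.species_pool, name) < 0:
                raise ConfigurationError(f"species_pool.{name} must be >= 0")
        for hab in ALL_HABITATS:
            if hab not in self.habitat_effects:
                raise ConfigurationError(f"habitat_effects missing {hab!r}")
            eff = self.habitat_effects[hab]
            if not 0.0 <= eff.deadwood_fraction <= 1.0:
                raise ConfigurationError(
                    f"habitat_effects[{hab!r}].deadwood_fraction must be in [0, 1]")
            for fname in ("stems_per_plot", "dbh_median_cm", "height_scale",
                          "herb_height_cm", "soc_scale", "root_density"):
                if getattr(eff, fname) < 0:
                    raise ConfigurationError(
                        f"habitat_effects[{hab!r}].{fname} must be >= 0")
        ta = self.trait_archetypes
        if not 0.0 <= ta.flip_probability <= 1.0:
            raise ConfigurationError("trait_archetypes.flip_probability must be in [0, 1]")
        if not 0 <= ta.n_ordinal <= ta.n_traits:
            raise ConfigurationError("trait_archetypes.n_ordinal must be <= n_traits")
        LandscapeAreas(**asdict(self.landscape))  # validates fractions
        return self

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


def landscape_areas(config: SimConfig) -> LandscapeAreas:
    """The configured landscape composition as a validated LandscapeAreas."""
    return LandscapeAreas(**asdict(config.landscape))


# ---------------------------------------------------------------------------
# forest inventory
# ---------------------------------------------------------------------------

def generate_forest_inventory(config: SimConfig) -> pd.DataFrame:
    """10 x 10 m forest-plot tree inventory (one row per stem).

    dbh is lognormal with a habitat-specific median, height follows a
    power law in dbh with multiplicative noise (hence positively
    correlated), and the standing-deadwood flag is Bernoulli with a
    habitat-specific rate.
    """
    config.validate()
    rng = config.rng(_STREAM_FOREST)
    rows = []
    for hab_idx, habitat in enumerate(FOREST_HABITATS):
        eff = config.habitat_effects[habitat]
        prefix = "IF" if habitat.startswith("inaccessible") else "AF"
        for p in range(config.plots_per_habitat):
            plot_id = f"{prefix}{p + 1:03d}"
            n = rng.poisson(eff.stems_per_plot)
            dbh = np.exp(rng.normal(np.log(eff.dbh_median_cm), 0.35, n))
            height = eff.height_scale * dbh ** 0.6 * np.exp(rng.normal(0, 0.15, n))
            dead = rng.random(n) < eff.deadwood_fraction
            species = rng.choice(["Polylepis sp. A", "Polylepis sp. B",
                                  "Gynoxys sp."], size=n, p=[0.6, 0.3, 0.1])
            for i in range(n):
                rows.append((plot_id, habitat, species[i],
                             "deadwood" if dead[i] else "live",
                             float(dbh[i]), float(height[i])))
    return pd.DataFrame(rows, columns=["plot_id", "habitat", "species",
                                       "status", "dbh_cm", "height_m"])


# ---------------------------------------------------------------------------
# soil profiles
# ---------------------------------------------------------------------------

def _layer_edges(depth_cm: float) -> list[tuple[float, float]]:
    edges = [b for b in DEPTH_INCREMENTS_CM if b < depth_cm] + [depth_cm]
    return list(zip(edges[:-1], edges[1:]))


def generate_soil_profiles(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Layer-sample table plus per-profile ground truth.

    Each profile is assigned a target WRB class first (class mix depends
    on vegetation type), and its class-determining fields — depth to
    rock, rock volume, base saturation, Munsell colour, carbon — are
    drawn with safety margins away from every rule boundary, so the
    generating class is recoverable exactly.  Ground-truth stocks are
    accumulated with the generator's own layer arithmetic.

    Returns ``(layers, truth)`` where ``truth`` has one row per profile
    with the generating class and true stocks.
    """
    config.validate()
    rng = config.rng(_STREAM_SOIL)
    layer_rows = []
    truth_rows = []
    pid_counter = 0
    for habitat in ALL_HABITATS:
        eff = config.habitat_effects[habitat]
        vegetation = "forest" if "forest" in habitat else "grassland"
        probs = _CLASS_PROBS[vegetation]
        classes = list(probs)
        pvec = np.array([probs[c] for c in classes])
        for _ in range(config.soil_profiles_per_habitat):
            pid_counter += 1
            profile_id = f"P{pid_counter:04d}"
            cls = classes[rng.choice(len(classes), p=pvec)]
            depth = (rng.uniform(15.0, 24.0) if cls in _SHALLOW_CLASSES
                     else rng.uniform(28.0, 90.0))
            depth = round(float(depth), 1)
            if cls in _HIGH_BS_CLASSES:
                bs_target = np.clip(rng.uniform(58, 88)
                                    + eff.base_saturation_shift, 55, 92)
            else:
                bs_target = np.clip(rng.uniform(15, 42)
                                    + eff.base_saturation_shift, 8, 45)

            soc = nitrogen = root = fe_mass = 0.0
            bs_wsum = 0.0
            for li, (top, bottom) in enumerate(_layer_edges(depth)):
                mid = 0.5 * (top + bottom)
                volume = rng.uniform(800, 1200)
                rho_w = float(np.clip(rng.normal(1.0, 0.08), 0.6, 1.5))
                rock_frac = rng.uniform(0.05, 0.30)
                w_total = rho_w * volume
                w_rock = rock_frac * w_total
                w_fe = w_total - w_rock
                conc = float(np.clip(
                    2.5 * eff.soc_scale * (0.6 + 0.4 * np.exp(-mid / 30.0))
                    * np.exp(rng.normal(0, 0.10)), 0.8, 15.0))
                n_conc = conc / 12.0 * float(np.exp(rng.normal(0, 0.05)))
                lo, hi = (55.0, 92.0) if cls in _HIGH_BS_CLASSES else (8.0, 45.0)
                bs_layer = float(np.clip(bs_target + rng.normal(0, 1.5), lo, hi))
                ecec = float(np.clip(rng.normal(15, 3), 5, 30))
                bases = bs_layer / 100.0 * ecec
                acids = ecec - bases
                rl = (eff.root_density * 1.3 * np.exp(-mid / 40.0)
                      * float(np.exp(rng.normal(0, 0.25))))
                layer_rows.append({
                    "profile_id": profile_id, "habitat": habitat,
                    "vegetation": vegetation, "layer_index": li,
                    "top_cm": top, "bottom_cm": bottom,
                    "volume_cm3": volume, "fine_earth_g": w_fe,
                    "rock_g": w_rock, "carbon_pct": conc,
                    "nitrogen_pct": n_conc,
                    "ph_cacl2": float(np.clip(rng.normal(4.6, 0.25), 3.5, 6.5)),
                    "exch_ca": 0.60 * bases, "exch_mg": 0.25 * bases,
                    "exch_k": 0.10 * bases, "exch_na": 0.05 * bases,
                    "exch_al": 0.70 * acids, "exch_fe": 0.10 * acids,
                    "exch_mn": 0.05 * acids, "exch_h": 0.15 * acids,
                    "munsell_value": int(rng.integers(2, 4)),
                    "munsell_chroma": int(rng.integers(2, 4)),
                    "root_subsample_soil_g": 20.0,
                    "root_subsample_root_g": rl * 20.0,
                })
                # ground truth with the generator's own arithmetic
                h_mm = (bottom - top) * 10.0
                m_w = rho_w * h_mm
                m_fe = m_w * w_fe / (w_fe + w_rock)
                fe_mass += m_fe
                soc += conc / 100.0 * m_fe
                nitrogen += n_conc / 100.0 * m_fe
                root += rl * m_fe
                bs_wsum += bs_layer * m_fe
            truth_rows.append({
                "profile_id": profile_id, "habitat": habitat,
                "vegetation": vegetation, "true_class": cls,
                "total_depth_cm": depth,
                "true_fine_earth_mass_kg_m2": fe_mass,
                "true_soc_stock_kg_m2": soc,
                "true_nitrogen_stock_kg_m2": nitrogen,
                "true_root_biomass_kg_m2": root,
                "true_base_saturation_pct": bs_wsum / fe_mass,
            })
    layers = pd.DataFrame(layer_rows, columns=LAYER_COLUMNS)
    return layers, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# community table
# ---------------------------------------------------------------------------

def _species_frame(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Species attribute table: status, origin, latitudinal range, traits."""
    pool = config.species_pool
    ta = config.trait_archetypes
    recs = []
    kinds = ([("und", "undescribed", "native")] * pool.n_undescribed
             + [("int", "described", "introduced")] * pool.n_introduced
             + [("wid", "described", "native")] * pool.n_native_widespread)
    counters = {"und": 0, "int": 0, "wid": 0}
    for kind, status, origin in kinds:
        counters[kind] += 1
        name = f"{kind}_{counters[kind]:03d}"
        if kind == "und":
            lat = rng.uniform(5, 120)       # narrow endemics
        elif kind == "wid":
            lat = rng.uniform(600, 4000)    # Andes-wide generalists
        else:
            lat = rng.uniform(1000, 5000)   # cosmopolitan aliens
        # archetype A = grazing/burning adapted (aliens + generalists)
        adapted = kind != "und"
        traits = {}
        for t in range(ta.n_traits):
            base = 1 if adapted else 0
            bit = base if rng.random() >= ta.flip_probability else 1 - base
            if t < ta.n_ordinal:  # ordinal 0-3 scale
                val = int(np.clip((3 if bit else 0) + rng.integers(-1, 2), 0, 3))
            else:
                val = bit
            traits[f"trait_{t + 1:02d}"] = val
        recs.append({"species": name, "status": status, "origin": origin,
                     "latitudinal_range_min": lat, **traits})
    return pd.DataFrame(recs).set_index("species")


# per-species plot-occupancy probability by accessibility class
_OCCUPANCY = {
    "und": {"inaccessible": 0.45, "accessible": 0.02},
    "int": {"inaccessible": 0.01, "accessible": 0.35},
    "wid": {"inaccessible": 0.20, "accessible": 0.55},
}
_COVER_MEDIAN = {"und": 8.0, "int": 4.0, "wid": 3.0}


def generate_community(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """2 x 2 m plot x species percent-cover matrix plus metadata.

    Returns ``(cover, plot_info, attributes)``: cover is plots x species
    in percent; ``plot_info`` carries the habitat label, grazed-cover
    percent and mean herb height per plot; ``attributes`` is the
    per-species table (status, origin, latitudinal range, traits).
    """
    config.validate()
    rng = config.rng(_STREAM_COMMUNITY)
    attributes = _species_frame(config, rng)
    kinds = attributes.index.str.slice(0, 3)
    plot_ids, habitats, grazed, herb = [], [], [], []
    cover_rows = []
    for habitat in ALL_HABITATS:
        eff = config.habitat_effects[habitat]
        access = habitat.split()[0]
        prefix = "".join(w[0].upper() for w in habitat.split())
        occ = np.array([_OCCUPANCY[k][access] for k in kinds])
        med = np.array([_COVER_MEDIAN[k] for k in kinds])
        for p in range(config.community_plots_per_habitat):
            plot_ids.append(f"V{prefix}{p + 1:03d}")
            habitats.append(habitat)
            if access == "accessible":
                grazed.append(float(rng.uniform(20, 70)))
            else:
                grazed.append(float(rng.uniform(0, 8)))
            herb.append(float(np.clip(rng.normal(eff.herb_height_cm,
                                                 0.25 * eff.herb_height_cm + 1),
                                      0.5, 150)))
            present = rng.random(len(attributes)) < occ
            cov = np.where(
                present,
                np.clip(med * np.exp(rng.normal(0, 1.0, len(attributes))),
                        0.1, 100.0),
                0.0)
            cover_rows.append(cov)
    cover = pd.DataFrame(cover_rows, index=plot_ids, columns=attributes.index)
    cover.index.name = "plot_id"
    plot_info = pd.DataFrame({"habitat": habitats, "grazed_cover_pct": grazed,
                              "herb_height_cm": herb}, index=plot_ids)
    plot_info.index.name = "plot_id"
    return cover, plot_info, attributes


# ---------------------------------------------------------------------------
# configuration I/O
# ---------------------------------------------------------------------------

def config_from_dict(d: dict) -> SimConfig:
    """Build a validated SimConfig from a (possibly partial) nested dict."""
    d = dict(d)
    kwargs = {}
    for key in ("seed", "n_sites", "plots_per_habitat",
                "soil_profiles_per_habitat", "community_plots_per_habitat"):
        if key in d:
            kwargs[key] = d.pop(key)
    if "habitat_effects" in d:
        eff = _default_habitat_effects()
        for hab, overrides in d.pop("habitat_effects").items():
            if hab not in eff:
                raise ConfigurationError(f"habitat_effects has unknown habitat {hab!r}")
            eff[hab] = HabitatEffects(**{**asdict(eff[hab]), **overrides})
        kwargs["habitat_effects"] = eff
    for key, cls in (("species_pool", SpeciesPool),
                     ("trait_archetypes", TraitArchetypes),
                     ("landscape", LandscapeConfig)):
        if key in d:
            kwargs[key] = cls(**d.pop(key))
    if d:
        raise ConfigurationError(f"unknown configuration field(s): {sorted(d)}")
    return SimConfig(**kwargs).validate()


def load_config(path: str | Path) -> SimConfig:
    """Read a SimConfig from a YAML file."""
    import yaml

    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh) or {})


# ---------------------------------------------------------------------------
# one-call simulation with on-disk output
# ---------------------------------------------------------------------------

def simulate_all(config: SimConfig, outdir: str | Path | None = None) -> dict:
    """Generate every pipeline input; optionally write CSVs + truth JSON.

    Returns a dict with keys ``inventory``, ``soil_layers``,
    ``soil_truth``, ``cover``, ``plot_info``, ``attributes`` and
    ``areas``.
    """
    config.validate()
    inventory = generate_forest_inventory(config)
    soil_layers, soil_truth = generate_soil_profiles(config)
    cover, plot_info, attributes = generate_community(config)
    areas = landscape_areas(config)
    out = {"inventory": inventory, "soil_layers": soil_layers,
           "soil_truth": soil_truth, "cover": cover, "plot_info": plot_info,
           "attributes": attributes, "areas": areas}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        inventory.to_csv(outdir / "forest_inventory.csv", index=False)
        soil_layers.to_csv(outdir / "soil_layers.csv", index=False)
        cover.to_csv(outdir / "community_cover.csv")
        plot_info.to_csv(outdir / "community_plots.csv")
        attributes.to_csv(outdir / "species_attributes.csv")
        truth = {
            "config": {"seed": config.seed,
                       "landscape": asdict(config.landscape),
                       "habitat_effects": {k: asdict(v) for k, v in
                                           config.habitat_effects.items()}},
            "soil_profiles": soil_truth.to_dict(orient="records"),
        }
        (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=1))
    return out
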