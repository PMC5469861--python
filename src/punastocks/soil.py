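"""Soil profile mass, carbon and nutrient accounting.

Implements the fine-earth mass bookkeeping used for volumetric soil
samples with rock fragments, stock conversion of element concentrations,
root-biomass scaling from washed subsamples, exchangeable-cation
bookkeeping (base saturation), and a rule-based WRB-style classification
into Mollic Leptosol / Leptosol / Phaeozem / Umbrisol.

A soil profile is represented as a pandas DataFrame with one row per
depth layer (see :data:`LAYER_COLUMNS`).  Masses are oven-dry grams per
volumetric sample, depths in cm, element concentrations in percent of
fine earth, exchangeable cations in cmol(+) kg^-1.

Unit contract of the mass chain: a weathered bulk density in g cm^-3
multiplied by a layer height in **mm** is numerically equal to the layer
mass in kg m^-2 (1 g cm^-3 x 1 mm = 1 kg m^-2).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import DomainError

logger = logging.getLogger(__name__)

ROCK_DENSITY_G_CM3 = 2.65  # assumed density of rock fragments

#: exchangeable base cations and the acidity cations (cmol(+) kg^-1 columns)
BASE_CATIONS = ("exch_ca", "exch_mg", "exch_k", "exch_na")
ACID_CATIONS = ("exch_al", "exch_fe", "exch_mn", "exch_h")

#: column layout of a layer-sample table
LAYER_COLUMNS = [
    "profile_id", "habitat", "vegetation", "layer_index",
    "top_cm", "bottom_cm", "volume_cm3", "fine_earth_g", "rock_g",
    "carbon_pct", "nitrogen_pct", "ph_cacl2",
    *BASE_CATIONS, *ACID_CATIONS,
    "munsell_value", "munsell_chroma",
    "root_subsample_soil_g", "root_subsample_root_g",
]


# ---------------------------------------------------------------------------
# layer-level arithmetic
# ---------------------------------------------------------------------------

def weathered_bulk_density(fine_earth_g, rock_g, volume_cm3):
    """Bulk density of the weathered pedon (fine earth + rocks), g cm^-3.

    rho_w = (W_fe + W_r) / V for each layer sample.
    """
    fine_earth_g = np.asarray(fine_earth_g, dtype=float)
    rock_g = np.asarray(rock_g, dtype=float)
    volume_cm3 = np.asarray(volume_cm3, dtype=float)
    if np.any(volume_cm3 <= 0):
        raise DomainError("sample volume must be positive")
    if np.any(fine_earth_g < 0) or np.any(rock_g < 0):
        raise DomainError("sample masses must be non-negative")
    out = (fine_earth_g + rock_g) / volume_cm3
    return float(out) if out.ndim == 0 else out


def layer_weathered_mass(rho_w_g_cm3, height_mm):
    """Mass of the weathered pedon per ground area for one layer, kg m^-2.

    M_w = rho_w * h with h in mm; the unit conversion factor is exactly 1.
    """
    rho = np.asarray(rho_w_g_cm3, dtype=float)
    h = np.asarray(height_mm, dtype=float)
    if np.any(h < 0):
        raise DomainError("layer height must be non-negative")
    out = rho * h
    return float(out) if out.ndim == 0 else out


def fine_earth_bulk_density(fine_earth_g, rock_g, volume_cm3):
    """Bulk density of the fine earth alone, g cm^-3.

    rho_fe = W_fe / (V - W_r / 2.65), subtracting the volume occupied by
    rock fragments at an assumed rock density of 2.65 g cm^-3.
    """
    fine_earth_g = np.asarray(fine_earth_g, dtype=float)
    rock_g = np.asarray(rock_g, dtype=float)
    volume_cm3 = np.asarray(volume_cm3, dtype=float)
    fe_volume = volume_cm3 - rock_g / ROCK_DENSITY_G_CM3
    if np.any(fe_volume <= 0):
        bad = np.atleast_1d(fe_volume <= 0)
        raise DomainError(
            f"rock volume >= sample volume in {int(bad.sum())} layer(s); "
            "fine-earth bulk density undefined"
        )
    out = fine_earth_g / fe_volume
    return float(out) if out.ndim == 0 else out


def layer_fine_earth_mass(weathered_mass_kg_m2, fine_earth_g, rock_g):
    """Fine-earth share of a layer's weathered mass, kg m^-2.

    Algebraic form M_w * W_fe / (W_fe + W_r); a layer with no fine earth
    contributes zero (logged).
    """
    mw = np.asarray(weathered_mass_kg_m2, dtype=float)
    wfe = np.asarray(fine_earth_g, dtype=float)
    wr = np.asarray(rock_g, dtype=float)
    total = wfe + wr
    frac = np.divide(wfe, total, out=np.zeros_like(mw, dtype=float),
                     where=total > 0)
    n_zero = int(np.sum((wfe == 0) & (wr > 0)))
    if n_zero:
        logger.info("%d layer(s) with no fine earth contribute zero mass", n_zero)
    out = mw * frac
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# profile-level accounting
# ---------------------------------------------------------------------------

def _layer_masses(layers: pd.DataFrame) -> pd.DataFrame:
    """Per-layer mass bookkeeping columns for one profile's layer table."""
    h_mm = (layers["bottom_cm"] - layers["top_cm"]).to_numpy() * 10.0
    if np.any(h_mm <= 0):
        raise DomainError("layer bottom depth must exceed top depth")
    rho_w = weathered_bulk_density(
        layers["fine_earth_g"], layers["rock_g"], layers["volume_cm3"])
    mw = layer_weathered_mass(rho_w, h_mm)
    mfe = layer_fine_earth_mass(mw, layers["fine_earth_g"], layers["rock_g"])
    return pd.DataFrame({
        "height_mm": h_mm,
        "rho_w": np.atleast_1d(rho_w),
        "weathered_mass_kg_m2": np.atleast_1d(mw),
        "fine_earth_mass_kg_m2": np.atleast_1d(mfe),
    }, index=layers.index)


def profile_fine_earth_mass(layers: pd.DataFrame, form: str = "algebraic") -> float:
    """Total fine-earth mass of a profile, kg m^-2.

    ``form="printed"`` evaluates sum_i M_w,i * 100 / ((W_r,i/W_fe,i * 100) + 100);
    ``form="algebraic"`` the equivalent sum_i M_w,i * W_fe,i / (W_fe,i + W_r,i),
    which also handles fine-earth-free layers.  The two agree to 1e-9
    relative whenever both are defined.
    """
    m = _layer_masses(layers)
    if form == "algebraic":
        return float(m["fine_earth_mass_kg_m2"].sum())
    if form == "printed":
        wfe = layers["fine_earth_g"].to_numpy(dtype=float)
        wr = layers["rock_g"].to_numpy(dtype=float)
        if np.any(wfe == 0):
            raise DomainError("printed form undefined for a layer with W_fe = 0")
        mw = m["weathered_mass_kg_m2"].to_numpy()
        return float(np.sum(mw * 100.0 / ((wr / wfe * 100.0) + 100.0)))
    raise ValueError(f"unknown form {form!r}")


def profile_element_stock(layers: pd.DataFrame, concentration_col: str = "carbon_pct") -> float:
    """Element stock of a profile, kg m^-2.

    Sum over layers of (concentration % / 100) x layer fine-earth mass.
    """
    conc = layers[concentration_col]
    if conc.isna().any():
        missing = layers.loc[conc.isna(), "layer_index"].tolist()
        raise DomainError(
            f"missing {concentration_col} in layer(s) {missing}")
    m = _layer_masses(layers)
    return float((conc.to_numpy(dtype=float) / 100.0
                  * m["fine_earth_mass_kg_m2"].to_numpy()).sum())


def profile_carbon_stock(layers: pd.DataFrame) -> tuple[float, float]:
    """(SOC stock, N stock) of a profile, kg m^-2 each."""
    return (profile_element_stock(layers, "carbon_pct"),
            profile_element_stock(layers, "nitrogen_pct"))


def root_stock(layers: pd.DataFrame, carbon_fraction: float = 0.5) -> tuple[float, float]:
    """Root biomass and root carbon of a profile, kg m^-2.

    Each layer's root density is the washed-subsample root mass divided
    by the subsample soil mass; scaled by the layer fine-earth mass and
    summed over the profile.  Dead and live roots are pooled.
    """
    sub_soil = layers["root_subsample_soil_g"].to_numpy(dtype=float)
    sub_root = layers["root_subsample_root_g"].to_numpy(dtype=float)
    if np.any(sub_soil <= 0):
        raise DomainError("root subsample soil mass must be positive")
    if np.any(sub_root < 0):
        raise DomainError("root subsample root mass must be non-negative")
    m = _layer_masses(layers)
    biomass = float(np.sum(sub_root / sub_soil
                           * m["fine_earth_mass_kg_m2"].to_numpy()))
    return biomass, biomass * carbon_fraction


def base_saturation(exch: pd.Series | dict) -> float:
    """Base saturation in percent of effective CEC.

    100 * (Ca + Mg + K + Na) / (Ca + Mg + K + Na + Al + Fe + Mn + H).
    Returns NaN (flagged missing) when the effective CEC is zero.
    """
    vals = {k: float(exch[k]) for k in BASE_CATIONS + ACID_CATIONS}
    if any(v < 0 for v in vals.values()):
        raise DomainError("exchangeable cation values must be non-negative")
    bases = sum(vals[k] for k in BASE_CATIONS)
    ecec = bases + sum(vals[k] for k in ACID_CATIONS)
    if ecec == 0:
        logger.warning("all-zero ECEC: base saturation undefined")
        return float("nan")
    return 100.0 * bases / ecec


def profile_base_saturation(layers: pd.DataFrame) -> float:
    """Fine-earth-mass-weighted mean base saturation of a profile, %.

    Mass weighting matches the stock bookkeeping: a thick, heavy layer
    dominates the profile's exchange complex.
    """
    m = _layer_masses(layers)
    bs = layers.apply(base_saturation, axis=1).to_numpy(dtype=float)
    w = m["fine_earth_mass_kg_m2"].to_numpy()
    if np.all(np.isnan(bs)) or w.sum() == 0:
        return float("nan")
    ok = ~np.isnan(bs)
    return float(np.average(bs[ok], weights=w[ok]))


def rock_volume_fraction(layers: pd.DataFrame) -> float:
    """Depth-weighted rock volume fraction of a profile.

    Per layer (W_r / 2.65) / V, weighted by layer thickness.
    """
    frac = (layers["rock_g"].to_numpy(dtype=float) / ROCK_DENSITY_G_CM3
            / layers["volume_cm3"].to_numpy(dtype=float))
    h = (layers["bottom_cm"] - layers["top_cm"]).to_numpy(dtype=float)
    return float(np.average(frac, weights=h))


def rock_mass_fraction(layers: pd.DataFrame) -> float:
    """Rock share of total weathered mass of the profile."""
    m = _layer_masses(layers)
    mw = m["weathered_mass_kg_m2"].sum()
    return float(1.0 - m["fine_earth_mass_kg_m2"].sum() / mw) if mw > 0 else float("nan")


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

MOLLIC_MIN_CARBON_PCT = 0.6
MOLLIC_MAX_MUNSELL = 3
MOLLIC_MIN_BASE_SAT = 50.0
MOLLIC_MIN_THICKNESS_CM = 10.0
LEPTOSOL_MAX_DEPTH_CM = 25.0
LEPTOSOL_MIN_ROCK_VOL = 0.80
PHAEOZEM_MIN_BASE_SAT = 50.0


def _is_mollic(layers: pd.DataFrame, total_depth: float, bs: float) -> bool:
    """Mollic-horizon check for a single dark A-horizon over rock.

    Criteria: >=0.6% organic carbon, Munsell value and chroma <=3,
    base saturation >=50%, >=10 cm thickness overlying continuous rock.
    The carbon-excess-over-parent-material criterion cannot be evaluated
    without parent-material analyses and is treated as satisfied.
    """
    m = _layer_masses(layers)
    w = m["fine_earth_mass_kg_m2"].to_numpy()
    c = layers["carbon_pct"].to_numpy(dtype=float)
    mean_c = float(np.average(c, weights=w)) if w.sum() > 0 else float(np.mean(c))
    dark = (layers["munsell_value"].le(MOLLIC_MAX_MUNSELL).all()
            and layers["munsell_chroma"].le(MOLLIC_MAX_MUNSELL).all())
    return (mean_c >= MOLLIC_MIN_CARBON_PCT and dark
            and bs >= MOLLIC_MIN_BASE_SAT
            and total_depth >= MOLLIC_MIN_THICKNESS_CM)


def classify_profile(layers: pd.DataFrame, total_depth_cm: float | None = None) -> str:
    """Rule-based WRB-style classification of a single-A-horizon profile.

    Rule order: (1) a profile <=25 cm deep to continuous rock, or with
    >=80% rock by volume, is a Leptosol, qualified Mollic when the
    mollic-horizon criteria hold; (2) otherwise a profile-weighted base
    saturation >=50% gives a Phaeozem; (3) otherwise an Umbrisol.

    Returns ``"undetermined: <reason>"`` when a required input is absent.
    """
    required = ["carbon_pct", "munsell_value", "munsell_chroma",
                *BASE_CATIONS, *ACID_CATIONS]
    for col in required:
        if col not in layers.columns or layers[col].isna().any():
            return f"undetermined: missing {col}"
    if total_depth_cm is None:
        total_depth_cm = float(layers["bottom_cm"].max())
    bs = profile_base_saturation(layers)
    if np.isnan(bs):
        return "undetermined: base saturation undefined (zero ECEC)"
    if (total_depth_cm <= LEPTOSOL_MAX_DEPTH_CM
            or rock_volume_fraction(layers) >= LEPTOSOL_MIN_ROCK_VOL):
        if _is_mollic(layers, total_depth_cm, bs):
            return "Mollic Leptosol"
        return "Leptosol"
    if bs >= PHAEOZEM_MIN_BASE_SAT:
        return "Phaeozem"
    return "Umbrisol"


# ---------------------------------------------------------------------------
# per-profile summary table
# ---------------------------------------------------------------------------

def summarize_profiles(layer_table: pd.DataFrame,
                       root_carbon_fraction: float = 0.5) -> pd.DataFrame:
    """One-row-per-profile stock and classification summary.

    Parameters
    ----------
    layer_table
        Layer samples for any number of profiles (:data:`LAYER_COLUMNS`).
    root_carbon_fraction
        Carbon content assumed for root dry mass (default 0.5, matching
        the aboveground assumption).
    """
    rows = []
    for pid, layers in layer_table.groupby("profile_id", sort=True):
        layers = layers.sort_values("top_cm")
        tops = layers["top_cm"].to_numpy(dtype=float)
        bottoms = layers["bottom_cm"].to_numpy(dtype=float)
        if not np.allclose(tops[1:], bottoms[:-1]):
            raise DomainError(f"profile {pid}: layers not contiguous")
        m = _layer_masses(layers)
        total_depth = float(bottoms[-1])
        soc, nitrogen = profile_carbon_stock(layers)
        root_bm, root_c = root_stock(layers, root_carbon_fraction)
        mfe = float(m["fine_earth_mass_kg_m2"].sum())
        h = m["height_mm"].to_numpy()
        rho_fe = fine_earth_bulk_density(
            layers["fine_earth_g"], layers["rock_g"], layers["volume_cm3"])
        rows.append({
            "profile_id": pid,
            "habitat": layers["habitat"].iloc[0],
            "vegetation": layers["vegetation"].iloc[0],
            "total_depth_cm": total_depth,
            "n_layers": len(layers),
            "fine_earth_mass_kg_m2": mfe,
            "weathered_mass_kg_m2": float(m["weathered_mass_kg_m2"].sum()),
            "soc_stock_kg_m2": soc,
            "nitrogen_stock_kg_m2": nitrogen,
            "root_biomass_kg_m2": root_bm,
            "root_carbon_kg_m2": root_c,
            "rock_mass_fraction": rock_mass_fraction(layers),
            "rock_volume_fraction": rock_volume_fraction(layers),
            "mean_bulk_density_weathered_g_cm3": float(np.average(m["rho_w"], weights=h)),
            "mean_bulk_density_fine_earth_g_cm3": float(np.average(np.atleast_1d(rho_fe), weights=h)),
            "base_saturation_pct": profile_base_saturation(layers),
            "classification": classify_profile(layers, total_depth),
        })
    return pd.DataFrame(rows)
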