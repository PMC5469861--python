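# punastocks

Ecosystem carbon-stock accounting for high-Andean forest/grassland
mosaics, built for ecologists comparing pristine (inaccessible) and
human-impacted (accessible) land. The package turns plain tabular field
data — tree inventories, volumetric soil-profile samples, plot × species
cover matrices, and mapped landscape area fractions — into stand
structure, soil and tree carbon stocks, WRB-style soil classes,
community composition statistics, and an actual-vs-potential landscape
carbon budget. A synthetic study-system generator makes the whole chain
testable end to end.

## What it computes

- **Stand structure** — per-plot basal area BA = Σ π·(dbh/200)² scaled
  to m² ha⁻¹, stem density, mean/max tree size, deadwood share.
- **Soil accounting** — per layer ρ_w = (W_fe+W_r)/V and
  M_w = ρ_w·h (g cm⁻³ × mm = kg m⁻²); profile fine-earth mass
  M_fe = Σ M_w·W_fe/(W_fe+W_r); ρ_fe = W_fe/(V−W_r/2.65); SOC/N stocks
  Σ (c/100)·M_fe,layer; root biomass scaled from washed 20 g subsamples;
  base saturation 100·Σbases/ECEC; rule-based classification into
  Mollic Leptosol / Leptosol / Phaeozem / Umbrisol.
- **Tree carbon** — d50 = 1.1613·dbh + 0.4628, per-tree biomass
  −16.51 + 40.26·log₁₀(height) + 9.30·log₁₀(d50) kg, carbon at 50 %.
- **Landscape scenario** — habitat stock summaries extrapolated over
  zonal area under the observed forest cover (*actual*) and under the
  inaccessible-reference cover applied everywhere (*potential*), with
  per-pool percent changes and forest-cover-loss arithmetic.
- **Community metrics** — richness, undescribed/introduced cover and
  proportions, native latitudinal amplitude, Dufrêne–Legendre IndVal
  (max_g 100·A·B) with permutation p-values, and PCA trait-syndrome
  scores per plot.

See `docs/methods.md` for models, assumptions and defaults.

## Worked example

```python
import punastocks as ps

cfg = ps.SimConfig(seed=1, plots_per_habitat=24, soil_profiles_per_habitat=80)
summaries, result = ps.run_scenario(cfg)
print(result.table.round(2))
print(f"forest cover loss: {result.forest_cover_loss_percent:.1f}%")
```

prints

```
    pool     actual_kg  potential_kg  percent_change
0   tree  2.961228e+10  3.856616e+11          -92.32
1   root  2.882720e+10  7.537566e+10          -61.76
2   soil  7.758849e+11  7.426231e+11            4.48
3  total  8.343243e+11  1.203660e+12          -30.68
forest cover loss: 89.3%
```

Reading: relative to the potential (pre-impact) landscape, conversion of
~90 % of the zonal forest to grassland removed ~92 % of aboveground tree
carbon and ~62 % of root carbon, but *increased* soil organic carbon by
~4 % — grassland soils hold more SOC per m² than forest soils — so the
total landscape carbon stock fell by only ~31 %.

The same chain is available as numbered drivers over simulated data:

```
python analysis/01_simulate.py --seed 1
python analysis/02_forest_structure.py
python analysis/03_soil_stocks.py
python analysis/04_tree_carbon.py
python analysis/05_community.py
python analysis/06_landscape_scenario.py
```

each of which writes tidy CSVs under `results/`.

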