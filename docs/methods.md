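# Methods

`punastocks` reimplements, as a tested pipeline, the accounting chain
used to compare pristine (inaccessible) and human-impacted (accessible)
high-Andean *Polylepis* forest and puna grassland: stand structure,
soil mass and carbon bookkeeping, allometric tree carbon, rule-based
soil classification, community composition statistics, and an
actual-vs-potential landscape carbon scenario. This note records the
models, their assumptions, and the design choices that were genuinely
open.

## Stand structure

Each stem with circumference > 10 cm at 130 cm contributes a basal area.
The default (`metric`) form is BA = π·(dbh/200)² m² for dbh in cm;
per-plot basal areas are summed and scaled to m² ha⁻¹. An `as_printed`
mode evaluating π·(dbh/2)²/144 is retained for fidelity with the
US-customary source formula (the ÷144 converts in² to ft²); it is
dimensionally inconsistent with metric per-hectare reporting and is
never the default. Whether published per-plot mean dbh/height include
standing deadwood is not documented, so both all-stem and live-only
means are emitted. Sub-threshold stems are filtered by the reader with a
logged count.

## Soil mass, stocks and base saturation

For each depth layer *i* of a volumetric sample:

- weathered bulk density ρ_w,i = (W_fe,i + W_r,i)/V_i (g cm⁻³),
- layer mass M_w,i = ρ_w,i × h_i with h_i in mm — the unit contract
  g cm⁻³ × mm = kg m⁻² has conversion factor exactly 1,
- profile fine-earth mass M_fe = Σ_i M_w,i·100/((W_r,i/W_fe,i·100)+100),
  implemented through the algebraically identical
  Σ_i M_w,i·W_fe,i/(W_fe,i+W_r,i), which also handles fine-earth-free
  layers (they contribute zero, logged); a property test holds the two
  forms to 1e-9 relative,
- fine-earth bulk density ρ_fe,i = W_fe,i/(V_i − W_r,i/2.65), with
  2.65 g cm⁻³ the assumed rock density; rock volume ≥ sample volume is a
  domain error naming the layer.

Element stocks are Σ_i (concentration_i/100) × layer fine-earth mass.
Total carbon is treated as organic carbon (low-pH soils, no carbonates).
Root biomass scales the washed-subsample root density (root mass /
20 g subsample soil) by the layer fine-earth mass; dead and live roots
are pooled. The root carbon fraction is not documented for these soils;
the default 0.5 matches the aboveground assumption and is configurable.

Base saturation is 100 × Σ(Ca,Mg,K,Na) / ECEC with ECEC the sum of base
cations plus exchangeable acidity (Al, Fe, Mn, H), all in cmol(+) kg⁻¹.
The profile-level value is the fine-earth-mass-weighted mean over
layers — mass weighting matches the stock logic; published profile
aggregation is not specified. Zero ECEC yields a flagged missing value.

Both ρ_w and ρ_fe are reported per profile (thickness-weighted means),
since published bulk-density comparisons do not state which was plotted.

## Soil classification

Rule order over a single dark A-horizon lying on continuous rock:

1. depth ≤ 25 cm or rock ≥ 80 % by volume → Leptosol; qualified
   *Mollic* when the mollic criteria hold (profile mass-weighted SOC
   ≥ 0.6 %, Munsell value and chroma ≤ 3 in every layer, base saturation
   ≥ 50 %, thickness ≥ 10 cm over rock);
2. else base saturation ≥ 50 % → Phaeozem;
3. else → Umbrisol.

The mollic criterion "≥ 0.6 % more organic carbon than parent material"
cannot be evaluated without parent-material analyses and is treated as
satisfied — an explicit, documented assumption. Rock volume is
(W_r/2.65)/V per layer, thickness-weighted. Missing inputs produce
`undetermined: <reason>` rather than an exception, keeping
classification a total function over valid profiles.

## Tree carbon

dbh is mapped to bole diameter at 50 cm by d50 = 1.1613·dbh + 0.4628
(cm), then per-tree dry biomass (kg) by
−16.51 + 40.26·log₁₀(height m) + 9.30·log₁₀(d50 cm), applied per tree
and summed per plot (per-stand aggregation was the alternative; per-tree
is the standard reading for a per-tree regression). Negative
predictions — small trees outside the allometry's calibration range —
are floored at zero with a warning counter. Carbon is 50 % of dry
biomass by default. Deadwood is excluded from carbon stocks by default
(no decay-stage mass-loss model) but can be included via a flag; the
output unit is assumed kg per tree, with a configurable scale factor.

## Landscape scenario

The mapped landscape splits into zonal-inaccessible, zonal-accessible
and azonal fractions; each zonal accessibility class has a forest-cover
fraction. The *actual* budget multiplies each accessibility class's
forest/grassland areas by that class's per-m² habitat stocks. The
*potential* budget applies the inaccessible forest fraction and
inaccessible habitat stocks to **all** zonal area — a static
extrapolation from the pristine relicts (an option substitutes
accessible stocks for sensitivity). Azonal area carries zero stock in
both scenarios — a documented limitation, not a claim that cliffs and
bogs are carbon-free. Percent change is 100·(actual−potential)/potential
(decrease negative); uncertainty is propagated by recomputing the
scenario at the min/q1/q3/max of the habitat stock distributions rather
than by resampling. Forest-cover loss is
100·(1 − ff_accessible/ff_inaccessible); with the default 70 % vs 7.5 %
cover this is 89.3 % (~90 % loss, ~10 % retention). The mapped area
itself is always an input — never hard-coded into the computation —
and percent changes are invariant to it.

## Community metrics

*IndVal.* For species *s* and group *j*, specificity A = mean cover in
*j* / Σ over groups of mean covers, fidelity B = share of *j*'s plots
where the species occurs (cover > 0), and IndVal = max_j 100·A·B.
Cover-based abundance is the default; a presence/absence variant exists
because the original analysis does not state which was used.
Significance comes from random reassignment of plot labels with the
add-one rule p = (1+#{permuted max ≥ observed})/(n_perm+1), default
n_perm = 999, seedable; an exact mode enumerates all distinct label
orderings for small tables and is tested against a brute-force oracle.

*Plot metrics.* Richness counts species with cover > 0; undescribed and
introduced cover/proportions are per plot (proportions relative to the
plot's species count); latitudinal amplitude (minutes of latitude
between northern- and southernmost records) is averaged over the native
species present, introduced species excluded.

*Trait syndromes.* The 32 binary/ordinal grazing/burning traits are
standardised per trait, decomposed by PCA, and each component's sign is
fixed deterministically (largest-magnitude loading positive). A plot's
syndrome score is the unweighted mean of component scores over the
species present, matching a presence-based community mean; a
cover-weighted variant is available but non-default. Constant trait
columns are dropped with a warning.

## Synthetic study system

The generator is first-class pipeline code: it emulates the four input
tables with the study's habitat contrasts so every downstream stage is
testable without the (unpublished) field data. One top-level seed feeds
fixed per-table substreams, so identical seeds give byte-identical
tables regardless of generation order.

Distributional choices (the source reports none): lognormal dbh and
cover (positive, right-skewed field data), power-law height on dbh with
multiplicative noise, Bernoulli deadwood/occupancy flags, uniform depth
within soil-class bands. Default habitat effects were chosen once to
reproduce the study's reported *directions* and rough magnitudes:

- forest inventory — inaccessible: ~70 stems/plot, median dbh 18 cm,
  30 % deadwood; accessible: ~35 stems, 14 cm, 5 % deadwood;
- soils — class mix by vegetation (forest: 75 % Phaeozem / 15 % Umbrisol /
  10 % Mollic Leptosol; grassland: 65 % Umbrisol / 18 % Phaeozem /
  12 % Mollic Leptosol / 5 % Leptosol), depth 15–90 cm, grassland carbon
  concentrations ×1.25 (so grassland SOC per m² exceeds forest SOC by
  ~10–20 %), root density 0.008 g g⁻¹ fine earth under forest vs
  0.002 under grassland;
- community — undescribed narrow-range species occupy inaccessible plots
  (occupancy 0.45 vs 0.02), introduced aliens accessible plots (0.35 vs
  0.01), widespread grazing/burning-adapted generalists dominate
  accessible plots; two opposed trait archetypes with 15 % flip noise;
- landscape — 1.1 % / 56.9 % / 42.0 % zonal-inaccessible /
  zonal-accessible / azonal split, 70 % vs 7.5 % forest cover.

Soil profiles are generated *class-first*: a target WRB class is drawn
per profile and its class-determining fields (depth, rock volume, base
saturation, colour, carbon) are sampled with safety margins away from
every rule boundary, so the classifier must recover the generating class
exactly; per-profile ground-truth stocks are accumulated with the
generator's own layer arithmetic and stored in a JSON sidecar for
recovery tests.

What the generator does **not** emulate: spatial autocorrelation among
plots, site-level random effects, within-profile pedogenic structure
beyond a depth-decaying carbon profile, species co-occurrence structure
beyond habitat filtering, measurement error in field covers, and any
climate forcing. Passing tests therefore demonstrate that the
accounting chain recovers configured effects from data with realistic
marginal structure — not that the field study's inferential statistics
are reproduced.

## Problem sizes and numerics

The test suite and the acceptance script run the scenario recovery at
24 forest plots and 80 soil profiles per habitat (320 profiles), where
habitat mean stocks are estimated tightly enough for the configured
effect directions — including the small positive soil-carbon change —
to be recovered across seeds; classification recovery uses 1,000
profiles, and the IndVal null calibration 500 species at 199
permutations. Ties in permutation statistics are counted as exceedances
(≥ with a 1e-12 tolerance), quantiles use numpy's linear interpolation,
and all equation cross-checks are held to 1e-9 relative.

## Known limitations

- The scenario is static: pristine per-m² stocks are assumed spatially
  transferable to all zonal accessible land.
- Azonal habitats carry zero stock, biasing landscape totals low.
- Herb-layer biomass and soil inorganic carbon are outside the
  accounting, as in the source design.
- The soil classifier covers only the four classes the rule set can
  reach; it is not a general WRB key.
- Mixed-model habitat inference (GLMM/LMM) is out of scope; tests
  assert effect directions on group means instead.
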