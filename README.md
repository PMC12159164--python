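# reforest

Raster pipeline for mapping **reforestation opportunity**: where on a
landscape could additional dense forest grow, how much area that is, how
much carbon it would draw down, and how many people live there.

The package is aimed at restoration-ecology and land-use analysts who
work with gridded land-cover products. It implements the full chain from
evidence layers to accounting tables:

1. **Forest potential** — a conservative dual-evidence composite. A pixel
   counts as potential forest only if a continuous potential-tree-cover
   prediction exceeds 60% *and* an independent potential-biomass product
   classifies it as closed forest *and* both products are confident
   there. Confidence is measured by a per-pixel **uncertainty index**
   UI = (3.92 · σ) / μ — the full two-sided 95% confidence-interval
   width over the prediction — screened at UI < 3. Frequently burning
   areas (≥ 2 fires over the counting window) that are not cropland or
   oil palm are then removed, since recurrent fire marks grassy
   ecosystems that should not be afforested.
2. **Exclusion cascade** — fine-resolution binary exclusion layers are
   unioned by sum-and-clamp, pixel-averaged to a mid grid and again to
   the coarse grid (a *proportion-excluded* raster p), and availability
   is 1 − p inside the forest-potential mask. *Maximum* potential removes
   the four implementation exclusions (existing forest, open water, bare
   ground, permanent ice/snow); *constrained* potential adds five
   precautionary safeguards (cropland, built-up, wetland, peatland,
   negative-net-albedo areas).
3. **Scenarios** — eight contextual overlays (individual rights, land
   tenure, rural-livelihood conflict, >30% forest cover within a radius,
   moderate hillslopes or floodplains, protected areas, national
   restoration goals) re-enter the cascade as full exclusions outside
   their masks; intersection areas of scenario combinations are exact
   cellwise minima over the shared base.
4. **Accounting** — area in Mha with latitude-aware spherical pixel
   areas A = R²·Δλ·(sin φ_top − sin φ_bot); net mitigation in TgCO₂e/yr
   from an albedo-adjusted sequestration flux; affected population; and
   an **additionality** discount that scales every one-degree cell by its
   forest loss:gain ratio capped at 1.
5. **Map comparison** — declarative reclassification of published
   products to binary maps, agreement counts, per-level and pairwise
   intersection areas.

Because the global source products are not redistributable, the package
ships a synthetic-data generator (`reforest.synthetic`) that emulates
their structure — autocorrelated fields, mean-correlated uncertainty,
clumped categorical layers, clustered fire counts, nested fine/mid/coarse
grids — with exact known ground truth, so the whole cascade can be
validated to machine precision.

## Worked example

```sh
reforest run --out demo_run --seed 1
```

prints

```
outputs written to demo_run
constrained potential: 0.058 Mha, 0.6717 TgCO2e/yr, 0.0128 M people
```

and writes `forest_potential.tif`, `maximum.tif`, `constrained.tif`, one
GeoTIFF per scenario, `summary.csv` and `combinations.csv`. The first
rows of `summary.csv`:

```
map_or_combo,area_Mha,area_additional_Mha,mitigation_TgCO2e_yr,mitigation_additional_TgCO2e_yr,population_millions
forest_potential,0.7875775159,,,,
maximum,0.1201003332,0.1177314741,1.227039176,1.206824513,0.02322735779
constrained,0.05780293635,0.05543407724,0.6716611516,0.6514464882,0.01280835958
```

Reading: on this synthetic 2° × 2° world (≈ 4.3 Mha of land), 0.79 Mha
could support closed forest; removing existing forest, water, bare
ground and ice leaves 0.12 Mha of maximum reforestation potential; the
precautionary safeguards cut that to 0.058 Mha of constrained potential,
which would sequester ≈ 0.67 TgCO₂e/yr and directly affect ≈ 12,800
people; ≈ 96% of the area is expected to be additional given the
loss:gain ratios. `--variant {no-fire,tc50,tc30-open,alt-forest,
alt-cropland,no-cropland}` reproduces the sensitivity runs, and
`reforest generate` / `reforest compare` expose the bundle writer and the
agreement analysis.

The same flow is available as a library:

```python
from reforest import SyntheticConfig, generate_bundle, run_pipeline

bundle = generate_bundle(SyntheticConfig(seed=1))
result = run_pipeline(bundle)
print(result.summary.head())
```

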