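# Methods

This note documents the models and procedures the package implements,
the parameters that matter, what the synthetic generator does and does
not emulate, and the numerical choices made where the design was open.

## Raster model

Grids are single-band, axis-aligned geographic (lat/lon) rasters with
the *area* convention: the transform origin is the outer corner of the
top-left pixel and a value describes the whole cell. Three resolution
classes mirror the native scales of the workflow: `fine` (the 30 m-class
land-cover layers), `mid` (500 m-class) and `coarse` (1 km-class, where
the final maps live). There is no reprojection; all layers in one
operation must share a transform and shape, and violations raise
`AlignmentError` rather than silently resampling.

Per-pixel areas use the spherical band formula
A = R²·Δλ·(sin φ_top − sin φ_bot) with the authalic radius
R = 6 371 007.2 m (configurable). A sphere is assumed rather than an
ellipsoid; at the precision of Mha-level accounting the difference is
immaterial, and the closed form makes conservation testable: summing 1°
cells over the sphere reproduces 4πR² to < 1e−9 relative.

### Resampling

Four kernels: `nearest` and `bilinear` sample at target cell centers;
`mean` and `max` aggregate over all source cells overlapping a target
cell. **Mean aggregation is area-weighted** using the same spherical
band weights, which is what makes the cascade exactly conservative: the
sum of value × pixel-area is invariant under aggregation to < 1e−9
relative, and the fractional-availability area equals a direct
per-fine-pixel count (see below). The weights vary only with latitude,
so along a row the weighted mean is the plain mean; across rows the two
differ by O(Δφ·tan φ) relative — negligible at fine pixel sizes but
deliberately not ignored. Mean/max ignore nodata cells and return nodata
only when no valid source cell contributes; nearest/bilinear propagate
it. Bilinear (and mean) are rejected on categorical grids.

Non-integer resolution ratios are handled by the same overlap-weight
machinery (area-weighted overlap averaging); tests use integer nesting
factors where brute-force oracles are exact.

## Forest potential

A pixel has forest potential iff

* potential tree cover > `tree_cover_threshold` (default 60%),
* the biomass classification is in `walker_classes_allowed` (default
  {closed forest}),
* both uncertainty indices < `ui_threshold` (default 3).

The uncertainty index re-expresses a prediction standard deviation on
the same footing as a percentile-range index: UI = (3.92·σ)/μ, the full
two-sided 95% interval width over the prediction. The factor is fixed at
3.92 (2 × 1.96, the conventional rounded normal quantile); a half-width
variant (1.96) is available via `ci_width_factor`. Where μ = 0 the UI is
undefined and the pixel fails the screen — no evidence, no forest
potential. All comparisons are strict (">", "<") and the boundaries are
config-exposed.

The fire screen removes pixels with ≥ `fire_count_threshold` fires
(default 2) over the counting window that are neither cropland
(map-agreement ≥ 3 of 6) nor oil palm. Fire counts reach the coarse grid
by **maximum-value** resampling (a single burned mid-pixel marks the
coarse pixel as fire-prone); cropland agreement and oil palm by nearest
neighbour. The fire counting window is a documented parameter
(`fire_years`, default 2002–2020); a 2002–2022 variant exists in the
literature and is representable by the same parameter. Whether the UI
screen should precede or follow rescaling to the coarse grid is
underdetermined; this implementation screens after rescaling, with all
evidence layers on the coarse grid.

## The exclusion cascade

Exclusion layers are binarized upstream by per-layer rules declared in
configuration (the cropland layer, e.g., is agreement ≥ 3, switchable to
a single product). The union is formed by summing and clamping at 1,
then pixel-averaged fine → mid → coarse. Two-stage averaging is retained
rather than collapsed to one stage because scenario overlays re-enter at
the mid stage; for nested integer factors the two coincide exactly and
tests assert it. Availability is 1 − p inside the forest-potential mask
and 0 outside.

Key identity (tested to < 1e−9 relative, and in practice to float
round-off): because mean aggregation is area-weighted and coarse-pixel
areas are sums of their fine-pixel areas,

    Σ availability·area  =  Σ_fine [in-mask ∧ not-excluded]·fine-area,

i.e. the cascade loses no information relative to a single-pass
per-fine-pixel count. This is also why the generator's ground truth is
recovered exactly.

Area summaries are reported in Mha (double precision internally; one
decimal is the conventional display precision). Mitigation is
Σ availability·area_ha·flux / 10⁶ TgCO₂e/yr; population is
Σ availability·population — people in partially available pixels count
proportionally, which is what the multiplicative definition implies.

## Scenarios and combinations

All scenarios except forest neighborhood apply at the mid stage: pixels
outside the scenario mask get proportion-excluded 1 before the final
averaging. Forest neighborhood applies at coarse: its rule — mean forest
cover over a circular window of given radius > 0.30 — is evaluated on
the coarse forest-cover fraction with window membership by great-circle
cell-center distance (a circular, not square, window; edge cells use the
available cells only). The real-scale default radius is 5 km on a
1 km-class grid; on synthetic grids the default scales to 2.2 coarse
pixel widths so the window spans multiple cells regardless of the
domain's pixel size. The water-quality rule keeps moderate hillslopes
(20–35% slope class) or floodplains, evaluated on fine categorical
layers and brought to mid resolution by nearest neighbour. Country-level
attribute masks (rights, tenure, restoration goals) are inputs, not
derived indices.

Scenario-combination intersection areas are cellwise **minima** of
availability. This is exact, not an approximation: all scenario maps
share the constrained map's base proportions and differ only by masking,
so the joint availability of a cell is the smallest member availability.
For the same reason, intersections of fractional maps and of binarized
maps coincide here — asserted in tests rather than assumed.

## Additionality

Each coarse pixel belongs to the one-degree cell (anchored on integer
lat/lon lines) containing its center. The cell's ratio is
min(loss/gain, 1). Conventions where the data are silent: gain = 0 with
loss > 0 gives ratio 1 (no background regrowth, fully additional), and
loss = gain = 0 gives ratio 1 (no evidence of background recovery);
both are config-visible choices in `AdditionalityCell.ratio`. Adjusted
area and mitigation are cellwise-scaled sums and can never exceed the
unadjusted totals, with equality iff every occupied cell has ratio 1.

## Synthetic worlds

The generator produces a 2° × 2° temperate domain (16 × 16 coarse cells,
mid factor 2, fine factor 8 → 128 × 128 fine cells by default) with:

* tree cover as a clipped Gaussian random field (mean 55%, spread 18%,
  correlation length 0.15°) and a standard deviation that rises with the
  mean times a lognormal factor;
* a biomass classification correlated with tree cover (50% closed, 25%
  open by quantile assignment) and a lognormal uncertainty index;
* mutually exclusive fine land-cover categories (35% forest, 12%
  cropland, 4% water, 3% built-up, 3% bare, 1% ice) assigned by greedy
  quantile partitioning of smoothed latent fields — fractions are exact
  to one cell and patches are spatially clumped; cropland agreement is
  ≥ 3 exactly on cropland cells;
* overlapping wetland (5%), peatland (3%), oil palm (2%) and
  negative-albedo (5%) layers; the sequestration flux (mean 11, sd 3
  tCO₂e ha⁻¹ yr⁻¹, consistent with 30-year natural-regrowth rates) dips
  where the albedo-negative fraction is high;
* fire counts per mid pixel from a Poisson process mixed over a smooth
  intensity field (rate 0.6), giving patchy burned areas;
* lognormal population; per-one-degree-cell loss/gain totals drawn
  directly at that granularity (which is what the additionality step
  consumes);
* blocky "countries" constant within coarse cells, so country-attribute
  scenarios commute with the cascade (a tested invariant); protected
  areas and livelihood masks at mid resolution; slope/landform classes
  at fine resolution.

Ground truth is computed inside the generator by an independent
arithmetic path — reshape-based block counting with closed-form band
weights, never the resampling engine — and records the exact
availability per coarse cell under the default criteria.

The generator emulates structure, not geography: it does not reproduce
the spatial distribution of any real product, real fire regimes,
radiative albedo physics, or the 862 m native resolution of real
tree-cover products (everything nests exactly). Passing tests therefore
demonstrate the correctness of the pipeline's arithmetic and logic on
realistic *structure*; they say nothing about the real-world magnitude
of reforestation opportunity, which depends entirely on the input
products.

Problem sizes in the shipped tests and the acceptance script (up to
128 × 128 fine cells, 20-seed Monte-Carlo sweeps on 24–64-cell grids)
were chosen as the smallest scales at which every oracle and invariant
is non-trivially exercised; all results above are scale-free properties.

## Known limitations

* Geographic lat/lon grids only; no projected CRS or datum changes.
* The forest-neighborhood window uses cell-center membership, so ragged
  window shapes at coarse resolution are expected; radius below one cell
  is rejected.
* Binarization rules for real third-party products are configuration
  placeholders with the documented semantics; real deployments must
  supply the product-specific class lists.
* `max` resampling loops over target cells in Python; adequate for the
  grid sizes here, not tuned for global 30 m mosaics.
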