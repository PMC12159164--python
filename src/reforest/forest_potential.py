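"""Composite forest-potential mapping with uncertainty and fire screening.

Forest potential is mapped conservatively from two independent evidence
layers: a continuous potential tree-cover prediction (with a per-pixel
standard deviation) and a potential-biomass classification (with its own
uncertainty index).  A pixel qualifies only where

* potential tree cover exceeds a threshold (default 60%),
* the biomass classification is an allowed class (default closed forest),
* both uncertainty indices fall below a threshold (default 3),

and, unless disabled, where the pixel is not a frequently burning
non-agricultural area (>= 2 fires over the counting window, outside
cropland and oil palm).  The uncertainty index (UI) re-expresses a
prediction standard deviation as a full two-sided 95% confidence-interval
width divided by the prediction, matching the percentile-range UI of the
biomass product.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .raster_core import Grid, RasterError, require_aligned, resample

# Potential-biomass class codes.
CLOSED_FOREST = 1
OPEN_FOREST = 2
NONWOODY = 3

#: Full width of a two-sided 95% confidence interval, in standard
#: deviations (2 x 1.96, the conventional rounded normal quantile).
FULL_CI95_WIDTH = 3.92
#: Half-width variant (one-sided margin), selectable via ``ci_width_factor``.
HALF_CI95_WIDTH = 1.96


@dataclass(frozen=True)
class ForestPotentialCriteria:
    """Thresholds defining forest potential and the fire screen.

    All comparisons are strict (">" for tree cover, "<" for UI) except the
    fire count, which excludes at ``fire_count_threshold`` *or more* fires.
    """

    tree_cover_threshold: float = 60.0
    walker_classes_allowed: frozenset = frozenset({CLOSED_FOREST})
    ui_threshold: float = 3.0
    fire_count_threshold: int = 2
    cropland_agreement_threshold: int = 3
    apply_fire_filter: bool = True
    ci_width_factor: float = FULL_CI95_WIDTH
    fire_years: tuple[int, int] = (2002, 2020)

    def __post_init__(self) -> None:
        if self.tree_cover_threshold <= 0 or self.ui_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.fire_count_threshold <= 0 or self.cropland_agreement_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if not self.walker_classes_allowed:
            raise ValueError("walker_classes_allowed must be nonempty")


@dataclass
class UncertaintyLayer:
    """Per-pixel prediction-uncertainty ratio (interval width / prediction).

    Undefined pixels (zero prediction) carry NaN and always fail the
    UI screen.
    """

    ui: Grid

    def __post_init__(self) -> None:
        v = self.ui.values[self.ui.valid_mask()]
        if v.size and np.nanmin(v) < 0:
            raise RasterError("uncertainty index must be non-negative where defined")


def ui_from_sd(
    mean: Grid, sd: Grid, ci_width_factor: float = FULL_CI95_WIDTH
) -> UncertaintyLayer:
    """Uncertainty index from a prediction mean and standard deviation.

    UI = (ci_width_factor * sd) / mean where mean > 0; the default factor
    3.92 is the full two-sided 95% interval width in standard deviations.
    Where the mean is zero the UI is undefined (NaN) and the pixel fails
    any UI screen.
    """
    require_aligned(mean, sd)
    sd_vals = np.asarray(sd.values, dtype=float)
    if np.nanmin(np.where(sd.valid_mask(), sd_vals, 0.0)) < 0:
        raise RasterError("standard deviation must be non-negative")
    m = np.asarray(mean.values, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ui = np.where(m > 0, ci_width_factor * sd_vals / m, np.nan)
    ui = np.where(mean.valid_mask() & sd.valid_mask(), ui, np.nan)
    return UncertaintyLayer(
        ui=Grid(ui, mean.transform, nodata=np.nan, res_class=mean.res_class)
    )


def composite_mask(
    tree_cover: Grid,
    ui_bastin: UncertaintyLayer,
    biomass_class: Grid,
    ui_walker: UncertaintyLayer,
    criteria: ForestPotentialCriteria = ForestPotentialCriteria(),
) -> Grid:
    """Dual-evidence forest-potential mask on the coarse grid.

    1 iff tree cover > threshold AND biomass class is allowed AND both
    UIs < threshold.  Nodata in any input makes the pixel 0 (the
    conservative choice: no evidence, no forest potential).
    """
    require_aligned(tree_cover, ui_bastin.ui, biomass_class, ui_walker.ui)
    tc = np.asarray(tree_cover.values, dtype=float)
    ub = np.asarray(ui_bastin.ui.values, dtype=float)
    uw = np.asarray(ui_walker.ui.values, dtype=float)
    cls = biomass_class.values
    allowed = np.isin(cls, sorted(criteria.walker_classes_allowed))
    with np.errstate(invalid="ignore"):
        ok = (
            (tc > criteria.tree_cover_threshold)
            & allowed
            & (ub < criteria.ui_threshold)
            & (uw < criteria.ui_threshold)
        )
    ok &= (
        tree_cover.valid_mask()
        & biomass_class.valid_mask()
        & ~np.isnan(ub)
        & ~np.isnan(uw)
    )
    return Grid(
        ok.astype(np.uint8),
        tree_cover.transform,
        nodata=None,
        res_class=tree_cover.res_class,
    )


def fire_exclusion_mask(
    fire_count: Grid,
    cropland_agreement: Grid,
    oil_palm: Grid,
    criteria: ForestPotentialCriteria = ForestPotentialCriteria(),
) -> Grid:
    """Frequent-fire exclusion with the agricultural exemption.

    Inputs must already be on the coarse grid: fire counts via
    maximum-value resampling, cropland agreement and oil palm via nearest
    neighbour (see :func:`forest_potential`, which performs the rescaling).
    1 (exclude) iff fires >= threshold AND cropland agreement below the
    map-agreement threshold AND not oil palm.
    """
    require_aligned(fire_count, cropland_agreement, oil_palm)
    fires = np.asarray(fire_count.values, dtype=float)
    fires_valid = fire_count.valid_mask()
    if fires[fires_valid].size and fires[fires_valid].min() < 0:
        raise RasterError("fire counts must be non-negative")
    fires = np.where(fires_valid, fires, 0.0)
    crop = np.where(
        cropland_agreement.valid_mask(), cropland_agreement.values, 0
    ).astype(float)
    palm = np.where(oil_palm.valid_mask(), oil_palm.values, 0).astype(float)
    exclude = (
        (fires >= criteria.fire_count_threshold)
        & (crop < criteria.cropland_agreement_threshold)
        & (palm == 0)
    )
    return Grid(
        exclude.astype(np.uint8),
        fire_count.transform,
        nodata=None,
        res_class=fire_count.res_class,
    )


def forest_potential(bundle, criteria: ForestPotentialCriteria = ForestPotentialCriteria()) -> Grid:
    """Forest-potential mask for a full input bundle.

    Computes the Bastin-style UI from the tree-cover mean and standard
    deviation, applies the dual-evidence composite on the coarse grid,
    then (unless ``apply_fire_filter`` is off) removes frequently burned
    non-agricultural pixels after rescaling fire counts to the coarse grid
    by maximum-value resampling and the cropland/oil-palm layers by
    nearest neighbour.
    """
    ui_b = ui_from_sd(bundle.tree_cover_mean, bundle.tree_cover_sd, criteria.ci_width_factor)
    ui_w = UncertaintyLayer(ui=bundle.walker_ui)
    comp = composite_mask(bundle.tree_cover_mean, ui_b, bundle.biomass_class, ui_w, criteria)
    if not criteria.apply_fire_filter:
        return comp
    coarse = bundle.tree_cover_mean.geometry
    fire = resample(bundle.fire_count, coarse, "max", res_class="coarse")
    crop = resample(bundle.cropland_agreement, coarse, "nearest", res_class="coarse")
    palm = resample(bundle.oil_palm, coarse, "nearest", res_class="coarse")
    excl = fire_exclusion_mask(fire, crop, palm, criteria)
    out = comp.values.astype(np.uint8) & (1 - excl.values.astype(np.uint8))
    return Grid(out, comp.transform, nodata=None, res_class="coarse")
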