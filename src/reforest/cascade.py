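"""Maximum / constrained reforestation potential via the exclusion cascade.

The cascade turns fine-resolution binary exclusion layers into a coarse
fractional availability map in four steps:

1. union the exclusion layers by summing and clamping at 1;
2. pixel-average the union to the mid grid (proportion excluded);
3. pixel-average again to the coarse grid;
4. availability = 1 - proportion excluded, inside the forest-potential
   mask, 0 outside.

*Maximum* reforestation potential uses the four implementation exclusions
(existing forest, open water, bare ground, permanent ice/snow);
*constrained* potential adds the five precautionary safeguards (cropland,
built-up, wetland, peatland, negative-net-albedo areas).  Areas are
reported in Mha by weighting availability with latitude-aware pixel
areas.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .forest_potential import ForestPotentialCriteria, forest_potential
from .raster_core import (
    AreaRaster,
    Grid,
    GridGeometry,
    RasterError,
    pixel_area,
    require_aligned,
    resample,
)

IMPLEMENTATION_LAYERS = ("existing_forest", "water", "bare", "ice")
PRECAUTIONARY_LAYERS = ("cropland", "builtup", "wetland", "peatland", "albedo_negative")

Stage = Literal["maximum", "constrained"]


class MissingLayerError(KeyError):
    """A required exclusion layer is absent from the bundle."""


@dataclass
class ExclusionSet:
    """Named fine-resolution binary exclusion layers with stage tags."""

    layers: dict[str, Grid]
    stage: dict[str, str]

    def __post_init__(self) -> None:
        for name, g in self.layers.items():
            if not g.is_binary():
                raise RasterError(f"exclusion layer {name!r} is not binary")

    def implementation(self) -> list[Grid]:
        return [g for n, g in self.layers.items() if self.stage[n] == "implementation"]

    def all_layers(self) -> list[Grid]:
        return list(self.layers.values())


@dataclass
class PotentialMap:
    """Fractional availability (0-1) on the coarse grid.

    ``availability`` is the proportion of each coarse pixel where
    reforestation could occur; it is zero outside the forest-potential
    mask.  ``criteria`` records the provenance of the map.
    """

    availability: Grid
    stage: str
    criteria: dict = field(default_factory=dict)


@dataclass
class ExclusionConfig:
    """Which layers feed the cascade (sensitivity-variant switches).

    ``forest_layer`` selects the existing-forest product ("existing_forest"
    or the radar-style alternative "existing_forest_alt");
    ``cropland_source`` selects the multi-map agreement rule or the single
    cropland product; ``include_cropland`` disables the cropland safeguard
    entirely (the no-cropland sensitivity run).
    """

    forest_layer: str = "existing_forest"
    cropland_source: Literal["agreement", "single"] = "agreement"
    include_cropland: bool = True


@dataclass
class SummaryRecord:
    """One row of the output summary table."""

    name: str
    area_Mha: float
    mitigation_TgCO2e_yr: float | None = None
    population_millions: float | None = None
    area_additional_Mha: float | None = None
    mitigation_additional_TgCO2e_yr: float | None = None


@dataclass
class CascadeResult:
    """Everything produced by :func:`run_cascade`.

    Retains the mid-resolution proportion-excluded grids because scenario
    overlays re-enter the cascade at that stage.
    """

    forest_potential: Grid
    maximum: PotentialMap
    constrained: PotentialMap
    prop_excluded_mid: dict[str, Grid]
    prop_excluded_coarse: dict[str, Grid]
    union_fine: dict[str, Grid]
    areas: AreaRaster
    mid_geometry: GridGeometry
    coarse_geometry: GridGeometry
    summaries: list[SummaryRecord]


def combine_exclusions(layers: list[Grid], geometry: GridGeometry | None = None) -> Grid:
    """Union binary exclusion layers by summing and clamping values above 1 to 1.

    An empty list yields an all-zero grid on ``geometry`` (required then).
    """
    if not layers:
        if geometry is None:
            raise RasterError("empty layer list requires an explicit geometry")
        return Grid(
            np.zeros(geometry.shape, dtype=np.uint8),
            geometry.transform,
            nodata=None,
            res_class="fine",
        )
    require_aligned(*layers)
    total = np.zeros(layers[0].shape, dtype=np.int64)
    for g in layers:
        if not g.is_binary():
            raise RasterError("exclusion layers must be binary (0/1)")
        total += np.where(g.valid_mask(), g.values, 0).astype(np.int64)
    union = np.minimum(total, 1).astype(np.uint8)
    return Grid(union, layers[0].transform, nodata=None, res_class=layers[0].res_class)


def proportion_excluded(
    union: Grid, mid: GridGeometry, coarse: GridGeometry
) -> tuple[Grid, Grid]:
    """Two-stage pixel averaging of a fine binary union to mid then coarse.

    For nested integer factors the coarse output equals the one-stage
    fine-to-coarse average exactly.
    """
    mid_grid = resample(union, mid, "mean", res_class="mid")
    coarse_grid = resample(mid_grid, coarse, "mean", res_class="coarse")
    return mid_grid, coarse_grid


def potential_map(fp_mask: Grid, prop_excl: Grid, stage: Stage, criteria: dict | None = None) -> PotentialMap:
    """Availability = 1 - proportion excluded inside the mask, 0 outside."""
    require_aligned(fp_mask, prop_excl)
    p = np.asarray(prop_excl.values, dtype=float)
    finite = np.isfinite(p)
    if finite.any() and (
        np.nanmin(p[finite]) < -1e-9 or np.nanmax(p[finite]) > 1 + 1e-9
    ):
        raise RasterError("proportion excluded must lie in [0, 1]")
    p = np.clip(p, 0.0, 1.0)
    inside = fp_mask.values == 1
    avail = np.where(inside & finite, 1.0 - p, 0.0)
    grid = Grid(avail, fp_mask.transform, nodata=None, res_class=fp_mask.res_class)
    return PotentialMap(availability=grid, stage=stage, criteria=dict(criteria or {}))


def area_summary(pm: PotentialMap, areas: AreaRaster) -> float:
    """Availability-weighted area in Mha."""
    require_aligned(pm.availability, areas)
    return float(np.sum(pm.availability.values * areas.values) / 1e6)


def build_exclusion_set(
    bundle,
    criteria: ForestPotentialCriteria = ForestPotentialCriteria(),
    config: ExclusionConfig = ExclusionConfig(),
) -> ExclusionSet:
    """Assemble the fine binary exclusion layers from a bundle.

    Cropland is binarised from the 0-6 map-agreement count (agreement >=
    threshold) or taken from the single-product layer, per ``config``.
    """
    layers: dict[str, Grid] = {}
    stage: dict[str, str] = {}

    def fetch(attr: str) -> Grid:
        g = getattr(bundle, attr, None)
        if g is None:
            raise MissingLayerError(f"bundle is missing required layer {attr!r}")
        return g

    impl_sources = {
        "existing_forest": config.forest_layer,
        "water": "water",
        "bare": "bare",
        "ice": "ice",
    }
    for name, attr in impl_sources.items():
        layers[name] = fetch(attr)
        stage[name] = "implementation"

    if config.include_cropland:
        if config.cropland_source == "agreement":
            agree = fetch("cropland_agreement")
            crop = (
                np.where(agree.valid_mask(), agree.values, 0)
                >= criteria.cropland_agreement_threshold
            ).astype(np.uint8)
            layers["cropland"] = Grid(
                crop, agree.transform, nodata=None, res_class=agree.res_class
            )
        else:
            layers["cropland"] = fetch("cropland_single")
        stage["cropland"] = "precautionary"
    for name in ("builtup", "wetland", "peatland", "albedo_negative"):
        layers[name] = fetch(name)
        stage[name] = "precautionary"
    return ExclusionSet(layers=layers, stage=stage)


def run_cascade(
    bundle,
    criteria: ForestPotentialCriteria = ForestPotentialCriteria(),
    exclusion_config: ExclusionConfig = ExclusionConfig(),
) -> CascadeResult:
    """Run the full forest-potential + exclusion cascade on a bundle.

    Returns the forest-potential mask, the maximum and constrained
    potential maps, the retained mid-stage proportion-excluded grids, and
    area summaries in Mha.
    """
    excl = build_exclusion_set(bundle, criteria, exclusion_config)
    fp = forest_potential(bundle, criteria)
    coarse = fp.geometry
    mid = bundle.fire_count.geometry

    union_impl = combine_exclusions(excl.implementation())
    union_all = combine_exclusions(excl.all_layers())
    mid_impl, coarse_impl = proportion_excluded(union_impl, mid, coarse)
    mid_all, coarse_all = proportion_excluded(union_all, mid, coarse)

    prov = {
        "tree_cover_threshold": criteria.tree_cover_threshold,
        "ui_threshold": criteria.ui_threshold,
        "apply_fire_filter": criteria.apply_fire_filter,
        "forest_layer": exclusion_config.forest_layer,
        "cropland_source": exclusion_config.cropland_source,
        "include_cropland": exclusion_config.include_cropland,
    }
    maximum = potential_map(fp, coarse_impl, "maximum", prov)
    constrained = potential_map(fp, coarse_all, "constrained", prov)
    areas = pixel_area(coarse)

    fp_pm = PotentialMap(
        availability=Grid(
            fp.values.astype(float), fp.transform, nodata=None, res_class="coarse"
        ),
        stage="forest_potential",
    )
    summaries = [
        SummaryRecord("forest_potential", area_summary(fp_pm, areas)),
        SummaryRecord("maximum", area_summary(maximum, areas)),
        SummaryRecord("constrained", area_summary(constrained, areas)),
    ]
    return CascadeResult(
        forest_potential=fp,
        maximum=maximum,
        constrained=constrained,
        prop_excluded_mid={"maximum": mid_impl, "constrained": mid_all},
        prop_excluded_coarse={"maximum": coarse_impl, "constrained": coarse_all},
        union_fine={"maximum": union_impl, "constrained": union_all},
        areas=areas,
        mid_geometry=mid,
        coarse_geometry=coarse,
        summaries=summaries,
    )
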