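"""Contextual scenario overlays on the constrained cascade.

Eight scenarios contextualize the constrained reforestation potential:
the base constrained map itself; three social-safeguard masks (high
individual rights, secure land tenure, low rural-livelihood conflict);
two ecosystem-service rules (forest neighborhood — >30% forest cover
within a radius — and water quality — moderate hillslopes or
floodplains); and two governance masks (protected areas, national
restoration goals).  A scenario is applied by re-entering the cascade:
pixels outside its mask become fully excluded at the scenario's
application resolution (mid for all but forest neighborhood, which
applies at coarse), and the usual averaging and 1 - p steps follow.

Because every scenario map shares the constrained map's base exclusion
proportions and differs from it only by masking, the intersection of a
set of scenario maps is exactly the cellwise minimum of their
availabilities; :func:`combination_areas` uses that rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .cascade import CascadeResult, PotentialMap, area_summary, potential_map
from .raster_core import (
    AreaRaster,
    AUTHALIC_RADIUS_M,
    Grid,
    RasterError,
    require_aligned,
    resample,
)
from .synthetic import (
    LANDFORM_FLOODPLAIN,
    LANDFORM_UPLAND,
    SLOPE_FLAT,
    SLOPE_MODERATE,
    SLOPE_STEEP,
)

KM_PER_DEG = np.pi * AUTHALIC_RADIUS_M / 180.0 / 1000.0


@dataclass(frozen=True)
class ScenarioSpec:
    """One scenario: a mask source, its application resolution, group."""

    name: str
    mask_source: str  # bundle scenario-mask key, or "derived:<rule>", or "base"
    application_res: Literal["mid", "coarse"]
    group: Literal["base", "social", "ecosystem_services", "government"]
    params: dict = field(default_factory=dict)


@dataclass(frozen=True)
class CombinationRecord:
    """Intersection area of a set of scenario maps."""

    members: frozenset[str]
    area_Mha: float


def default_scenarios(radius_km: float | None = None) -> list[ScenarioSpec]:
    """The eight standard scenarios.

    ``radius_km`` overrides the forest-neighborhood window radius; by
    default it is 2.2 coarse-pixel widths (the real-scale default of 5 km
    corresponds to a 1 km-class grid).
    """
    fn_params: dict = {"threshold": 0.30}
    if radius_km is not None:
        fn_params["radius_km"] = radius_km
    return [
        ScenarioSpec("constrained", "base", "mid", "base"),
        ScenarioSpec("high_rights", "high_rights", "mid", "social"),
        ScenarioSpec("secure_tenure", "secure_tenure", "mid", "social"),
        ScenarioSpec(
            "low_livelihood_conflict", "low_livelihood_conflict", "mid", "social"
        ),
        ScenarioSpec(
            "forest_neighborhood", "derived:forest_neighborhood", "coarse",
            "ecosystem_services", fn_params,
        ),
        ScenarioSpec(
            "water_quality", "derived:water_quality", "mid", "ecosystem_services"
        ),
        ScenarioSpec("protected_areas", "protected_areas", "mid", "government"),
        ScenarioSpec("restoration_goals", "restoration_goals", "mid", "government"),
    ]


def forest_neighborhood_mask(
    forest_cover: Grid, radius_km: float, threshold: float
) -> Grid:
    """1 where mean forest cover within ``radius_km`` of the cell center
    exceeds ``threshold``.

    Window membership is by great-circle cell-center distance (circular
    window); cells near the grid edge use the available cells only.
    """
    if not 0.0 < threshold < 1.0:
        raise RasterError("threshold must lie in (0, 1)")
    geom = forest_cover.geometry
    t = geom.transform
    lat_c = np.radians(geom.lat_centers())
    lon_c = np.radians(geom.lon_centers())
    mid_lat = float(np.mean(lat_c))
    cell_km = min(t.px_height * KM_PER_DEG, t.px_width * KM_PER_DEG * abs(np.cos(mid_lat)))
    if radius_km <= 0 or radius_km < cell_km:
        raise RasterError("window radius must be at least one cell")

    values = np.asarray(forest_cover.values, dtype=float)
    valid = forest_cover.valid_mask() & np.isfinite(values)
    v = np.where(valid, values, 0.0)
    rows, cols = geom.shape
    r_earth_km = AUTHALIC_RADIUS_M / 1000.0

    dlon = lon_c[None, :] - lon_c[:, None]  # (cols, cols)
    out = np.zeros((rows, cols), dtype=np.uint8)
    for i in range(rows):
        # haversine from row i centers to every cell
        lat1 = lat_c[i]
        dlat = lat_c - lat1  # (rows,)
        a = (
            np.sin(dlat[None, :, None] / 2) ** 2
            + np.cos(lat1)
            * np.cos(lat_c)[None, :, None]
            * np.sin(dlon[:, None, :] / 2) ** 2
        )  # (cols_i, rows, cols)
        dist = 2.0 * r_earth_km * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
        member = dist <= radius_km
        num = np.einsum("jrc,rc->j", member, v)
        den = np.einsum("jrc,rc->j", member, valid.astype(float))
        mean = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
        out[i] = (mean > threshold).astype(np.uint8)
    return Grid(out, t, nodata=None, res_class=forest_cover.res_class)


def water_quality_mask(slope_class: Grid, landform: Grid) -> Grid:
    """1 iff slope class is moderate (20-35%) or landform is floodplain."""
    require_aligned(slope_class, landform)
    s = slope_class.values
    l = landform.values
    if not np.isin(s[slope_class.valid_mask()], (SLOPE_FLAT, SLOPE_MODERATE, SLOPE_STEEP)).all():
        raise RasterError("unknown slope class code")
    if not np.isin(l[landform.valid_mask()], (LANDFORM_UPLAND, LANDFORM_FLOODPLAIN)).all():
        raise RasterError("unknown landform code")
    keep = (s == SLOPE_MODERATE) | (l == LANDFORM_FLOODPLAIN)
    return Grid(
        keep.astype(np.uint8), slope_class.transform, nodata=None,
        res_class=slope_class.res_class,
    )


def _scenario_mask(spec: ScenarioSpec, cascade: CascadeResult, bundle) -> Grid:
    if spec.mask_source.startswith("derived:"):
        rule = spec.mask_source.split(":", 1)[1]
        if rule == "forest_neighborhood":
            t = cascade.coarse_geometry.transform
            radius = spec.params.get("radius_km") or 2.2 * t.px_height * KM_PER_DEG
            return forest_neighborhood_mask(
                bundle.forest_cover_coarse, radius, spec.params.get("threshold", 0.30)
            )
        if rule == "water_quality":
            fine_mask = water_quality_mask(bundle.slope_class, bundle.landform)
            mid = resample(fine_mask, cascade.mid_geometry, "nearest", res_class="mid")
            vals = np.where(np.isnan(mid.values.astype(float)), 0, mid.values).astype(np.uint8)
            return Grid(vals, mid.transform, nodata=None, res_class="mid")
        raise RasterError(f"unknown derived scenario rule: {rule!r}")
    try:
        return bundle.scenario_masks[spec.mask_source]
    except KeyError as exc:
        raise RasterError(f"unknown scenario mask source: {spec.mask_source!r}") from exc


def apply_scenario(spec: ScenarioSpec, cascade: CascadeResult, bundle) -> PotentialMap:
    """Apply one scenario overlay to the constrained cascade.

    Pixels outside the scenario mask become fully excluded (proportion
    excluded set to 1) at the scenario's application resolution; the
    retained cascade intermediates then flow through the usual averaging
    and 1 - p steps.
    """
    if spec.mask_source == "base":
        return cascade.constrained
    mask = _scenario_mask(spec, cascade, bundle)
    fp = cascade.forest_potential
    if spec.application_res == "mid":
        prop_mid = cascade.prop_excluded_mid["constrained"]
        require_aligned(prop_mid, mask)
        masked = np.where(mask.values == 1, prop_mid.values, 1.0)
        masked_grid = Grid(masked, prop_mid.transform, nodata=np.nan, res_class="mid")
        prop_coarse = resample(masked_grid, cascade.coarse_geometry, "mean",
                               res_class="coarse")
    else:
        prop_coarse_base = cascade.prop_excluded_coarse["constrained"]
        require_aligned(prop_coarse_base, mask)
        masked = np.where(mask.values == 1, prop_coarse_base.values, 1.0)
        prop_coarse = Grid(masked, prop_coarse_base.transform, nodata=np.nan,
                           res_class="coarse")
    return potential_map(fp, prop_coarse, "constrained",
                         {"scenario": spec.name, "group": spec.group})


def run_scenarios(
    cascade: CascadeResult, bundle, specs: list[ScenarioSpec] | None = None
) -> dict[str, PotentialMap]:
    """Apply a list of scenarios (default: the standard eight)."""
    specs = specs if specs is not None else default_scenarios()
    return {spec.name: apply_scenario(spec, cascade, bundle) for spec in specs}


def combination_areas(
    maps: dict[str, PotentialMap],
    areas: AreaRaster,
    combos: list[list[str]] | list[frozenset[str]],
) -> list[CombinationRecord]:
    """Intersection areas for scenario combinations.

    The intersection of maps sharing one base cascade is the cellwise
    minimum of their availabilities (members differ only by masking of a
    shared base, so the minimum is the exact joint availability).
    """
    records = []
    for combo in combos:
        members = frozenset(combo)
        if not members:
            raise RasterError("a combination must have at least one member")
        stack = []
        for name in sorted(members):
            if name not in maps:
                raise RasterError(f"unknown scenario map: {name!r}")
            stack.append(maps[name].availability.values)
        inter = np.minimum.reduce(stack)
        pm = PotentialMap(
            availability=Grid(
                inter, maps[sorted(members)[0]].availability.transform,
                nodata=None, res_class="coarse",
            ),
            stage="intersection",
        )
        records.append(CombinationRecord(members, area_summary(pm, areas)))
    return records
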