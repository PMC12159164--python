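"""End-to-end pipeline: cascade, scenarios, combinations and accounting.

This is the orchestration layer behind the command-line interface and
the worked examples: it runs the forest-potential + exclusion cascade,
applies the scenario overlays, computes scenario-combination
intersection areas, and attaches mitigation, population and
additionality accounting to every map, producing one tidy summary table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import geotiff
from .accounting import (
    FluxLayer,
    additionality_adjust,
    cells_from_bundle,
    mitigation_summary,
    population_summary,
)
from .cascade import (
    CascadeResult,
    ExclusionConfig,
    PotentialMap,
    area_summary,
    run_cascade,
)
from .forest_potential import (
    CLOSED_FOREST,
    OPEN_FOREST,
    ForestPotentialCriteria,
)
from .raster_core import Grid
from .scenarios import (
    CombinationRecord,
    ScenarioSpec,
    combination_areas,
    default_scenarios,
    run_scenarios,
)

#: Named sensitivity runs (forest-definition and exclusion-dataset variants).
VARIANTS = ("no-fire", "tc50", "tc30-open", "alt-forest", "alt-cropland", "no-cropland")


def variant_settings(
    variant: str | None,
    criteria: ForestPotentialCriteria = ForestPotentialCriteria(),
    exclusions: ExclusionConfig = ExclusionConfig(),
) -> tuple[ForestPotentialCriteria, ExclusionConfig]:
    """Map a named sensitivity variant onto criteria/exclusion settings."""
    if variant is None:
        return criteria, exclusions
    if variant == "no-fire":
        return replace(criteria, apply_fire_filter=False), exclusions
    if variant == "tc50":
        return replace(criteria, tree_cover_threshold=50.0), exclusions
    if variant == "tc30-open":
        return (
            replace(
                criteria,
                tree_cover_threshold=30.0,
                walker_classes_allowed=frozenset({CLOSED_FOREST, OPEN_FOREST}),
            ),
            exclusions,
        )
    if variant == "alt-forest":
        return criteria, replace(exclusions, forest_layer="existing_forest_alt")
    if variant == "alt-cropland":
        return criteria, replace(exclusions, cropland_source="single")
    if variant == "no-cropland":
        return criteria, replace(exclusions, include_cropland=False)
    raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")


def default_combinations(specs: list[ScenarioSpec]) -> list[list[str]]:
    """Singletons, the three thematic groups, and the all-scenario set."""
    names = [s.name for s in specs if s.group != "base"]
    groups: dict[str, list[str]] = {}
    for s in specs:
        if s.group != "base":
            groups.setdefault(s.group, []).append(s.name)
    combos: list[list[str]] = [[n] for n in names]
    combos += [members for members in groups.values() if len(members) > 1]
    if len(names) > 1:
        combos.append(names)
        combos.append(["constrained", *names])
    return combos


@dataclass
class PipelineResult:
    """Everything a full pipeline run produces."""

    cascade: CascadeResult
    scenario_maps: dict[str, PotentialMap]
    combinations: list[CombinationRecord]
    summary: pd.DataFrame


def run_pipeline(
    bundle,
    criteria: ForestPotentialCriteria = ForestPotentialCriteria(),
    exclusions: ExclusionConfig = ExclusionConfig(),
    scenario_specs: list[ScenarioSpec] | None = None,
    combos: list[list[str]] | None = None,
    variant: str | None = None,
) -> PipelineResult:
    """Run cascade + scenarios + combinations + accounting on a bundle."""
    criteria, exclusions = variant_settings(variant, criteria, exclusions)
    specs = scenario_specs if scenario_specs is not None else default_scenarios()
    cascade = run_cascade(bundle, criteria, exclusions)
    maps = run_scenarios(cascade, bundle, specs)
    combos = combos if combos is not None else default_combinations(specs)
    records = combination_areas(maps, cascade.areas, combos)

    flux = FluxLayer(bundle.flux)
    cells = cells_from_bundle(bundle)
    rows = []

    fp_pm = PotentialMap(
        availability=Grid(
            cascade.forest_potential.values.astype(float),
            cascade.forest_potential.transform,
            res_class="coarse",
        ),
        stage="forest_potential",
    )
    rows.append(
        {
            "map_or_combo": "forest_potential",
            "area_Mha": area_summary(fp_pm, cascade.areas),
            "area_additional_Mha": np.nan,
            "mitigation_TgCO2e_yr": np.nan,
            "mitigation_additional_TgCO2e_yr": np.nan,
            "population_millions": np.nan,
        }
    )

    accounted: dict[str, PotentialMap] = {"maximum": cascade.maximum, **maps}
    for name, pm in accounted.items():
        adj_area, adj_mit = additionality_adjust(pm, cascade.areas, flux, cells)
        rows.append(
            {
                "map_or_combo": name,
                "area_Mha": area_summary(pm, cascade.areas),
                "area_additional_Mha": adj_area,
                "mitigation_TgCO2e_yr": mitigation_summary(pm, cascade.areas, flux),
                "mitigation_additional_TgCO2e_yr": adj_mit,
                "population_millions": population_summary(pm, bundle.population) / 1e6,
            }
        )
    for rec in records:
        rows.append(
            {
                "map_or_combo": ";".join(sorted(rec.members)),
                "area_Mha": rec.area_Mha,
                "area_additional_Mha": np.nan,
                "mitigation_TgCO2e_yr": np.nan,
                "mitigation_additional_TgCO2e_yr": np.nan,
                "population_millions": np.nan,
            }
        )
    summary = pd.DataFrame(rows)
    return PipelineResult(cascade, maps, records, summary)


def write_outputs(result: PipelineResult, out_dir: str | Path) -> Path:
    """Write the three core maps (GeoTIFF), scenario maps, the summary
    table and the combination table to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    geotiff.write_geotiff(out / "forest_potential.tif", result.cascade.forest_potential)
    geotiff.write_geotiff(out / "maximum.tif", result.cascade.maximum.availability)
    geotiff.write_geotiff(out / "constrained.tif", result.cascade.constrained.availability)
    for name, pm in result.scenario_maps.items():
        if name != "constrained":
            geotiff.write_geotiff(out / f"scenario_{name}.tif", pm.availability)
    result.summary.to_csv(out / "summary.csv", index=False, float_format="%.10g")
    combo_rows = [
        {"members": ";".join(sorted(r.members)), "area_Mha": r.area_Mha}
        for r in result.combinations
    ]
    pd.DataFrame(combo_rows).to_csv(out / "combinations.csv", index=False,
                                    float_format="%.10g")
    return out
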