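"""Mitigation, population and additionality accounting for potential maps.

All three summaries are linear in availability:

* net mitigation (TgCO2e/yr) = sum(availability x area_ha x flux) / 1e6,
  where flux is the albedo-adjusted 30-year mean sequestration rate in
  tCO2e/ha/yr;
* affected population = sum(availability x per-pixel population), i.e.
  people in partially available pixels count proportionally;
* additionality scales each one-degree cell's area and mitigation totals
  by a forest loss:gain ratio capped at 1 — where background forest gain
  already matches or exceeds loss, reforestation there is discounted as
  non-additional.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cascade import PotentialMap
from .raster_core import AreaRaster, Grid, RasterError, require_aligned


@dataclass
class FluxLayer:
    """Net sequestration flux, tCO2e/ha/yr, albedo-adjusted."""

    flux: Grid

    def __post_init__(self) -> None:
        v = self.flux.values[self.flux.valid_mask()]
        if v.size and not np.isfinite(v).all():
            raise RasterError("flux must be finite where defined")


@dataclass(frozen=True)
class AdditionalityCell:
    """One-degree cell (integer south-west corner) with loss/gain totals."""

    lat0: int
    lon0: int
    loss: float
    gain: float

    @property
    def ratio(self) -> float:
        """min(loss/gain, 1); by convention 1 when gain is zero (no
        background regrowth => fully additional) and 1 when loss and gain
        are both zero (no evidence of background recovery)."""
        if self.gain <= 0.0:
            return 1.0
        return min(self.loss / self.gain, 1.0)


def mitigation_summary(pm: PotentialMap, areas: AreaRaster, flux: FluxLayer) -> float:
    """Availability-weighted net mitigation in TgCO2e per year."""
    require_aligned(pm.availability, areas, flux.flux)
    f = np.where(flux.flux.valid_mask(), flux.flux.values, 0.0)
    return float(np.sum(pm.availability.values * areas.values * f) / 1e6)


def population_summary(pm: PotentialMap, population: Grid) -> float:
    """Availability-weighted person count (proportional in partial pixels)."""
    require_aligned(pm.availability, population)
    p = np.asarray(population.values, dtype=float)
    valid = population.valid_mask()
    if p[valid].size and p[valid].min() < 0:
        raise RasterError("population must be non-negative")
    return float(np.sum(pm.availability.values * np.where(valid, p, 0.0)))


def _cell_index(pm: PotentialMap, cells: list[AdditionalityCell]) -> np.ndarray:
    """Per-pixel index into ``cells`` by pixel-center membership."""
    geom = pm.availability.geometry
    lat_c = geom.lat_centers()
    lon_c = geom.lon_centers()
    keys = {(c.lat0, c.lon0): k for k, c in enumerate(cells)}
    la = np.floor(lat_c).astype(int)
    lo = np.floor(lon_c).astype(int)
    idx = np.empty(geom.shape, dtype=int)
    for i in range(geom.shape[0]):
        for j in range(geom.shape[1]):
            key = (la[i], lo[j])
            if key not in keys:
                raise RasterError(
                    f"pixel center at ({lat_c[i]:.4f}, {lon_c[j]:.4f}) is not "
                    f"covered by any one-degree cell"
                )
            idx[i, j] = keys[key]
    return idx


def additionality_adjust(
    pm: PotentialMap,
    areas: AreaRaster,
    flux: FluxLayer,
    cells: list[AdditionalityCell],
) -> tuple[float, float]:
    """Additionality-adjusted (area Mha, mitigation TgCO2e/yr).

    Every coarse pixel is assigned to one one-degree cell by its center;
    the cell's loss:gain ratio scales that cell's area and mitigation
    contributions before the global sums.
    """
    require_aligned(pm.availability, areas, flux.flux)
    idx = _cell_index(pm, cells)
    ratios = np.array([c.ratio for c in cells])[idx]
    f = np.where(flux.flux.valid_mask(), flux.flux.values, 0.0)
    area_ha = pm.availability.values * areas.values
    adj_area = float(np.sum(ratios * area_ha) / 1e6)
    adj_mit = float(np.sum(ratios * area_ha * f) / 1e6)
    return adj_area, adj_mit


def cells_from_bundle(bundle) -> list[AdditionalityCell]:
    """Build the one-degree cell list from a bundle's loss/gain tables."""
    return [
        AdditionalityCell(la, lo, bundle.forest_loss[(la, lo)], bundle.forest_gain[(la, lo)])
        for (la, lo) in sorted(bundle.forest_loss)
    ]
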