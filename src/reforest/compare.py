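"""Multi-map agreement and intersection analysis.

Published forest-potential and reforestation-potential products differ in
their forest definitions; to compare them each product is first
*reclassified* to a binary map by a declarative rule (a threshold on a
continuous layer or a retained-class set on a categorical one), rescaled
to a common grid, and then summed cellwise.  The agreement count raster,
the area at each agreement level, and all pairwise intersection areas
are reported with latitude-aware area weighting.  Per-level areas
partition the union area exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .raster_core import AreaRaster, Grid, RasterError, require_aligned


@dataclass(frozen=True)
class ReclassRule:
    """Declarative binarization rule: threshold or retained-class set.

    ``kind='threshold'`` keeps cells with value strictly greater than
    ``threshold``; ``kind='classes'`` keeps cells whose code is in
    ``classes``.
    """

    kind: str  # "threshold" | "classes"
    threshold: float | None = None
    classes: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.kind not in ("threshold", "classes"):
            raise RasterError(f"unknown reclassification rule kind: {self.kind!r}")
        if self.kind == "threshold" and self.threshold is None:
            raise RasterError("threshold rule requires a threshold value")
        if self.kind == "classes" and not self.classes:
            raise RasterError("class rule requires a nonempty class set")


@dataclass
class AgreementResult:
    """Agreement count raster plus per-level and pairwise area tables."""

    count: Grid
    names: list[str]
    per_level_areas: list[tuple[int, float]]  # (agreement count, Mha)
    pairwise_Mha: np.ndarray  # symmetric (N, N)

    def per_level_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.per_level_areas, columns=["agreement_count", "area_Mha"])

    def pairwise_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairwise_Mha, index=self.names, columns=self.names)


def reclassify_product(raw: Grid, rule: ReclassRule) -> Grid:
    """Binarize a product map according to a declarative rule.

    Nodata cells map to 0 (not retained).  A class rule referencing codes
    absent from the layer's observed codes is rejected, to catch
    misconfigured rules early.
    """
    valid = raw.valid_mask()
    if rule.kind == "threshold":
        v = np.asarray(raw.values, dtype=float)
        keep = valid & (v > float(rule.threshold))  # type: ignore[arg-type]
    else:
        present = set(np.unique(raw.values[valid]).tolist())
        unknown = {c for c in rule.classes if c not in present}
        if unknown == set(rule.classes):
            raise RasterError(
                f"rule references categories absent from the layer: {sorted(unknown)}"
            )
        keep = valid & np.isin(raw.values, sorted(rule.classes))
    return Grid(
        keep.astype(np.uint8), raw.transform, nodata=None, res_class=raw.res_class
    )


def agreement(
    maps: dict[str, Grid] | list[Grid], areas: AreaRaster
) -> AgreementResult:
    """Cellwise agreement count, per-level areas and pairwise intersections.

    Inputs must share one geometry (rescale by nearest neighbour first);
    nodata cells count as 0.
    """
    if isinstance(maps, dict):
        names = list(maps.keys())
        grids = list(maps.values())
    else:
        names = [f"map_{k}" for k in range(len(maps))]
        grids = list(maps)
    if not grids:
        raise RasterError("agreement requires at least one map")
    require_aligned(*grids, areas)
    binmaps = []
    for name, g in zip(names, grids):
        if not g.is_binary():
            raise RasterError(f"map {name!r} is not binary")
        binmaps.append(np.where(g.valid_mask(), g.values, 0).astype(np.int32))
    count = np.sum(binmaps, axis=0)
    n = len(binmaps)
    per_level = [
        (k, float(np.sum((count == k) * areas.values) / 1e6)) for k in range(1, n + 1)
    ]
    pair = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            inter = binmaps[i] & binmaps[j]
            pair[i, j] = pair[j, i] = float(np.sum(inter * areas.values) / 1e6)
    count_grid = Grid(count, grids[0].transform, nodata=None, res_class=grids[0].res_class)
    return AgreementResult(count_grid, names, per_level, pair)
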