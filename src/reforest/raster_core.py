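"""Grid data model and raster primitives for geographic (lat/lon) rasters.

Everything downstream — exclusion cascades, scenario overlays, area and
mitigation accounting — is built from the three primitives defined here:

* :func:`resample` — nearest / bilinear / max / mean resampling between
  axis-aligned geographic grids, with nodata propagation.  Mean aggregation
  is *area-weighted* (spherical band weights), so aggregating a value field
  conserves the global sum of value x pixel-area exactly.
* :func:`pixel_area` — latitude-dependent per-pixel area in hectares from
  the spherical band formula A = R^2 * dlambda * (sin(phi_top) - sin(phi_bot)).
* :func:`mask_apply` — cellwise masking with nodata preservation.

Grids use the area (cell) convention: the transform origin is the outer
corner of the top-left pixel and a value describes the whole cell.  Only
geographic lat/lon grids are supported; there is no reprojection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

#: Authalic Earth radius in metres (sphere with the same surface area as
#: the WGS84 ellipsoid).  Configurable per call in :func:`pixel_area`.
AUTHALIC_RADIUS_M = 6_371_007.2

M2_PER_HA = 1.0e4

ResClass = Literal["fine", "mid", "coarse"]
ResampleMethod = Literal["nearest", "bilinear", "max", "mean"]


class RasterError(ValueError):
    """Base class for raster-model violations."""


class AlignmentError(RasterError):
    """Layers combined in one operation do not share a geometry."""


@dataclass(frozen=True)
class GridTransform:
    """Geographic affine transform (north-up, axis-aligned).

    ``origin_lon``/``origin_lat`` locate the outer corner of the top-left
    pixel; rows advance southward, columns eastward.  Pixel sizes are in
    degrees and strictly positive.
    """

    origin_lon: float
    origin_lat: float
    px_width: float
    px_height: float

    def __post_init__(self) -> None:
        if not (self.px_width > 0 and self.px_height > 0):
            raise RasterError("pixel width and height must be strictly positive")


@dataclass(frozen=True)
class GridGeometry:
    transform: GridTransform
    shape: tuple[int, int]

    def __post_init__(self) -> None:
        rows, cols = self.shape
        if rows <= 0 or cols <= 0:
            raise RasterError("grid must have at least one row and one column")

    # pixel edges / centers, used by every resampling kernel
    def lon_edges(self) -> np.ndarray:
        t = self.transform
        return t.origin_lon + t.px_width * np.arange(self.shape[1] + 1)

    def lat_edges(self) -> np.ndarray:
        t = self.transform
        return t.origin_lat - t.px_height * np.arange(self.shape[0] + 1)

    def lon_centers(self) -> np.ndarray:
        e = self.lon_edges()
        return 0.5 * (e[:-1] + e[1:])

    def lat_centers(self) -> np.ndarray:
        e = self.lat_edges()
        return 0.5 * (e[:-1] + e[1:])

    def bounds(self) -> tuple[float, float, float, float]:
        """(west, south, east, north)."""
        t = self.transform
        rows, cols = self.shape
        return (
            t.origin_lon,
            t.origin_lat - rows * t.px_height,
            t.origin_lon + cols * t.px_width,
            t.origin_lat,
        )


@dataclass
class Grid:
    """A single-band geographic raster.

    Parameters
    ----------
    values
        2-D array; floats for continuous fields, integer codes for
        categorical layers.
    transform
        Geographic transform of the top-left pixel corner.
    nodata
        Sentinel for missing cells, or None if the layer is complete.
        Never a valid category code.
    res_class
        Resolution class tag: "fine", "mid" or "coarse" (the 30 m /
        500 m / 1 km analogues of the cascade).
    categorical
        True for class-coded layers; bilinear resampling is rejected
        for these.
    """

    values: np.ndarray
    transform: GridTransform
    nodata: float | int | None = None
    res_class: ResClass = "coarse"
    categorical: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise RasterError("Grid values must be a 2-D array")
        if self.values.size == 0:
            raise RasterError("grid must have at least one row and one column")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def geometry(self) -> GridGeometry:
        return GridGeometry(self.transform, self.shape)

    def valid_mask(self) -> np.ndarray:
        if self.nodata is None:
            return np.ones(self.shape, dtype=bool)
        if isinstance(self.nodata, float) and np.isnan(self.nodata):
            return ~np.isnan(self.values)
        return self.values != self.nodata

    def with_values(self, values: np.ndarray, **kw) -> "Grid":
        g = replace(self, values=np.asarray(values))
        for k, v in kw.items():
            setattr(g, k, v)
        return g

    def is_binary(self) -> bool:
        v = self.values[self.valid_mask()]
        return bool(np.isin(v, (0, 1)).all())


@dataclass
class AreaRaster:
    """Per-pixel area in hectares on a geographic grid."""

    values: np.ndarray
    transform: GridTransform

    @property
    def geometry(self) -> GridGeometry:
        return GridGeometry(self.transform, self.values.shape)


def _same_geometry(a: GridGeometry, b: GridGeometry, tol: float = 1e-9) -> bool:
    if a.shape != b.shape:
        return False
    ta, tb = a.transform, b.transform
    return (
        abs(ta.origin_lon - tb.origin_lon) <= tol
        and abs(ta.origin_lat - tb.origin_lat) <= tol
        and abs(ta.px_width - tb.px_width) <= tol
        and abs(ta.px_height - tb.px_height) <= tol
    )


def require_aligned(*grids: Grid | AreaRaster) -> None:
    """Raise :class:`AlignmentError` unless all grids share one geometry."""
    ref = grids[0].geometry
    for g in grids[1:]:
        if not _same_geometry(ref, g.geometry):
            raise AlignmentError("layers do not share an identical transform and shape")


def _overlap_matrix(t_edges: np.ndarray, s_edges: np.ndarray, weight: str) -> np.ndarray:
    """Dense (target x source) matrix of interval-overlap weights.

    ``weight='lon'`` gives overlap length in degrees; ``weight='sinlat'``
    gives sin(phi_hi) - sin(phi_lo) of the overlap, i.e. the spherical
    band weight.  Edge arrays may be ascending (lon) or descending (lat).
    """
    t_lo = np.minimum(t_edges[:-1], t_edges[1:])[:, None]
    t_hi = np.maximum(t_edges[:-1], t_edges[1:])[:, None]
    s_lo = np.minimum(s_edges[:-1], s_edges[1:])[None, :]
    s_hi = np.maximum(s_edges[:-1], s_edges[1:])[None, :]
    lo = np.maximum(t_lo, s_lo)
    hi = np.minimum(t_hi, s_hi)
    if weight == "lon":
        return np.clip(hi - lo, 0.0, None)
    out = np.sin(np.radians(np.maximum(hi, lo))) - np.sin(np.radians(lo))
    out[hi <= lo] = 0.0
    return out


def _check_overlap(src: GridGeometry, target: GridGeometry) -> None:
    sw, ss, se, sn = src.bounds()
    tw, ts, te, tn = target.bounds()
    if te <= sw or tw >= se or tn <= ss or ts >= sn:
        raise RasterError("target geometry does not overlap the source grid")


def _resample_mean(src: Grid, target: GridGeometry) -> np.ndarray:
    wr = _overlap_matrix(target.lat_edges(), src.geometry.lat_edges(), "sinlat")
    wc = _overlap_matrix(target.lon_edges(), src.geometry.lon_edges(), "lon")
    valid = src.valid_mask()
    v = np.where(valid, src.values, 0.0).astype(float)
    num = wr @ v @ wc.T
    den = wr @ valid.astype(float) @ wc.T
    out = np.full(target.shape, np.nan)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out


def _index_ranges(t_edges: np.ndarray, s_edges: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous source-index range [i0, i1) overlapping each target cell."""
    asc = s_edges[0] < s_edges[-1]
    se = s_edges if asc else s_edges[::-1]
    n = len(s_edges) - 1
    ranges = []
    for lo, hi in zip(t_edges[:-1], t_edges[1:]):
        a, b = (lo, hi) if lo < hi else (hi, lo)
        i0 = int(np.searchsorted(se, a, side="right")) - 1
        i1 = int(np.searchsorted(se, b, side="left"))
        i0, i1 = max(i0, 0), min(i1, n)
        if not asc:
            i0, i1 = n - i1, n - i0
        ranges.append((i0, max(i1, i0)))
    return ranges


def _resample_max(src: Grid, target: GridGeometry) -> np.ndarray:
    rr = _index_ranges(target.lat_edges(), src.geometry.lat_edges())
    cr = _index_ranges(target.lon_edges(), src.geometry.lon_edges())
    valid = src.valid_mask()
    v = np.where(valid, src.values.astype(float), -np.inf)
    out = np.full(target.shape, np.nan)
    for i, (r0, r1) in enumerate(rr):
        if r1 <= r0:
            continue
        for j, (c0, c1) in enumerate(cr):
            if c1 <= c0:
                continue
            m = v[r0:r1, c0:c1].max()
            if np.isfinite(m):
                out[i, j] = m
    return out


def _resample_nearest(src: Grid, target: GridGeometry) -> np.ndarray:
    t = src.transform
    rows, cols = src.shape
    lc = target.lon_centers()
    ltc = target.lat_centers()
    ci = np.floor((lc - t.origin_lon) / t.px_width).astype(int)
    ri = np.floor((t.origin_lat - ltc) / t.px_height).astype(int)
    ok_c = (ci >= 0) & (ci < cols)
    ok_r = (ri >= 0) & (ri < rows)
    ri_c = np.clip(ri, 0, rows - 1)
    ci_c = np.clip(ci, 0, cols - 1)
    out = src.values[np.ix_(ri_c, ci_c)].astype(float)
    valid = src.valid_mask()[np.ix_(ri_c, ci_c)]
    bad = ~(ok_r[:, None] & ok_c[None, :]) | ~valid
    out[bad] = np.nan
    return out


def _resample_bilinear(src: Grid, target: GridGeometry) -> np.ndarray:
    sg = src.geometry
    rows, cols = src.shape
    xc = sg.lon_centers()
    yc = sg.lat_centers()  # descending
    t = src.transform
    # fractional index of target centers in source center coordinates
    fx = (target.lon_centers() - xc[0]) / t.px_width
    fy = (yc[0] - target.lat_centers()) / t.px_height
    inside = (fx >= -0.5) & (fx <= cols - 0.5)
    inside_y = (fy >= -0.5) & (fy <= rows - 0.5)
    fx = np.clip(fx, 0.0, cols - 1.0)
    fy = np.clip(fy, 0.0, rows - 1.0)
    x0 = np.floor(fx).astype(int)
    y0 = np.floor(fy).astype(int)
    x0 = np.minimum(x0, cols - 2) if cols > 1 else x0 * 0
    y0 = np.minimum(y0, rows - 2) if rows > 1 else y0 * 0
    tx = fx - x0 if cols > 1 else fx * 0
    ty = fy - y0 if rows > 1 else fy * 0
    x1 = np.minimum(x0 + 1, cols - 1)
    y1 = np.minimum(y0 + 1, rows - 1)

    v = src.values.astype(float)
    Y0, X0 = np.ix_(y0, x0)
    Y1, X1 = np.ix_(y1, x1)
    TY, TX = ty[:, None], tx[None, :]
    out = (
        v[Y0, X0] * (1 - TY) * (1 - TX)
        + v[Y0, X1] * (1 - TY) * TX
        + v[Y1, X0] * TY * (1 - TX)
        + v[Y1, X1] * TY * TX
    )
    # nodata propagates from any corner that actually contributes
    invalid = ~src.valid_mask()
    w00 = (1 - TY) * (1 - TX)
    w01 = (1 - TY) * TX
    w10 = TY * (1 - TX)
    w11 = TY * TX
    bad = (
        (invalid[Y0, X0] & (w00 > 0))
        | (invalid[Y0, X1] & (w01 > 0))
        | (invalid[Y1, X0] & (w10 > 0))
        | (invalid[Y1, X1] & (w11 > 0))
    )
    out[bad] = np.nan
    out[~(inside_y[:, None] & inside[None, :])] = np.nan
    return out


def resample(
    src: Grid,
    target: GridGeometry,
    method: ResampleMethod,
    res_class: ResClass | None = None,
) -> Grid:
    """Resample ``src`` onto ``target`` geometry.

    ``mean`` and ``max`` are aggregation kernels over all source cells
    overlapping a target cell (mean is area-weighted by spherical band
    area so value x area sums are conserved on nested grids); ``nearest``
    and ``bilinear`` sample at target cell centers.  Nodata cells are
    ignored by mean/max and a target cell is nodata only when no valid
    source cell contributes; nearest/bilinear propagate nodata.

    Raises
    ------
    RasterError
        If ``bilinear`` is requested on a categorical grid, the method is
        unknown, or the geometries are disjoint.
    """
    if method not in ("nearest", "bilinear", "max", "mean"):
        raise RasterError(f"unknown resampling method: {method!r}")
    if method == "bilinear" and src.categorical:
        raise RasterError("bilinear resampling is not defined for categorical grids")
    if method == "mean" and src.categorical:
        raise RasterError("mean resampling is not defined for categorical grids")
    _check_overlap(src.geometry, target)
    kernel = {
        "mean": _resample_mean,
        "max": _resample_max,
        "nearest": _resample_nearest,
        "bilinear": _resample_bilinear,
    }[method]
    out = kernel(src, target)
    values = out
    nodata: float | int | None = np.nan
    if method in ("nearest", "max") and src.categorical:
        # keep category codes intact
        if src.nodata is not None and not (
            isinstance(src.nodata, float) and np.isnan(src.nodata)
        ):
            values = np.where(np.isnan(out), src.nodata, out).astype(src.values.dtype)
            nodata = src.nodata
        else:
            values = out
    return Grid(
        values=values,
        transform=target.transform,
        nodata=nodata,
        res_class=res_class or src.res_class,
        categorical=src.categorical and method in ("nearest", "max"),
    )


def pixel_area(grid: Grid | GridGeometry, radius_m: float = AUTHALIC_RADIUS_M) -> AreaRaster:
    """Per-pixel area in hectares on a sphere.

    Uses the spherical band formula
    ``A = R^2 * dlambda * (sin(phi_top) - sin(phi_bottom))`` so that area
    is exact for axis-aligned geographic cells and strictly decreasing
    with |latitude| for fixed angular size.
    """
    geom = grid if isinstance(grid, GridGeometry) else grid.geometry
    if radius_m <= 0:
        raise RasterError("sphere radius must be positive")
    lat = geom.lat_edges()
    if lat.max() > 90.0 + 1e-12 or lat.min() < -90.0 - 1e-12:
        raise RasterError("pixel latitudes must lie within [-90, 90] degrees")
    dlam = np.radians(geom.transform.px_width)
    band = np.sin(np.radians(lat[:-1])) - np.sin(np.radians(lat[1:]))  # positive
    area_m2 = radius_m**2 * dlam * band
    values = np.repeat(area_m2[:, None] / M2_PER_HA, geom.shape[1], axis=1)
    return AreaRaster(values=values, transform=geom.transform)


def mask_apply(values: Grid, mask: Grid, outside: float = 0.0) -> Grid:
    """Keep ``values`` where ``mask == 1``; set to ``outside`` elsewhere.

    Nodata cells of ``values`` stay nodata.
    """
    require_aligned(values, mask)
    if not mask.is_binary():
        raise RasterError("mask must be binary (0/1)")
    keep = mask.values == 1
    out = np.where(keep, values.values, outside)
    if values.nodata is not None:
        out = np.where(values.valid_mask(), out, values.nodata)
    return values.with_values(out)
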