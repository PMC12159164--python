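"""Single-band GeoTIFF read/write for :class:`~reforest.raster_core.Grid`.

Writes standard GeoTIFF georeferencing tags (ModelPixelScale,
ModelTiepoint, a minimal EPSG:4326 GeoKey directory and GDAL's nodata
tag) so files open in GDAL/QGIS, and round-trips the grid's resolution
class and categorical flag through the ImageDescription tag.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .raster_core import Grid, GridTransform, RasterError

_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_KEY_DIRECTORY = 34735
_TAG_GDAL_NODATA = 42113

# GTModelTypeGeoKey=2 (geographic), GTRasterTypeGeoKey=1 (PixelIsArea),
# GeographicTypeGeoKey=4326 (WGS84 lat/lon).
_GEO_KEYS = (1, 1, 0, 3, 1024, 0, 1, 2, 1025, 0, 1, 1, 2048, 0, 1, 4326)


def write_geotiff(path: str | Path, grid: Grid) -> None:
    """Write a Grid as a single-band GeoTIFF."""
    t = grid.transform
    desc = json.dumps(
        {"res_class": grid.res_class, "categorical": bool(grid.categorical)}
    )
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (t.px_width, t.px_height, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, t.origin_lon, t.origin_lat, 0.0)),
        (_TAG_GEO_KEY_DIRECTORY, "H", len(_GEO_KEYS), _GEO_KEYS),
    ]
    if grid.nodata is not None:
        nd = grid.nodata
        nd_str = "nan" if isinstance(nd, float) and np.isnan(nd) else repr(nd)
        extratags.append((_TAG_GDAL_NODATA, "s", 0, nd_str))
    values = grid.values
    if values.dtype == bool:
        values = values.astype(np.uint8)
    tifffile.imwrite(
        str(path),
        values,
        description=desc,
        extratags=extratags,
        photometric="minisblack",
    )


def read_geotiff(path: str | Path) -> Grid:
    """Read a single-band GeoTIFF written by :func:`write_geotiff` (or any
    GDAL-style geographic GeoTIFF with pixel-scale/tiepoint tags)."""
    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        values = page.asarray()
        tags = page.tags
        try:
            scale = tags[_TAG_MODEL_PIXEL_SCALE].value
            tie = tags[_TAG_MODEL_TIEPOINT].value
        except KeyError as exc:
            raise RasterError(f"{path}: missing GeoTIFF georeferencing tags") from exc
        transform = GridTransform(
            origin_lon=float(tie[3]) - float(tie[0]) * float(scale[0]),
            origin_lat=float(tie[4]) + float(tie[1]) * float(scale[1]),
            px_width=float(scale[0]),
            px_height=float(scale[1]),
        )
        nodata: float | int | None = None
        if _TAG_GDAL_NODATA in tags:
            raw = str(tags[_TAG_GDAL_NODATA].value).strip().strip("\x00")
            if raw:
                nodata = float(raw) if raw == "nan" or "." in raw or "e" in raw else int(raw)
        res_class = "coarse"
        categorical = False
        desc = tags.get("ImageDescription")
        if desc is not None:
            try:
                meta = json.loads(desc.value)
                res_class = meta.get("res_class", res_class)
                categorical = bool(meta.get("categorical", categorical))
            except (json.JSONDecodeError, TypeError):
                pass
    if values.ndim != 2:
        raise RasterError(f"{path}: expected a single-band raster")
    return Grid(
        values=values,
        transform=transform,
        nodata=nodata,
        res_class=res_class,  # type: ignore[arg-type]
        categorical=categorical,
    )


def write_manifest(path: str | Path, entries: dict[str, dict]) -> None:
    """Write a bundle manifest (layer name -> file, res_class, semantics)."""
    Path(path).write_text(json.dumps(entries, indent=2, sort_keys=True) + "\n")


def read_manifest(path: str | Path) -> dict[str, dict]:
    return json.loads(Path(path).read_text())
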