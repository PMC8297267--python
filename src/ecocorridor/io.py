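"""Raster and vector file I/O.

Rasters: GeoTIFF (via ``tifffile``, writing the standard GeoTIFF
georeferencing tags directly) and ESRI ASCII grid (``.asc`` with a ``.prj``
sidecar holding the CRS identifier).  Vectors: GeoJSON.

Round-trip contract: ``write_raster`` followed by ``read_raster`` returns
bit-identical finite values and identical grid metadata.
"""

from __future__ import annotations

import json
import os
from pathlib import Path
from typing import Any, Iterable, Mapping

import numpy as np
import tifffile
from shapely.geometry import mapping, shape as shapely_shape
from shapely.validation import make_valid

from .grid import GridError, GridRaster

# GeoTIFF tag codes
_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922
_GEO_KEY_DIRECTORY = 34735
_GDAL_NODATA = 42113


class RasterIOError(IOError):
    pass


class VectorIOError(IOError):
    pass


# ---------------------------------------------------------------------------
# rasters
# ---------------------------------------------------------------------------

def read_raster(path: str | os.PathLike) -> GridRaster:
    """Read a GeoTIFF or ESRI ASCII grid into a :class:`GridRaster`.

    Raises an explicit error naming the layer when the file is missing,
    the format is unsupported, or the layer carries no CRS.
    """
    path = Path(path)
    if not path.exists():
        raise RasterIOError(f"raster file not found: {path}")
    suffix = path.suffix.lower()
    if suffix in {".tif", ".tiff"}:
        return _read_geotiff(path)
    if suffix == ".asc":
        return _read_ascii_grid(path)
    raise RasterIOError(f"unsupported raster format {suffix!r} for layer {path.name}")


def write_raster(raster: GridRaster, path: str | os.PathLike) -> Path:
    """Write a :class:`GridRaster` to GeoTIFF or ESRI ASCII grid."""
    path = Path(path)
    if not path.parent.is_dir():
        raise RasterIOError(f"parent directory does not exist: {path.parent}")
    suffix = path.suffix.lower()
    if suffix in {".tif", ".tiff"}:
        _write_geotiff(raster, path)
    elif suffix == ".asc":
        _write_ascii_grid(raster, path)
    else:
        raise RasterIOError(f"unsupported raster format {suffix!r} for layer {path.name}")
    return path


def _crs_epsg(crs: str | None) -> int | None:
    if crs and crs.upper().startswith("EPSG:"):
        try:
            return int(crs.split(":", 1)[1])
        except ValueError:
            return None
    return None


def _write_geotiff(raster: GridRaster, path: Path) -> None:
    meta = {
        "cell_size": raster.cell_size,
        "origin": list(raster.origin),
        "crs": raster.crs,
        "nodata": raster.nodata,
    }
    extratags = [
        (_MODEL_PIXEL_SCALE, "d", 3, (raster.cell_size, raster.cell_size, 0.0)),
        (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, raster.origin[0], raster.origin[1], 0.0)),
    ]
    epsg = _crs_epsg(raster.crs)
    if epsg is not None:
        # minimal GeoKeyDirectory: projected model, CS type = EPSG code
        keys = (1, 1, 0, 2, 1024, 0, 1, 1, 3072, 0, 1, epsg)
        extratags.append((_GEO_KEY_DIRECTORY, "H", len(keys), keys))
    if raster.nodata is not None:
        nd = repr(raster.nodata).encode() + b"\x00"
        extratags.append((_GDAL_NODATA, "s", len(nd), nd))
    try:
        tifffile.imwrite(
            path,
            raster.values,
            description=json.dumps(meta),
            extratags=extratags,
        )
    except PermissionError as exc:
        raise RasterIOError(f"cannot write raster {path}: {exc}") from exc


def _read_geotiff(path: Path) -> GridRaster:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray()
        tags = page.tags
        meta: dict[str, Any] = {}
        desc = tags.get("ImageDescription")
        if desc is not None:
            try:
                meta = json.loads(desc.value)
            except (json.JSONDecodeError, TypeError):
                meta = {}
        cell_size = None
        origin = None
        scale_tag = tags.get(_MODEL_PIXEL_SCALE)
        tie_tag = tags.get(_MODEL_TIEPOINT)
        if scale_tag is not None and tie_tag is not None:
            cell_size = float(scale_tag.value[0])
            tie = tie_tag.value
            origin = (float(tie[3]) - float(tie[0]) * cell_size,
                      float(tie[4]) + float(tie[1]) * cell_size)
        crs = meta.get("crs")
        if crs is None:
            geokeys = tags.get(_GEO_KEY_DIRECTORY)
            if geokeys is not None:
                vals = list(geokeys.value)
                for i in range(4, len(vals), 4):
                    if vals[i] == 3072:
                        crs = f"EPSG:{vals[i + 3]}"
        nodata = meta.get("nodata")
        if nodata is None:
            nd_tag = tags.get(_GDAL_NODATA)
            if nd_tag is not None:
                raw = nd_tag.value
                if isinstance(raw, bytes):
                    raw = raw.decode()
                nodata = float(str(raw).strip("\x00 "))
        if cell_size is None:
            cell_size = meta.get("cell_size")
        if origin is None and "origin" in meta:
            origin = tuple(meta["origin"])
        if cell_size is None or origin is None:
            raise RasterIOError(f"layer {path.name} has no georeferencing")
        if crs is None:
            raise RasterIOError(f"layer {path.name} has no CRS")
    return GridRaster(values, cell_size, origin, crs, nodata)


def _write_ascii_grid(raster: GridRaster, path: Path) -> None:
    nrows, ncols = raster.shape
    nodata = raster.nodata if raster.nodata is not None else -9999
    x0, y0 = raster.origin
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {float(x0):.17g}\n"
        f"yllcorner {float(y0 - nrows * raster.cell_size):.17g}\n"
        f"cellsize {float(raster.cell_size):.17g}\n"
        f"NODATA_value {float(nodata):.17g}\n"
    )
    vals = raster.values
    if np.issubdtype(vals.dtype, np.floating) and raster.nodata is None:
        vals = np.where(np.isfinite(vals), vals, nodata)
    try:
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, vals, fmt="%.17g" if vals.dtype.kind == "f" else "%d")
        if raster.crs is not None:
            path.with_suffix(".prj").write_text(raster.crs + "\n")
    except PermissionError as exc:
        raise RasterIOError(f"cannot write raster {path}: {exc}") from exc


def _read_ascii_grid(path: Path) -> GridRaster:
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, _, val = line.partition(" ")
            key = key.strip().lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                       "nodata_value"}:
                header[key] = float(val)
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        values = np.loadtxt(fh, ndmin=2)
    for req in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if req not in header:
            raise RasterIOError(f"layer {path.name}: malformed ASCII grid header")
    nrows = int(header["nrows"])
    cell = header["cellsize"]
    origin = (header["xllcorner"], header["yllcorner"] + nrows * cell)
    prj = path.with_suffix(".prj")
    if not prj.exists():
        raise RasterIOError(f"layer {path.name} has no CRS (missing .prj sidecar)")
    crs = prj.read_text().strip()
    nodata = header.get("nodata_value")
    return GridRaster(values, cell, origin, crs, nodata)


# ---------------------------------------------------------------------------
# vectors
# ---------------------------------------------------------------------------

def write_vector(
    features: Iterable[Mapping[str, Any]],
    path: str | os.PathLike,
    crs: str | None = None,
    repair: bool = False,
) -> Path:
    """Write features to GeoJSON.

    Each feature is a mapping with a shapely ``geometry`` and a
    ``properties`` dict.  Invalid geometries are repaired with
    ``make_valid`` when ``repair`` is true, otherwise rejected.
    """
    path = Path(path)
    out = {"type": "FeatureCollection", "features": []}
    if crs is not None:
        out["crs"] = {"type": "name", "properties": {"name": crs}}
    for feat in features:
        geom = feat["geometry"]
        if geom is not None and not geom.is_valid:
            if repair:
                geom = make_valid(geom)
            else:
                raise VectorIOError(
                    f"invalid geometry in feature {feat.get('properties')}; "
                    "pass repair=True to fix automatically"
                )
        out["features"].append(
            {
                "type": "Feature",
                "geometry": mapping(geom) if geom is not None else None,
                "properties": dict(feat.get("properties", {})),
            }
        )
    try:
        path.write_text(json.dumps(out, indent=1, default=float))
    except PermissionError as exc:
        raise VectorIOError(f"cannot write vector file {path}: {exc}") from exc
    return path


def read_vector(path: str | os.PathLike) -> list[dict[str, Any]]:
    """Read a GeoJSON FeatureCollection into shapely features."""
    path = Path(path)
    if not path.exists():
        raise VectorIOError(f"vector file not found: {path}")
    data = json.loads(path.read_text())
    feats = []
    for feat in data.get("features", []):
        geom = feat.get("geometry")
        feats.append(
            {
                "geometry": shapely_shape(geom) if geom is not None else None,
                "properties": feat.get("properties", {}),
            }
        )
    return feats
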