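"""Raster I/O: GeoTIFF (via tifffile geo-tags) and ESRI ASCII grids.

Two dialects are supported. GeoTIFF is the primary on-disk format and is
read/written through :mod:`tifffile`, carrying georeferencing in the standard
GeoTIFF ``ModelPixelScale``/``ModelTiepoint`` tags and NoData in the
``GDAL_NODATA`` tag. ESRI ASCII grids (``.asc``) are plain text and serve as
human-readable fixtures; values are written with 17 significant digits so a
write/read roundtrip is bit-exact for float64.

All grids are float64 in memory with NoData as NaN; the accompanying
:class:`~windshift.landscape.Landscape` carries the boolean NoData mask.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .landscape import GeometryMismatchError, Landscape

__all__ = ["read_grid", "write_grid", "write_result_tables", "read_result_table"]

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113
_DEFAULT_NODATA = -9999.0

_ASCII_SUFFIXES = {".asc", ".txt"}
_TIFF_SUFFIXES = {".tif", ".tiff"}


def read_grid(
    path: str | os.PathLike,
    expected_geometry: Landscape | None = None,
) -> tuple[Landscape, np.ndarray]:
    """Read a raster, returning its geometry and values (NoData as NaN).

    Raises
    ------
    ValueError
        If the file suffix is not a supported raster dialect.
    GeometryMismatchError
        If ``expected_geometry`` is given and the raster is not registered on
        it (rows/cols/cell size/origin beyond tolerance).
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in _ASCII_SUFFIXES:
        landscape, values = _read_ascii(path)
    elif suffix in _TIFF_SUFFIXES:
        landscape, values = _read_geotiff(path)
    else:
        raise ValueError(f"unsupported raster format: {path.name!r}")
    if expected_geometry is not None:
        expected_geometry.require_congruent(landscape)
    return landscape, values


def write_grid(
    path: str | os.PathLike,
    landscape: Landscape,
    values: np.ndarray,
    nodata: float = _DEFAULT_NODATA,
) -> None:
    """Write a grid in the dialect implied by the file suffix."""
    path = Path(path)
    arr = np.asarray(landscape.validate_grid(values), dtype=np.float64)
    filled = np.where(landscape.nodata_mask | np.isnan(arr), nodata, arr)
    suffix = path.suffix.lower()
    if suffix in _ASCII_SUFFIXES:
        _write_ascii(path, landscape, filled, nodata)
    elif suffix in _TIFF_SUFFIXES:
        _write_geotiff(path, landscape, filled, nodata)
    else:
        raise ValueError(f"unsupported raster format: {path.name!r}")


def _mask_values(values: np.ndarray, nodata: float) -> tuple[np.ndarray, np.ndarray]:
    mask = np.isnan(values) if np.isnan(nodata) else np.isclose(values, nodata)
    return mask, np.where(mask, np.nan, values)


def _read_ascii(path: Path) -> tuple[Landscape, np.ndarray]:
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"{path.name}: missing ESRI ASCII header field {key!r}")
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    cell = header["cellsize"]
    nodata = header.get("nodata_value", _DEFAULT_NODATA)
    values = np.loadtxt(lines[n_header:], dtype=np.float64).reshape(n_rows, n_cols)
    mask, values = _mask_values(values, nodata)
    # ESRI origin is the lower-left corner; ours is the top-left.
    origin = (header["xllcorner"], header["yllcorner"] + n_rows * cell)
    return Landscape(n_rows, n_cols, cell, origin, mask), values


def _write_ascii(path: Path, landscape: Landscape, filled: np.ndarray, nodata: float) -> None:
    x0, y_top = landscape.origin
    yll = y_top - landscape.n_rows * landscape.cell_size
    with open(path, "w") as fh:
        fh.write(f"ncols {landscape.n_cols}\n")
        fh.write(f"nrows {landscape.n_rows}\n")
        fh.write(f"xllcorner {x0:.17g}\n")
        fh.write(f"yllcorner {yll:.17g}\n")
        fh.write(f"cellsize {landscape.cell_size:.17g}\n")
        fh.write(f"NODATA_value {nodata:.17g}\n")
        np.savetxt(fh, filled, fmt="%.17g")


def _read_geotiff(path: Path) -> tuple[Landscape, np.ndarray]:
    import tifffile

    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        values = np.asarray(page.asarray(), dtype=np.float64)
        scale_tag = page.tags.get(_TAG_PIXEL_SCALE)
        tie_tag = page.tags.get(_TAG_TIEPOINT)
        nodata_tag = page.tags.get(_TAG_GDAL_NODATA)
        if scale_tag is None or tie_tag is None:
            raise ValueError(f"{path.name}: missing GeoTIFF georeferencing tags")
        scale = tuple(scale_tag.value)
        tie = tuple(tie_tag.value)
        nodata = float(nodata_tag.value) if nodata_tag is not None else _DEFAULT_NODATA
    if values.ndim != 2:
        raise ValueError(f"{path.name}: expected a single-band 2-D raster")
    sx, sy = float(scale[0]), float(scale[1])
    if abs(sx - sy) > 1e-6 * sx:
        raise ValueError(f"{path.name}: non-square cells are not supported")
    origin = (float(tie[3]), float(tie[4]))
    mask, values = _mask_values(values, nodata)
    n_rows, n_cols = values.shape
    return Landscape(n_rows, n_cols, sx, origin, mask), values


def _write_geotiff(path: Path, landscape: Landscape, filled: np.ndarray, nodata: float) -> None:
    import tifffile

    cell = float(landscape.cell_size)
    x0, y_top = landscape.origin
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (cell, cell, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, float(x0), float(y_top), 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, f"{nodata:.17g}"),
    ]
    tifffile.imwrite(path, filled, extratags=extratags)


def write_result_tables(result, out_dir: str | os.PathLike) -> dict[str, Path]:
    """Write per-replicate counters, an aggregate row, and a config echo.

    ``result`` is a :class:`~windshift.engine.RunResult`. Produces
    ``replicates.csv`` (one row per replicate plus a ``mean`` row) and
    ``config.yaml`` echoing the simulation configuration for provenance.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frame = result.to_frame()
    if frame.empty:
        raise ValueError("cannot serialize a result with no replicates")
    aggregate = frame.drop(columns=["replicate"]).mean(numeric_only=True)
    aggregate["replicate"] = "mean"
    table = pd.concat([frame, aggregate.to_frame().T], ignore_index=True)
    table = table[frame.columns]
    csv_path = out_dir / "replicates.csv"
    table.to_csv(csv_path, index=False)
    cfg_path = out_dir / "config.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(result.config_echo(), fh, sort_keys=False)
    return {"replicates": csv_path, "config": cfg_path}


def read_result_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read back a ``replicates.csv`` table."""
    return pd.read_csv(path)
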