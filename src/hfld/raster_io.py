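"""Minimal single-band raster I/O.

Rasters are exchanged as plain single-band TIFF written with :mod:`tifffile`,
north-up with square pixels. Georeferencing (pixel size in metres, origin,
nodata) travels in a JSON sidecar ``<name>.aux.json`` next to the TIFF, since
the stack carries no GDAL bindings. Loss-year bands follow the Hansen
convention: 0 = never lost, k = lost in year 2000 + k; nodata is -1.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

NODATA = -1


def write_raster(path: str | Path, array: np.ndarray, pixel_size: float,
                 nodata: float = NODATA, origin: tuple[float, float] = (0.0, 0.0)) -> Path:
    """Write a 2-D array as single-band TIFF plus a JSON georeferencing sidecar."""
    path = Path(path)
    if array.ndim != 2:
        raise ValueError(f"expected a 2-D single-band array, got shape {array.shape}")
    tifffile.imwrite(path, np.ascontiguousarray(array))
    meta = {
        "pixel_size_m": float(pixel_size),
        "origin_xy": [float(origin[0]), float(origin[1])],
        "nodata": nodata,
        "rows": int(array.shape[0]),
        "cols": int(array.shape[1]),
        "dtype": str(array.dtype),
        "convention": "north-up, row 0 = northern edge, loss band: 0=never, k=year 2000+k",
    }
    sidecar(path).write_text(json.dumps(meta, indent=2))
    return path


def read_raster(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a single-band TIFF and its sidecar metadata (empty dict if absent)."""
    path = Path(path)
    array = tifffile.imread(path)
    meta: dict = {}
    aux = sidecar(path)
    if aux.exists():
        meta = json.loads(aux.read_text())
    return array, meta


def sidecar(path: str | Path) -> Path:
    path = Path(path)
    return path.with_name(path.name + ".aux.json")


def pixel_centers(rows: int, cols: int, pixel_size: float,
                  origin: tuple[float, float] = (0.0, 0.0)):
    """World coordinates of pixel centers; y increases northwards (row 0 on top)."""
    x = origin[0] + (np.arange(cols) + 0.5) * pixel_size
    y = origin[1] + (rows - np.arange(rows) - 0.5) * pixel_size
    return np.meshgrid(x, y)
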