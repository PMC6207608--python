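"""Raster preprocessing: forest mask, majority filter, exclusions, tabulation.

Turns a tree-cover raster and a Hansen-style loss-year raster into a clean
2000 forest mask and per-territory annual deforestation series. Three
filters are applied in a fixed order: crown-cover threshold (default 75 %),
a majority filter removing isolated deforested pixels, and exclusion of
coastal swamp / mangrove polygons where land-use change is assumed natural.
Each step is idempotent. Loss is permanent (no re-growth): deforestation in
any year requires forest in 2000.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage

from .errors import AmbiguousZonesError, InvalidSpecError
from .raster_io import pixel_centers


@dataclass
class ForestMask:
    mask: np.ndarray                  # bool, True = forest in 2000
    pixel_size: float                 # metres
    threshold: float                  # percent crown cover

    @property
    def pixel_area_ha(self) -> float:
        return self.pixel_size**2 / 10_000.0

    @property
    def area_ha(self) -> float:
        return float(self.mask.sum()) * self.pixel_area_ha


def forest_mask(tree_cover: np.ndarray, threshold: float = 75.0,
                pixel_size: float = 30.0) -> ForestMask:
    """Binary forest map: pixel is forest iff crown cover >= threshold."""
    if not 0.0 <= threshold <= 100.0:
        raise InvalidSpecError(f"threshold must be in [0, 100], got {threshold}")
    return ForestMask(mask=np.asarray(tree_cover) >= threshold,
                      pixel_size=pixel_size, threshold=threshold)


def majority_filter(loss_year: np.ndarray, window: int = 3,
                    min_neighbors: int = 2, max_passes: int | None = None) -> np.ndarray:
    """Remove isolated deforested pixels (likely misclassification/blowdowns).

    A deforested pixel with fewer than ``min_neighbors`` deforested neighbors
    inside the ``window`` x ``window`` box (excluding itself) is relabelled
    never-lost; all other pixels are unchanged. Applied to the any-year loss
    composite, not per year, and iterated to a fixpoint by default (removal
    can isolate further pixels), which makes the filter idempotent;
    ``max_passes`` caps the iteration.
    """
    if window % 2 == 0 or window < 1:
        raise InvalidSpecError(f"window must be odd and positive, got {window}")
    kernel = np.ones((window, window), dtype=int)
    kernel[window // 2, window // 2] = 0
    out = loss_year.copy()
    passes = 0
    while max_passes is None or passes < max_passes:
        lost = out > 0
        neighbors = ndimage.convolve(lost.astype(int), kernel, mode="constant", cval=0)
        isolated = lost & (neighbors < min_neighbors)
        if not isolated.any():
            break
        out[isolated] = 0
        passes += 1
    return out


def rasterize_polygons(polygons, shape: tuple[int, int], pixel_size: float,
                       origin: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """Boolean mask of pixels whose centers fall inside any polygon."""
    mask = np.zeros(shape, dtype=bool)
    geoms = [shapely.geometry.shape(p) if isinstance(p, dict) else p
             for p in polygons]
    if not geoms:
        return mask
    union = shapely.union_all(geoms)
    xs, ys = pixel_centers(shape[0], shape[1], pixel_size, origin)
    inside = shapely.contains_xy(union, xs.ravel(), ys.ravel())
    return inside.reshape(shape)


def apply_exclusion(loss_year: np.ndarray, exclusion_polygons,
                    pixel_size: float = 30.0,
                    origin: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """Set loss pixels inside any exclusion polygon to never-lost."""
    mask = rasterize_polygons(exclusion_polygons, loss_year.shape, pixel_size, origin)
    return apply_exclusion_mask(loss_year, mask)


def apply_exclusion_mask(loss_year: np.ndarray, exclusion: np.ndarray) -> np.ndarray:
    """Mask-based form of the exclusion filter (identity for an empty mask)."""
    out = loss_year.copy()
    out[exclusion.astype(bool)] = 0
    return out


def tabulate_annual(loss_year: np.ndarray, fmask: ForestMask,
                    zones: np.ndarray, zone_names: dict[int, str] | None = None,
                    years=range(2001, 2015)) -> pd.DataFrame:
    """Hectares deforested per territory per year.

    ``zones`` is an integer label raster partitioning the grid (checked
    against the mask shape); loss is only counted where forest in 2000.
    Returns a tidy frame (year, territory, area_ha), additive over zone
    partitions and year ranges.
    """
    if zones.shape != loss_year.shape:
        raise AmbiguousZonesError("zone raster does not match the loss grid")
    zone_names = zone_names or {int(z): str(int(z)) for z in np.unique(zones)}
    pa = fmask.pixel_area_ha
    valid = fmask.mask
    records = []
    for year in years:
        k = year - 2000
        hit = (loss_year == k) & valid
        for z, name in zone_names.items():
            records.append({"year": int(year), "territory": name,
                            "area_ha": float((hit & (zones == z)).sum() * pa)})
    return pd.DataFrame.from_records(records)


def zones_from_polygons(polygons: dict[str, object], shape: tuple[int, int],
                        pixel_size: float,
                        origin: tuple[float, float] = (0.0, 0.0)
                        ) -> tuple[np.ndarray, dict[int, str]]:
    """Label raster from named territory polygons; overlap is an error."""
    zones = np.full(shape, -1, dtype=np.int32)
    names: dict[int, str] = {}
    for i, (name, poly) in enumerate(polygons.items()):
        m = rasterize_polygons([poly], shape, pixel_size, origin)
        if (zones[m] != -1).any():
            raise AmbiguousZonesError(f"territory {name} overlaps another zone")
        zones[m] = i
        names[i] = name
    return zones, names
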