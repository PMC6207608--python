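"""Deforestation location modelling and spatial allocation.

The location model is a random-forest classifier over static geographic
covariates (distances to roads, greenstone belts and three Strahler stream
classes, plus a protected-area indicator). Covariates are ranked by Mean
Decrease in Gini (MDG), the impurity-based importance accumulated over all
splits of the ensemble. Coupling with an intensity scenario is done by
weighted sampling without replacement from the resulting risk surface:
each projection year the scenario's annual median area, converted to a pixel
count, is drawn with probability proportional to risk and removed from the
forest pool.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.ensemble import RandomForestClassifier

from .errors import DegenerateTrainingError, SaturationError, SchemaError

#: canonical covariate order (Table-2-style geographic predictors)
COVARIATE_NAMES = (
    "protected",
    "dist_road",
    "dist_greenstone",
    "dist_stream_small",   # Strahler order 1-3
    "dist_stream_mid",     # Strahler order 4-6
    "dist_stream_large",   # Strahler order 7+
)

STRAHLER_CLASSES = {
    "dist_stream_small": (1, 3),
    "dist_stream_mid": (4, 6),
    "dist_stream_large": (7, 10**6),
}


@dataclass
class CovariateStack:
    """Co-registered covariate rasters, distances in metres."""

    layers: dict[str, np.ndarray]
    pixel_size: float
    empty_layers: frozenset[str] = frozenset()

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.layers)

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.layers.values())).shape

    def matrix(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Stack layers into an (n_pixels, p) design matrix, optionally masked."""
        cols = []
        for arr in self.layers.values():
            cols.append(arr[mask] if mask is not None else arr.ravel())
        return np.column_stack(cols).astype(np.float64)


def distance_stack(roads: np.ndarray, greenstone: np.ndarray,
                   streams: np.ndarray, protected: np.ndarray,
                   pixel_size: float) -> CovariateStack:
    """Euclidean distance transforms (metres) to each feature class.

    ``streams`` holds Strahler orders (0 = no stream); it is split into the
    small/intermediate/large classes before transforming. An empty feature
    layer yields a sentinel distance of ``pixel_size * (rows + cols)`` and is
    recorded in ``empty_layers``.
    """
    shapes = {roads.shape, greenstone.shape, streams.shape, protected.shape}
    if len(shapes) != 1:
        raise SchemaError(f"covariate layers are not co-registered: {shapes}")
    rows, cols = roads.shape
    sentinel = pixel_size * (rows + cols)
    empty: set[str] = set()

    def edt(feature: np.ndarray, name: str) -> np.ndarray:
        if not feature.any():
            empty.add(name)
            return np.full(feature.shape, sentinel, dtype=np.float64)
        return ndimage.distance_transform_edt(~feature, sampling=pixel_size)

    layers = {
        "protected": protected.astype(np.float64),
        "dist_road": edt(roads.astype(bool), "dist_road"),
        "dist_greenstone": edt(greenstone.astype(bool), "dist_greenstone"),
    }
    for name, (lo, hi) in STRAHLER_CLASSES.items():
        layers[name] = edt((streams >= lo) & (streams <= hi), name)
    return CovariateStack(layers=layers, pixel_size=pixel_size,
                          empty_layers=frozenset(empty))


@dataclass
class LocationModelConfig:
    """Random-forest hyperparameters (standard practice defaults, config-exposed)."""

    n_estimators: int = 500
    max_features: str | int = "sqrt"
    min_samples_leaf: int = 5
    background_ratio: float = 1.0  # never-lost pixels sampled per lost pixel


@dataclass
class LocationModel:
    forest: RandomForestClassifier
    covariate_names: tuple[str, ...]
    importance: pd.Series = field(repr=False)  # MDG, sorted descending

    def top_covariate(self) -> str:
        return str(self.importance.index[0])


def train_location_model(stack: CovariateStack, loss_labels: np.ndarray,
                         forest_mask: np.ndarray,
                         config: LocationModelConfig | None = None,
                         seed: int = 0) -> LocationModel:
    """Fit the risk classifier on lost vs. retained forest pixels.

    Positives are pixels with any historical loss inside the 2000 forest mask;
    the background is a seeded random sample of never-lost forest pixels at
    ``background_ratio`` : 1. Importance is the Gini impurity decrease (MDG).
    """
    config = config or LocationModelConfig()
    rng = np.random.default_rng(seed)
    lost = loss_labels.astype(bool) & forest_mask
    kept = forest_mask & ~lost
    n_pos = int(lost.sum())
    if n_pos == 0 or not kept.any():
        raise DegenerateTrainingError(
            "training labels contain a single class; need both lost and retained forest")
    kept_idx = np.flatnonzero(kept.ravel())
    n_bg = min(len(kept_idx), max(1, int(round(config.background_ratio * n_pos))))
    bg_idx = rng.choice(kept_idx, size=n_bg, replace=False)

    x_pos = stack.matrix(lost)
    x_bg = stack.matrix()[bg_idx]
    x = np.vstack([x_pos, x_bg])
    y = np.concatenate([np.ones(n_pos, dtype=int), np.zeros(n_bg, dtype=int)])

    clf = RandomForestClassifier(
        n_estimators=config.n_estimators,
        criterion="gini",
        max_features=config.max_features,
        min_samples_leaf=config.min_samples_leaf,
        random_state=int(rng.integers(2**31 - 1)),
        n_jobs=1,
    )
    clf.fit(x, y)
    importance = pd.Series(clf.feature_importances_, index=list(stack.names),
                           name="mdg").sort_values(ascending=False)
    return LocationModel(forest=clf, covariate_names=stack.names, importance=importance)


def predict_risk(model: LocationModel, stack: CovariateStack,
                 forest_mask: np.ndarray) -> np.ndarray:
    """Per-pixel deforestation probability over the forest mask, 0 elsewhere."""
    if stack.names != model.covariate_names:
        raise SchemaError(
            f"covariate names {stack.names} do not match the trained model "
            f"{model.covariate_names}")
    risk = np.zeros(stack.shape, dtype=np.float64)
    if not forest_mask.any():
        return risk
    x = stack.matrix(forest_mask)
    proba = model.forest.predict_proba(x)
    cls = list(model.forest.classes_)
    risk[forest_mask] = proba[:, cls.index(1)]
    return risk


def pixels_for_area(area_ha: float, pixel_area_ha: float) -> int:
    """Demanded pixel count: area rounded to the nearest whole pixel."""
    return int(round(area_ha / pixel_area_ha))


def allocate(risk: np.ndarray, annual_area_ha: float, pixel_area_ha: float,
             seed: int | np.random.Generator, pool_mask: np.ndarray | None = None
             ) -> tuple[np.ndarray, np.ndarray]:
    """Draw newly deforested pixels, probability proportional to risk.

    Exactly ``round(annual_area_ha / pixel_area_ha)`` pixels are sampled
    without replacement from ``pool_mask`` (default: positive-risk pixels)
    via Gumbel-key weighting, which is reproducible under a seed. Returns
    (rows, cols) index arrays of the drawn pixels.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if pool_mask is None:
        pool_mask = risk > 0
    n = pixels_for_area(annual_area_ha, pixel_area_ha)
    if n == 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    pool_idx = np.flatnonzero(pool_mask.ravel())
    if n > len(pool_idx):
        raise SaturationError(
            f"demand of {n} pixels exceeds pool of {len(pool_idx)} forest pixels")
    w = risk.ravel()[pool_idx].astype(np.float64)
    # tiny floor keeps zero-risk pixels reachable at exhaustion without
    # measurably perturbing the weighted draw
    w = w + max(w.max(), 1.0) * 1e-12
    keys = np.log(w) + rng.gumbel(size=len(w))
    take = np.argpartition(-keys, n - 1)[:n]
    flat = pool_idx[take]
    return np.unravel_index(flat, risk.shape)


def annual_increments(cumulative: np.ndarray) -> np.ndarray:
    """Per-year areas from a cumulative trajectory (first year from zero)."""
    return np.diff(np.asarray(cumulative, dtype=float), prepend=0.0)


def project_maps(annual_areas: dict[str, np.ndarray],
                 risk_maps: dict[str, np.ndarray],
                 forest_mask: np.ndarray, pixel_area_ha: float,
                 seed: int, years: np.ndarray | None = None,
                 allowed_mask: np.ndarray | None = None) -> np.ndarray:
    """Allocate a scenario's annual demands into a year-of-loss map.

    ``annual_areas`` maps component names to per-year hectare vectors and
    ``risk_maps`` maps the same names to risk surfaces: plain scenarios use a
    single component, gold-mining scenarios split demand into a gold component
    allocated on the gold-mining risk map (GMM) and a demographic component
    allocated on the no-gold-mining map (NGMM). The output uint16 raster
    records the first loss year per pixel (calendar year; 0 = never).
    Demand beyond the remaining pool is capped with a warning.
    """
    if set(annual_areas) != set(risk_maps):
        raise SchemaError(f"components {set(annual_areas)} != risk maps {set(risk_maps)}")
    horizons = {len(v) for v in annual_areas.values()}
    if len(horizons) != 1:
        raise SchemaError("component demand vectors have differing horizons")
    horizon = horizons.pop()
    if years is None:
        years = 2016 + np.arange(horizon)
    rng = np.random.default_rng(seed)
    proj = np.zeros(forest_mask.shape, dtype=np.uint16)
    pool = forest_mask.copy()
    if allowed_mask is not None:
        pool &= allowed_mask
    for t in range(horizon):
        for comp in sorted(annual_areas):
            demand = float(annual_areas[comp][t])
            n = pixels_for_area(demand, pixel_area_ha)
            avail = int(pool.sum())
            if n > avail:
                warnings.warn(
                    f"year {years[t]} component {comp}: demand {n} px capped to "
                    f"remaining pool {avail} px", stacklevel=2)
                n = avail
            if n == 0:
                continue
            r, c = allocate(risk_maps[comp], n * pixel_area_ha, pixel_area_ha,
                            rng, pool_mask=pool)
            proj[r, c] = years[t]
            pool[r, c] = False
    return proj


def hotspot_share(projection: np.ndarray, forest_mask: np.ndarray,
                  cell: int = 10, threshold: float = 0.30) -> np.ndarray:
    """Per reporting cell: is more than ``threshold`` of initial forest lost?

    Aggregates the year-of-loss map over ``cell`` x ``cell`` pixel blocks and
    flags blocks whose share of deforested initial-forest pixels exceeds the
    threshold (the >30 % convention used for hotspot maps).
    """
    lost = (projection > 0) & forest_mask
    rows, cols = forest_mask.shape
    nr, nc = -(-rows // cell), -(-cols // cell)
    flags = np.zeros((nr, nc), dtype=bool)
    for i in range(nr):
        for j in range(nc):
            sl = np.s_[i * cell:(i + 1) * cell, j * cell:(j + 1) * cell]
            f = forest_mask[sl].sum()
            if f:
                flags[i, j] = lost[sl].sum() / f > threshold
    return flags
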