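"""Synthetic landscapes, deforestation histories and socio-economic series.

Generates every input the downstream pipeline expects from real data —
a tree-cover raster, an annual loss-year raster, geographic feature layers
(roads, greenstone belts, Strahler-ordered streams, protected areas, coastal
swamps) and gold-price / population / GDP series — with the statistical
structure the models assume, so the whole pipeline is testable without any
download. Every generator is a pure function of (spec, seed).

Design notes: the stream network is a random spanning-tree drainage with
Strahler orders computed bottom-up, which yields the three distance classes
(orders 1-3, 4-6, 7+) without hydrological modelling. Historical loss pixels
are placed by weighted sampling without replacement from a planted logistic
risk surface, so the location model family downstream can recover the
planted covariate weights. Pixel area is (pixel size)^2 / 10000 ha
(0.09 ha at 30 m).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line

from .allocation import CovariateStack, distance_stack
from .errors import InfeasibleHistoryError, InvalidSpecError

CALIBRATION_YEARS = tuple(range(2001, 2015))

#: deterministic default annual gold price 2001-2014, USD/ounce. The peak is
#: 1538.5 so that the high-price hypothesis (double the maximum) is 3077.
DEFAULT_GOLD_PRICE = {
    2001: 271.0, 2002: 310.0, 2003: 363.0, 2004: 410.0, 2005: 445.0,
    2006: 604.0, 2007: 696.0, 2008: 872.0, 2009: 972.0, 2010: 1225.0,
    2011: 1435.0, 2012: 1538.5, 2013: 1411.0, 2014: 1266.0,
}


@dataclass(frozen=True)
class LandscapeSpec:
    """Geometry and feature density of a synthetic landscape."""

    rows: int
    cols: int
    pixel_size: float = 30.0          # metres
    seed: int = 0
    n_roads: int = 4
    n_greenstone: int = 3
    stream_spacing: int = 6           # drainage-lattice node spacing, pixels
    protected_fraction: float = 0.15
    swamp_fraction: float = 0.05

    def __post_init__(self):
        if self.rows <= 0 or self.cols <= 0:
            raise InvalidSpecError("grid dimensions must be positive")
        if self.pixel_size <= 0:
            raise InvalidSpecError("pixel size must be positive")
        for name in ("protected_fraction", "swamp_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidSpecError(f"{name} must be in [0, 1], got {v}")
        if self.stream_spacing < 2:
            raise InvalidSpecError("stream_spacing must be >= 2 pixels")

    @property
    def pixel_area_ha(self) -> float:
        return self.pixel_size**2 / 10_000.0


@dataclass
class Landscape:
    """Co-registered synthetic layers sharing grid, extent and pixel size."""

    spec: LandscapeSpec
    tree_cover: np.ndarray            # percent, [0, 100]
    roads: np.ndarray                 # bool
    greenstone: np.ndarray            # bool
    streams: np.ndarray               # int16 Strahler order, 0 = no stream
    protected: np.ndarray             # bool
    swamp: np.ndarray                 # bool

    @property
    def pixel_area_ha(self) -> float:
        return self.spec.pixel_area_ha

    def covariates(self) -> CovariateStack:
        """Distance-transform covariate stack for the location models."""
        return distance_stack(self.roads, self.greenstone, self.streams,
                              self.protected, self.spec.pixel_size)


def _smooth_field(rng: np.random.Generator, rows: int, cols: int,
                  scale: int = 12) -> np.ndarray:
    """Smooth unit-variance noise by zooming a coarse Gaussian grid."""
    cr, cc = max(2, rows // scale + 2), max(2, cols // scale + 2)
    coarse = rng.normal(size=(cr, cc))
    z = ndimage.zoom(coarse, (rows / cr, cols / cc), order=1, mode="nearest")
    z = z[:rows, :cols]
    pad = [(0, rows - z.shape[0]), (0, cols - z.shape[1])]
    return np.pad(z, pad, mode="edge")


def _blob_mask(rng: np.random.Generator, rows: int, cols: int, fraction: float,
               r_lo: float = 0.04, r_hi: float = 0.10,
               row_range: tuple[float, float] = (0.0, 1.0)) -> np.ndarray:
    """Union of random disks grown until the target area fraction is reached."""
    mask = np.zeros((rows, cols), dtype=bool)
    if fraction <= 0:
        return mask
    target = fraction * rows * cols
    base = min(rows, cols)
    # cap disk size so overshoot stays well inside a few percent of the grid
    while mask.sum() < target:
        r0 = rng.uniform(row_range[0] * rows, row_range[1] * rows)
        c0 = rng.uniform(0, cols)
        radius = rng.uniform(r_lo, r_hi) * base
        rr, cc = draw_disk((r0, c0), radius, shape=(rows, cols))
        mask[rr, cc] = True
    return mask


def _random_spanning_tree(rng: np.random.Generator, nr: int, nc: int
                          ) -> dict[tuple[int, int], tuple[int, int]]:
    """Randomized-Prim spanning tree on an nr x nc lattice; child -> parent."""
    root = (nr - 1, int(rng.integers(nc)))  # outlet on the southern edge
    in_tree = {root}
    parent: dict[tuple[int, int], tuple[int, int]] = {}
    frontier = []

    def push(node):
        r, c = node
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            nb = (r + dr, c + dc)
            if 0 <= nb[0] < nr and 0 <= nb[1] < nc and nb not in in_tree:
                frontier.append((node, nb))

    push(root)
    while frontier:
        i = int(rng.integers(len(frontier)))
        frontier[i], frontier[-1] = frontier[-1], frontier[i]
        src, dst = frontier.pop()
        if dst in in_tree:
            continue
        parent[dst] = src
        in_tree.add(dst)
        push(dst)
    return parent


def _strahler_orders(parent: dict) -> dict:
    """Bottom-up Strahler order: leaves are 1; equal maxima merge to max+1."""
    children: dict = {}
    for child, par in parent.items():
        children.setdefault(par, []).append(child)
    order: dict = {}

    def visit(node):
        stack = [(node, False)]
        while stack:
            n, done = stack.pop()
            kids = children.get(n, [])
            if not kids:
                order[n] = 1
                continue
            if not done:
                stack.append((n, True))
                stack.extend((k, False) for k in kids)
            else:
                vals = [order[k] for k in kids]
                top = max(vals)
                order[n] = top + 1 if vals.count(top) >= 2 else top
    roots = set(parent.values()) - set(parent)
    for r in roots:
        visit(r)
    return order


def generate_landscape(spec: LandscapeSpec) -> Landscape:
    """Build all co-registered layers from a spec; deterministic under seed."""
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.rows, spec.cols

    cover = np.clip(88.0 + 7.0 * _smooth_field(rng, rows, cols), 0.0, 100.0)

    roads = np.zeros((rows, cols), dtype=bool)
    for _ in range(spec.n_roads):
        # polyline crossing the grid with one interior bend
        r0, c0 = int(rng.integers(rows)), 0
        r2, c2 = int(rng.integers(rows)), cols - 1
        r1, c1 = int(rng.integers(rows)), int(rng.integers(cols // 4, 3 * cols // 4 + 1))
        for (ra, ca), (rb, cb) in (((r0, c0), (r1, c1)), ((r1, c1), (r2, c2))):
            rr, cc = draw_line(ra, ca, rb, cb)
            roads[rr, cc] = True

    greenstone = np.zeros((rows, cols), dtype=bool)
    # belts traverse the region: one blob per vertical band so no large
    # sub-territory is systematically void of gold-bearing formations
    for i in range(spec.n_greenstone):
        band = cols / max(1, spec.n_greenstone)
        r0 = rng.uniform(0, rows)
        c0 = rng.uniform(i * band, (i + 1) * band)
        rr, cc = draw_disk((r0, c0), rng.uniform(0.05, 0.12) * min(rows, cols),
                           shape=(rows, cols))
        greenstone[rr, cc] = True

    streams = np.zeros((rows, cols), dtype=np.int16)
    s = spec.stream_spacing
    nr, nc = max(2, rows // s), max(2, cols // s)
    parent = _random_spanning_tree(rng, nr, nc)
    order = _strahler_orders(parent)
    for child, par in parent.items():
        seg_order = order[child]
        rr, cc = draw_line(child[0] * s, child[1] * s, par[0] * s, par[1] * s)
        keep = (rr < rows) & (cc < cols)
        rr, cc = rr[keep], cc[keep]
        streams[rr, cc] = np.maximum(streams[rr, cc], seg_order)

    protected = _blob_mask(rng, rows, cols, spec.protected_fraction)
    swamp = _blob_mask(rng, rows, cols, spec.swamp_fraction,
                       r_lo=0.03, r_hi=0.07, row_range=(0.0, 0.2))

    return Landscape(spec=spec, tree_cover=cover, roads=roads,
                     greenstone=greenstone, streams=streams,
                     protected=protected, swamp=swamp)


# --------------------------------------------------------------------------
# historical deforestation


@dataclass(frozen=True)
class HistorySpec:
    """Planted structure of the 2001-2014 loss history.

    ``weights`` are log-odds coefficients on z-scored covariates for the
    non-gold location process; ``gold_weights`` for the gold-mining process
    (concentrated near greenstone and small streams). ``gold_share`` is the
    fraction of each year's loss allocated by the gold process.
    """

    annual_ha: tuple[float, ...] = tuple(30.0 for _ in CALIBRATION_YEARS)
    gold_share: float = 0.0
    annual_gold_ha: tuple[float, ...] | None = None  # overrides gold_share
    weights: dict[str, float] = field(
        default_factory=lambda: {"dist_road": -2.0})
    gold_weights: dict[str, float] = field(
        default_factory=lambda: {"dist_greenstone": -2.5, "dist_stream_small": -1.0})
    noise_sigma: float = 0.5          # log-odds pixel noise
    patch_px: int = 1                 # mean patch size; 1 = independent pixels
    min_patch_px: int = 1             # smallest clearing, pixels
    start_year: int = 2001
    cover_threshold: float = 75.0

    def __post_init__(self):
        if any(a < 0 for a in self.annual_ha):
            raise InvalidSpecError("annual intensities must be >= 0")
        if not 0.0 <= self.gold_share <= 1.0:
            raise InvalidSpecError("gold share must be in [0, 1]")
        if self.annual_gold_ha is not None and len(self.annual_gold_ha) != len(self.annual_ha):
            raise InvalidSpecError("annual_gold_ha must match annual_ha length")
        if self.patch_px < 1 or self.min_patch_px < 1:
            raise InvalidSpecError("patch sizes must be >= 1")
        if self.min_patch_px > 1 and self.patch_px < self.min_patch_px:
            raise InvalidSpecError("patch_px must be >= min_patch_px")

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(self.start_year + i for i in range(len(self.annual_ha)))


@dataclass
class History:
    loss_year: np.ndarray             # int16, 0 = never, k = year 2000+k
    gold: np.ndarray                  # bool, generator truth of gold-driven loss
    series: pd.DataFrame              # year, territory, area_ha, gold_ha


def _planted_logit(stack: CovariateStack, weights: dict[str, float],
                   mask: np.ndarray, rng: np.random.Generator,
                   noise_sigma: float) -> np.ndarray:
    logit = np.zeros(mask.shape, dtype=np.float64)
    for name, w in weights.items():
        layer = stack.layers[name]
        vals = layer[mask]
        sd = vals.std()
        z = (layer - vals.mean()) / (sd if sd > 0 else 1.0)
        logit += w * z
    if noise_sigma > 0:
        logit += rng.normal(0.0, noise_sigma, size=mask.shape)
    return logit


def _weighted_take(rng: np.random.Generator, logit: np.ndarray,
                   pool: np.ndarray, n: int) -> np.ndarray:
    """Gumbel-key top-n flat indices from pool, weight = exp(logit)."""
    idx = np.flatnonzero(pool.ravel())
    keys = logit.ravel()[idx] + rng.gumbel(size=len(idx))
    take = np.argpartition(-keys, n - 1)[:n] if n < len(idx) else np.arange(len(idx))
    return idx[take[:n]]


def _flat_neighbors(flat: int, shape: tuple[int, int]) -> list[int]:
    rows, cols = shape
    r, c = divmod(flat, cols)
    out = []
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == dc == 0:
                continue
            rr, cc = r + dr, c + dc
            if 0 <= rr < rows and 0 <= cc < cols:
                out.append(rr * cols + cc)
    return out


def _place_component(rng: np.random.Generator, logit: np.ndarray,
                     pool: np.ndarray, n: int, patch_px: int,
                     min_patch_px: int = 1) -> np.ndarray:
    """Place n pixels as weighted patches; returns flat indices.

    With ``patch_px`` = 1 this is plain weighted sampling without
    replacement. Larger values grow connected clumps (geometric patch
    sizes, mean ``patch_px``) seeded by the same weighted draw, emulating
    the patchy footprint of real clearings so that isolated-pixel filters
    do not erase the sparse synthetic histories.
    """
    if patch_px <= 1:
        flat = _weighted_take(rng, logit, pool, n)
        pool.ravel()[flat] = False
        return flat
    logit_flat = logit.ravel()
    pool_flat = pool.ravel()  # view: mutates pool in place
    placed: list[int] = []
    while len(placed) < n:
        size = min(n - len(placed),
                   max(min_patch_px, int(rng.geometric(1.0 / patch_px))))
        seed_px = int(_weighted_take(rng, logit, pool, 1)[0])
        patch = [seed_px]
        pool_flat[seed_px] = False
        frontier = [nb for nb in _flat_neighbors(seed_px, pool.shape) if pool_flat[nb]]
        while len(patch) < size and frontier:
            keys = logit_flat[frontier] + rng.gumbel(size=len(frontier))
            nxt = frontier[int(np.argmax(keys))]
            if not pool_flat[nxt]:
                frontier.remove(nxt)
                continue
            patch.append(nxt)
            pool_flat[nxt] = False
            frontier = [f for f in frontier if f != nxt]
            frontier.extend(nb for nb in _flat_neighbors(nxt, pool.shape)
                            if pool_flat[nb] and nb not in frontier)
        placed.extend(patch)
    return np.asarray(placed, dtype=np.int64)


def generate_history(landscape: Landscape, hist: HistorySpec, seed: int,
                     zones: np.ndarray | None = None,
                     zone_names: dict[int, str] | None = None,
                     pool_mask: np.ndarray | None = None) -> History:
    """Simulate the annual loss raster 2001-2014 on a landscape.

    Each year's requested intensity is converted to a pixel count and placed
    by weighted sampling without replacement: a gold fraction (``gold_share``
    or per-year ``annual_gold_ha``) from the gold risk surface (near
    greenstone / small streams), the remainder from the base surface.
    Pixels are lost in exactly one year or never, and only where 2000 tree
    cover meets the threshold (optionally restricted to ``pool_mask``).
    """
    rng = np.random.default_rng(seed)
    stack = landscape.covariates()
    forest = landscape.tree_cover >= hist.cover_threshold
    if pool_mask is not None:
        forest = forest & pool_mask
    base_logit = _planted_logit(stack, hist.weights, forest, rng, hist.noise_sigma)
    gold_logit = _planted_logit(stack, hist.gold_weights, forest, rng, hist.noise_sigma)

    pa = landscape.pixel_area_ha
    loss_year = np.zeros(forest.shape, dtype=np.int16)
    gold_mask = np.zeros(forest.shape, dtype=bool)
    pool = forest.copy()
    gold_areas = hist.annual_gold_ha
    for i, (year, area) in enumerate(zip(hist.years, hist.annual_ha)):
        n = int(round(area / pa))
        if n == 0:
            continue
        if n > pool.sum():
            raise InfeasibleHistoryError(
                f"year {year}: requested {area} ha exceeds remaining forest "
                f"({pool.sum() * pa:.1f} ha)")
        if gold_areas is not None:
            n_gold = min(n, int(round(gold_areas[i] / pa)))
        else:
            n_gold = int(round(n * hist.gold_share))
        if n_gold:
            flat = _place_component(rng, gold_logit, pool, n_gold,
                                    hist.patch_px, hist.min_patch_px)
            loss_year.ravel()[flat] = year - 2000
            gold_mask.ravel()[flat] = True
        n_base = n - n_gold
        if n_base:
            flat = _place_component(rng, base_logit, pool, n_base,
                                    hist.patch_px, hist.min_patch_px)
            loss_year.ravel()[flat] = year - 2000

    if zones is None:
        zones = np.zeros(forest.shape, dtype=np.int32)
        zone_names = {0: "all"}
    zone_names = zone_names or {z: str(z) for z in np.unique(zones)}
    records = []
    for year in hist.years:
        k = year - 2000
        hit = loss_year == k
        for z, name in zone_names.items():
            inz = hit & (zones == z)
            records.append({
                "year": year, "territory": name,
                "area_ha": float(inz.sum() * pa),
                "gold_ha": float((inz & gold_mask).sum() * pa),
            })
    return History(loss_year=loss_year, gold=gold_mask,
                   series=pd.DataFrame.from_records(records))


# --------------------------------------------------------------------------
# socio-economic series


@dataclass
class SeriesBundle:
    """Tidy socio-economic series: gold price, population and GDP per year."""

    gold_price: pd.Series             # USD/ounce, index = year
    population: pd.DataFrame          # year, territory, value (persons)
    gdp: pd.DataFrame                 # year, territory, value (USD)

    def __post_init__(self):
        if (self.gold_price <= 0).any():
            raise InvalidSpecError("gold price must be strictly positive")
        for df, label in ((self.population, "population"), (self.gdp, "GDP")):
            if (df["value"] <= 0).any():
                raise InvalidSpecError(f"{label} series must be strictly positive")
        years = np.sort(self.gold_price.index.values)
        if len(years) > 1 and np.any(np.diff(years) != 1):
            raise InvalidSpecError("years must be contiguous")

    def to_tidy(self) -> pd.DataFrame:
        gp = pd.DataFrame({"year": self.gold_price.index,
                           "territory": "region", "variable": "gold_price",
                           "value": self.gold_price.values})
        pop = self.population.assign(variable="population")
        gdp = self.gdp.assign(variable="gdp")
        return pd.concat([gp, pop, gdp], ignore_index=True)[
            ["year", "territory", "variable", "value"]]


def default_gold_price(years=CALIBRATION_YEARS) -> pd.Series:
    price = pd.Series({y: DEFAULT_GOLD_PRICE[y] for y in years if y in DEFAULT_GOLD_PRICE})
    missing = [y for y in years if y not in DEFAULT_GOLD_PRICE]
    for y in missing:  # extrapolate flat at the last known price
        price[y] = price[max(DEFAULT_GOLD_PRICE)]
    return price.sort_index()


def generate_series(territories: dict[str, dict], years, gm_params, seed: int,
                    gold_price: pd.Series | None = None
                    ) -> tuple[SeriesBundle, pd.DataFrame]:
    """Socio-economic series plus deforestation drawn from the GM model.

    ``territories`` maps names to dicts with keys ``pop0`` (initial
    population), ``pop_growth`` (persons/yr, > 0) and ``gdp0`` (USD). The
    returned deforestation frame has per-territory gold and demographic
    components, each a log-normal draw whose log-median is the model's
    linear function of log gold price / log population change — suitable
    for parameter-recovery tests.
    """
    years = list(years)
    rng = np.random.default_rng(seed)
    if gold_price is None:
        gold_price = default_gold_price(years)
    gold_price = gold_price.loc[years]
    if (gold_price <= 0).any():
        raise InvalidSpecError("gold price must be > 0")

    pop_rows, gdp_rows, def_rows = [], [], []
    for terr, cfg in territories.items():
        pop0 = float(cfg["pop0"])
        growth = float(cfg.get("pop_growth", 0.02 * pop0))
        gdp0 = float(cfg["gdp0"])
        popch = growth
        mu_dem = gm_params.theta0_dem + gm_params.theta1_dem * np.log(popch)
        for i, y in enumerate(years):
            pop_rows.append({"year": y, "territory": terr, "value": pop0 + growth * i})
            gdp_rows.append({"year": y, "territory": terr,
                             "value": gdp0 * 1.03**i})
            mu_gm = (gm_params.theta0_gm[terr]
                     + gm_params.theta_v[terr] * np.log(gold_price[y]))
            gold = float(rng.lognormal(mu_gm, gm_params.sigma_gm))
            dem = float(rng.lognormal(mu_dem, gm_params.sigma_dem))
            def_rows.append({"year": y, "territory": terr, "gold_ha": gold,
                             "dem_ha": dem, "area_ha": gold + dem})
    bundle = SeriesBundle(gold_price=gold_price,
                          population=pd.DataFrame(pop_rows),
                          gdp=pd.DataFrame(gdp_rows))
    return bundle, pd.DataFrame(def_rows)
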