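"""Reference-level (baseline) scenario models with log-normal uncertainty.

Seven models of cumulative deforestation 2015-2050 per territory:

* **HA** — historical average: past mean annual deforestation continues.
* **ERB** — economically rational baseline: all available forest (outside
  integrally protected and indigenous areas) deforested by 2050.
* **JRC2050 / JRC2100** — territory tracks half the world deforestation rate,
  linearly decreasing to zero at the stated year.
* **CI-BAU / CI-FPS / CI-NPS** — Combined-Incentives fixed annual rates
  (0.275 / 0.056 / 0.1 %/yr) applied to remaining forest cover.
* **GM-low / GM-high** — socio-economic gold-mining model: annual
  deforestation is the sum of a gold-mining component driven by the gold
  price and a demographic component driven by population change, each
  log-normal.

All models carry a multiplicative (log-normal) error term. ``logN(m; sigma)``
denotes a log-normal whose *log-median* is ``m`` (natural log) with log-scale
standard deviation ``sigma``. The dispersion estimated when calibrating the
historical-average model is injected unchanged into all normative models.

Time indexing: 35 annual increments starting in 2015; cumulative totals are
labelled with the year they complete, 2016..2050, so the terminal entry is
the 2050 total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (CalibrationError, DegenerateSeriesError, InvalidSpecError,
                     SchemaError)

HORIZON = 35                      # annual deforestation steps 2015..2049/50
START_YEAR = 2015                 # first projection year
CALIBRATION_YEARS = np.arange(2001, 2015)


def projection_years(horizon: int = HORIZON) -> np.ndarray:
    """Calendar labels of cumulative totals (year each increment completes)."""
    return START_YEAR + 1 + np.arange(horizon)


# --------------------------------------------------------------------------
# trajectories


@dataclass
class LogNormalTrajectory:
    """Cumulative deforestation as per-year log-normal: log-median mu_t, sigma."""

    mu: np.ndarray                # log cumulative hectares, per year
    sigma: float
    years: np.ndarray = field(default=None)  # type: ignore[assignment]
    scenario: str = ""
    territory: str = ""

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        if self.years is None:
            self.years = projection_years(len(self.mu))
        self.years = np.asarray(self.years)
        if self.sigma < 0:
            raise InvalidSpecError(f"sigma must be >= 0, got {self.sigma}")
        finite = self.mu[np.isfinite(self.mu)]
        if np.any(np.diff(finite) < -1e-9):
            raise InvalidSpecError("cumulative log-medians must be non-decreasing")

    @property
    def median(self) -> np.ndarray:
        return np.exp(self.mu)

    @property
    def mean(self) -> np.ndarray:
        return np.exp(self.mu + self.sigma**2 / 2.0)

    def envelope(self, z: float = 1.96) -> pd.DataFrame:
        """Mean and 95 % bounds per year: mean=exp(mu+s^2/2), exp(mu +/- z s)."""
        return pd.DataFrame({
            "year": self.years,
            "median": self.median,
            "mean": self.mean,
            "lo95": np.exp(self.mu - z * self.sigma),
            "hi95": np.exp(self.mu + z * self.sigma),
            "scenario": self.scenario,
            "territory": self.territory,
        })


@dataclass
class MonteCarloTrajectory:
    """Cumulative trajectory summarized from Monte-Carlo draws (GM models)."""

    median: np.ndarray            # analytic central path (sum of medians)
    mean: np.ndarray
    lo95: np.ndarray
    hi95: np.ndarray
    years: np.ndarray
    scenario: str = ""
    territory: str = ""

    def envelope(self) -> pd.DataFrame:
        return pd.DataFrame({
            "year": self.years, "median": self.median, "mean": self.mean,
            "lo95": self.lo95, "hi95": self.hi95,
            "scenario": self.scenario, "territory": self.territory,
        })


def envelope(trajectory) -> pd.DataFrame:
    """Per-year (mean, lower95, upper95) summary of any trajectory."""
    return trajectory.envelope()


# --------------------------------------------------------------------------
# parameters


@dataclass
class HAParams:
    def_log: float                # log of mean annual deforestation (log ha)
    sigma: float                  # log-scale SD of annual deforestation

    def __post_init__(self):
        if self.sigma < 0:
            raise InvalidSpecError("sigma must be >= 0")


@dataclass
class ERBParams:
    available_ha: float           # forest outside protected/indigenous areas
    horizon: int = HORIZON


@dataclass
class JRCParams:
    """Half-world-rate model; rates carried in percent units.

    Defaults are the printed constants: initial world rate 0.52 %/yr and
    linear-decrease coefficient 0.0029 percentage points/yr. Note half of
    0.52 %/yr falling by 0.0029 points/yr from 2015 hits zero near 2104, not
    2050; :meth:`from_zero_year` instead derives alpha from the target year,
    with the printed value recovered for a 2100 target.
    """

    fc0: float                    # initial forest cover, ha
    wdr0: float = 0.52            # %/yr
    alpha: float = 0.0029         # percentage points/yr
    zero_year: int | None = None  # rate hard-floored at 0 after this year

    def __post_init__(self):
        if self.wdr0 < 0 or self.alpha < 0:
            raise InvalidSpecError("WDR_0 and alpha must be non-negative")

    @classmethod
    def from_zero_year(cls, fc0: float, zero_year: int, wdr0: float = 0.52
                       ) -> "JRCParams":
        alpha = (wdr0 / 2.0) / (zero_year - 2011)
        return cls(fc0=fc0, wdr0=wdr0, alpha=alpha, zero_year=zero_year)


#: Combined-Incentives annual deforestation rates, %/yr
CI_RATES = {"BAU": 0.275, "NPS": 0.1, "FPS": 0.056}


@dataclass
class CIParams:
    fc0: float
    rates: dict[str, float] = field(default_factory=lambda: dict(CI_RATES))

    def __post_init__(self):
        if not self.rates["FPS"] <= self.rates["NPS"] <= self.rates["BAU"]:
            raise InvalidSpecError("CI rates must satisfy FPS <= NPS <= BAU")


@dataclass
class GMParams:
    """Gold-mining + demographic model coefficients.

    Per-territory: intercept theta0_gm and gold-price elasticity theta_v of
    the log gold-mining deforestation. Pooled: intercept/slope of log
    non-gold deforestation on log mean annual population change (PopCh).
    """

    theta0_gm: dict[str, float]
    theta_v: dict[str, float]
    sigma_gm: float
    theta0_dem: float
    theta1_dem: float
    sigma_dem: float
    popch: dict[str, float]       # mean annual population change, persons/yr

    def __post_init__(self):
        if self.sigma_gm < 0 or self.sigma_dem < 0:
            raise InvalidSpecError("sigmas must be >= 0")
        if any(v <= 0 for v in self.popch.values()):
            raise InvalidSpecError("PopCh must be > 0")


# --------------------------------------------------------------------------
# calibration


def calibrate_ha(annual_ha: np.ndarray) -> HAParams:
    """Historical-average parameters from an observed annual series.

    ``Def^HA`` is the log of the arithmetic mean annual deforestation;
    ``sigma`` is the sample SD (ddof=1) of the log of the positive annual
    values around their mean log. This sigma is the dispersion injected into
    every normative trajectory.
    """
    x = np.asarray(annual_ha, dtype=float)
    pos = x[x > 0]
    if len(pos) < 2:
        raise DegenerateSeriesError(
            "need >= 2 years with positive deforestation to calibrate on the log scale")
    logs = np.log(pos)
    return HAParams(def_log=float(np.log(x.mean())),
                    sigma=float(logs.std(ddof=1)))


def calibrate_gm(gold_def: pd.DataFrame, nongold_def: pd.DataFrame,
                 gold_price: pd.Series, population: pd.DataFrame) -> GMParams:
    """Fit the socio-economic model on 2001-2014 style calibration data.

    Per territory, OLS of log(gold-mining deforestation) on log(gold price)
    gives the intercept and price elasticity; sigma_gm is the pooled residual
    SD. A pooled cross-territory OLS of log(non-gold deforestation) on
    log(PopCh_c) gives the demographic coefficients, where PopCh_c is the
    territory's mean annual population change.

    ``gold_def``/``nongold_def``: tidy frames with columns year, territory,
    area_ha. ``population``: columns year, territory, value (persons).
    """
    if float(np.ptp(np.log(gold_price.values.astype(float)))) < 1e-12:
        raise CalibrationError("gold price is constant; elasticity is unidentified")

    theta0, theta_v = {}, {}
    resid_gm: list[np.ndarray] = []
    for terr, grp in gold_def.groupby("territory"):
        grp = grp.loc[grp["area_ha"] > 0].sort_values("year")
        if len(grp) < 5:
            raise CalibrationError(f"territory {terr}: need >= 5 calibration years")
        y = np.log(grp["area_ha"].values.astype(float))
        xp = np.log(gold_price.loc[grp["year"].values].values.astype(float))
        design = np.column_stack([np.ones_like(xp), xp])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        theta0[terr], theta_v[terr] = float(coef[0]), float(coef[1])
        resid_gm.append(y - design @ coef)
    res = np.concatenate(resid_gm)
    dof = max(1, len(res) - 2 * len(theta0))
    sigma_gm = float(np.sqrt((res**2).sum() / dof))

    popch = mean_annual_population_change(population)
    rows_y, rows_x = [], []
    for terr, grp in nongold_def.groupby("territory"):
        if popch.get(terr, 0.0) <= 0:
            raise CalibrationError(f"territory {terr}: PopCh must be > 0")
        grp = grp.loc[grp["area_ha"] > 0]
        rows_y.append(np.log(grp["area_ha"].values.astype(float)))
        rows_x.append(np.full(len(grp), np.log(popch[terr])))
    y = np.concatenate(rows_y)
    xp = np.concatenate(rows_x)
    if len(y) == 0:
        raise CalibrationError(
            "no positive non-gold deforestation years; cannot fit the "
            "demographic component (check the gold-attribution radius)")
    if len(y) < 2 or np.var(xp) == 0.0:
        # single territory (or identical growth): elasticity unidentified,
        # fall back to an intercept-only demographic component
        theta0_dem, theta1_dem = float(y.mean()), 0.0
        sigma_dem = float(y.std(ddof=1)) if len(y) > 1 else 0.0
    else:
        design = np.column_stack([np.ones_like(xp), xp])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        theta0_dem, theta1_dem = float(coef[0]), float(coef[1])
        r = y - design @ coef
        sigma_dem = float(np.sqrt((r**2).sum() / max(1, len(r) - 2)))
    return GMParams(theta0_gm=theta0, theta_v=theta_v, sigma_gm=sigma_gm,
                    theta0_dem=theta0_dem, theta1_dem=theta1_dem,
                    sigma_dem=sigma_dem, popch=popch)


def mean_annual_population_change(population: pd.DataFrame) -> dict[str, float]:
    """PopCh_c: mean year-on-year population change per territory (persons/yr)."""
    out = {}
    for terr, grp in population.groupby("territory"):
        v = grp.sort_values("year")["value"].values.astype(float)
        if len(v) < 2:
            raise CalibrationError(f"territory {terr}: need >= 2 population years")
        out[terr] = float(np.diff(v).mean())
    return out


def gm_low_price(price_2001_2014: pd.Series) -> float:
    """Low-price hypothesis: mean annual gold price over the calibration window."""
    return float(np.mean(price_2001_2014.values))


def gm_high_price(price_2001_2014: pd.Series) -> float:
    """High-price hypothesis: double the maximum annual price over the window."""
    return 2.0 * float(np.max(price_2001_2014.values))


# --------------------------------------------------------------------------
# projection


def project_ha(params: HAParams, horizon: int = HORIZON, **tags) -> LogNormalTrajectory:
    """Median cumulative deforestation grows linearly: exp(mu_t)=(t+1)e^{Def}."""
    if horizon < 1:
        raise InvalidSpecError("horizon must be >= 1")
    t = np.arange(horizon)
    return LogNormalTrajectory(mu=params.def_log + np.log(t + 1.0),
                               sigma=params.sigma, **tags)


def project_erb(params: ERBParams, sigma: float, **tags) -> LogNormalTrajectory:
    """All available land deforested linearly over the horizon (35 yr)."""
    if params.available_ha <= 0:
        raise DegenerateSeriesError("available area must be > 0")
    t = np.arange(params.horizon)
    mu = np.log(params.available_ha / params.horizon) + np.log(t + 1.0)
    return LogNormalTrajectory(mu=mu, sigma=sigma, **tags)


def project_jrc(params: JRCParams, sigma: float, horizon: int = HORIZON,
                **tags) -> LogNormalTrajectory:
    """Annual median (WDR_0/2 - alpha t)/100 x FC_t, rate floored at zero.

    FC recurses on the median annual deforestation; the rate is clamped at
    zero once the linear decrease crosses it (and after ``zero_year``).
    """
    if params.fc0 <= 0:
        raise InvalidSpecError("FC_0 must be > 0")
    fc = params.fc0
    annual = np.empty(horizon)
    years = START_YEAR + np.arange(horizon)
    for t in range(horizon):
        rate_pct = max(0.0, params.wdr0 / 2.0 - params.alpha * t)
        if params.zero_year is not None and years[t] > params.zero_year:
            rate_pct = 0.0
        annual[t] = rate_pct / 100.0 * fc
        fc -= annual[t]
        if fc < 0:
            raise InvalidSpecError("forest cover became negative during recursion")
    with np.errstate(divide="ignore"):
        mu = np.log(np.cumsum(annual))
    return LogNormalTrajectory(mu=mu, sigma=sigma, **tags)


def project_ci(params: CIParams, sub_scenario: str, sigma: float,
               horizon: int = HORIZON, **tags) -> LogNormalTrajectory:
    """Fixed-rate model: annual median r x FC_{t-1}; geometric decline of FC."""
    if sub_scenario not in params.rates:
        raise InvalidSpecError(
            f"unknown CI sub-scenario {sub_scenario!r}; expected one of {set(params.rates)}")
    if params.fc0 <= 0:
        raise InvalidSpecError("FC_0 must be > 0")
    r = params.rates[sub_scenario] / 100.0
    fc = params.fc0
    annual = np.empty(horizon)
    for t in range(horizon):
        annual[t] = r * fc
        fc -= annual[t]
    with np.errstate(divide="ignore"):
        mu = np.log(np.cumsum(annual))
    return LogNormalTrajectory(mu=mu, sigma=sigma, **tags)


def project_gm(params: GMParams, territory: str, gold_price: float | np.ndarray,
               horizon: int = HORIZON, n_draws: int = 10_000, seed: int = 0,
               **tags) -> MonteCarloTrajectory:
    """Monte-Carlo cumulative trajectory of the gold-mining model.

    Annual deforestation is the sum of two independent log-normal draws:
    the mining component ``logN(theta0 + theta_v log(GoldPrice_t), sigma_gm)``
    and the demographic component ``logN(theta0d + theta1d log(PopCh),
    sigma_dem)``. The cumulative distribution has no closed form, so the
    mean and 2.5/97.5 percentiles are estimated from ``n_draws`` draws.
    """
    if n_draws < 2:
        raise InvalidSpecError("n_draws must be >= 2")
    price = np.broadcast_to(np.asarray(gold_price, dtype=float), (horizon,))
    if np.any(price <= 0):
        raise InvalidSpecError("gold price must be > 0")
    rng = np.random.default_rng(seed)
    mu_gm = params.theta0_gm[territory] + params.theta_v[territory] * np.log(price)
    mu_dem = params.theta0_dem + params.theta1_dem * np.log(params.popch[territory])
    annual = (rng.lognormal(mu_gm, params.sigma_gm, size=(n_draws, horizon))
              + rng.lognormal(mu_dem, params.sigma_dem, size=(n_draws, horizon)))
    cum = np.cumsum(annual, axis=1)
    lo, hi = np.percentile(cum, [2.5, 97.5], axis=0)
    median = np.cumsum(np.exp(mu_gm) + np.full(horizon, np.exp(mu_dem)))
    return MonteCarloTrajectory(
        median=median, mean=cum.mean(axis=0), lo95=lo, hi95=hi,
        years=projection_years(horizon), territory=territory, **tags)


def check_alignment(a, b) -> None:
    """Raise if two trajectories do not share horizon and territory."""
    if len(a.years) != len(b.years) or np.any(np.asarray(a.years) != np.asarray(b.years)):
        raise SchemaError("trajectories do not share a common horizon")
    if a.territory and b.territory and a.territory != b.territory:
        raise SchemaError(f"territory mismatch: {a.territory} vs {b.territory}")
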