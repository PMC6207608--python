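"""Carbon-crediting arithmetic for avoided deforestation.

Avoided deforestation is the terminal-year gap between a candidate baseline
trajectory and the historical trajectory (the pathway the territory is
assumed to actually follow), floored at zero — a territory incurs no debt
when the agreed baseline sits below its historical average. Avoided area
converts to emissions through an aboveground carbon density (265 t/ha dry
biomass x 0.5 carbon fraction = 132.5 tC/ha) and the 44/12 CO2/C mass
ratio, then to revenue at a low (5 USD/tCO2e) and high (30 USD/tCO2e)
carbon price, expressed as a share of mean yearly GDP over 2001-2014.
Belowground biomass, soil carbon and degradation are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidSpecError
from .scenarios import check_alignment


@dataclass(frozen=True)
class CarbonConfig:
    biomass_t_ha: float = 265.0       # dry aboveground biomass, t/ha
    carbon_fraction: float = 0.5      # dry biomass -> carbon
    co2_per_c: float = 44.0 / 12.0    # CO2/C molar mass ratio
    price_low: float = 5.0            # USD/tCO2e
    price_high: float = 30.0          # USD/tCO2e

    def __post_init__(self):
        for name in ("biomass_t_ha", "carbon_fraction", "co2_per_c",
                     "price_low", "price_high"):
            if getattr(self, name) <= 0:
                raise InvalidSpecError(f"{name} must be positive")

    @property
    def carbon_density_tc_ha(self) -> float:
        """Aboveground carbon density, tC/ha (132.5 at defaults)."""
        return self.biomass_t_ha * self.carbon_fraction


@dataclass
class CreditEstimate:
    territory: str
    scenario: str
    price_usd: float
    avoided_ha: float
    avoided_ha_lo: float
    avoided_ha_hi: float
    tco2e: float
    revenue_usd: float
    gdp_share_pct: float
    gdp_share_lo: float
    gdp_share_hi: float


def avoided_area(scenario_traj, historical_traj) -> tuple[float, float, float]:
    """Terminal-year avoided deforestation (ha) with envelope bounds.

    max(0, mean cumulative(scenario) - mean cumulative(historical)) at the
    last shared year; the bounds propagate the scenario envelope only, the
    historical path being treated as the realized one.
    """
    check_alignment(scenario_traj, historical_traj)
    sc = scenario_traj.envelope().iloc[-1]
    hist_mean = float(historical_traj.envelope()["mean"].iloc[-1])
    central = max(0.0, float(sc["mean"]) - hist_mean)
    lo = max(0.0, float(sc["lo95"]) - hist_mean)
    hi = max(0.0, float(sc["hi95"]) - hist_mean)
    return central, lo, hi


def emissions(avoided_ha: float, config: CarbonConfig | None = None) -> float:
    """Avoided emissions, tCO2e = ha x carbon density x 44/12."""
    config = config or CarbonConfig()
    if avoided_ha < 0:
        raise InvalidSpecError("avoided area must be >= 0")
    return avoided_ha * config.carbon_density_tc_ha * config.co2_per_c


def gdp_share(revenue_usd: float, gdp_series) -> float:
    """Revenue as percent of mean yearly GDP (2001-2014 window).

    May exceed 100: cumulated 2015-2050 credits are compared with a single
    year's GDP.
    """
    gdp = np.asarray(gdp_series, dtype=float)
    if len(gdp) == 0 or np.any(gdp <= 0):
        raise InvalidSpecError("GDP series must be non-empty and positive")
    return 100.0 * revenue_usd / gdp.mean()


def ci_payment_fraction(annual_rate_percent: float, full_rate: float = 0.056,
                        zero_rate: float = 0.1) -> float:
    """Combined-Incentives payment rule.

    Full payment at or below the full-payment rate (0.056 %/yr), none at or
    above the no-payment rate (0.1 %/yr), linear in between (the published
    rule states only the endpoints).
    """
    if annual_rate_percent < 0:
        raise InvalidSpecError("deforestation rate must be >= 0")
    if full_rate >= zero_rate:
        raise InvalidSpecError("full-payment rate must be below no-payment rate")
    if annual_rate_percent <= full_rate:
        return 1.0
    if annual_rate_percent >= zero_rate:
        return 0.0
    return (zero_rate - annual_rate_percent) / (zero_rate - full_rate)


def credit_estimate(scenario_traj, historical_traj, gdp_series,
                    config: CarbonConfig | None = None) -> list[CreditEstimate]:
    """Full crediting line at both carbon prices for one scenario/territory."""
    config = config or CarbonConfig()
    a, lo, hi = avoided_area(scenario_traj, historical_traj)
    out = []
    for price in (config.price_low, config.price_high):
        e = emissions(a, config)
        out.append(CreditEstimate(
            territory=scenario_traj.territory,
            scenario=scenario_traj.scenario,
            price_usd=price,
            avoided_ha=a, avoided_ha_lo=lo, avoided_ha_hi=hi,
            tco2e=e,
            revenue_usd=e * price,
            gdp_share_pct=gdp_share(e * price, gdp_series),
            gdp_share_lo=gdp_share(emissions(lo, config) * price, gdp_series),
            gdp_share_hi=gdp_share(emissions(hi, config) * price, gdp_series),
        ))
    return out


def credits_frame(estimates: list[CreditEstimate]) -> pd.DataFrame:
    return pd.DataFrame([e.__dict__ for e in estimates])
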