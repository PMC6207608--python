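"""Run configuration: a single YAML document with per-module blocks."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .allocation import LocationModelConfig
from .crediting import CarbonConfig
from .errors import InvalidSpecError
from .synthetic import LandscapeSpec

SCENARIO_NAMES = ("HA", "ERB", "JRC2050", "JRC2100",
                  "CI_BAU", "CI_FPS", "CI_NPS", "GM_low", "GM_high")


@dataclass
class RunConfig:
    """Everything the end-to-end driver needs, seeds included."""

    seed: int = 1
    landscape: dict = field(default_factory=dict)
    territories: dict = field(default_factory=dict)   # name -> pop0/pop_growth/gdp0
    planted_gm: dict = field(default_factory=dict)    # generator truth for the GM draws
    history: dict = field(default_factory=dict)       # HistorySpec overrides
    preprocess: dict = field(default_factory=dict)    # threshold, window, min_neighbors
    gold_attribution_km: float = 10.0                 # greenstone-proximity rule
    location_model: dict = field(default_factory=dict)
    carbon: dict = field(default_factory=dict)
    scenarios: tuple = SCENARIO_NAMES
    maps_for: tuple = ("HA", "GM_high", "ERB")
    n_draws: int = 10_000
    figures: bool = False

    def __post_init__(self):
        unknown = set(self.scenarios) - set(SCENARIO_NAMES)
        if unknown:
            raise InvalidSpecError(f"unknown scenario name(s): {sorted(unknown)}")
        unknown = set(self.maps_for) - set(self.scenarios)
        if unknown:
            raise InvalidSpecError(f"maps requested for unlisted scenario(s): {sorted(unknown)}")

    def landscape_spec(self) -> LandscapeSpec:
        return LandscapeSpec(seed=self.seed, **self.landscape)

    def location_config(self) -> LocationModelConfig:
        return LocationModelConfig(**self.location_model)

    def carbon_config(self) -> CarbonConfig:
        return CarbonConfig(**self.carbon)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("scenarios", "maps_for"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["scenarios"] = list(self.scenarios)
        data["maps_for"] = list(self.maps_for)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def demo_config(seed: int = 1) -> RunConfig:
    """Bundled synthetic demo: two territories on a 300x300 landscape.

    Intensities are deliberately low relative to the forest stock (an HFLD
    situation): planted gold-mining and demographic medians of about 0.45
    and 0.35 ha/yr per territory against ~3,500 ha of available forest each.
    """
    return RunConfig(
        seed=seed,
        landscape=dict(rows=300, cols=300, pixel_size=30.0, n_roads=5,
                       n_greenstone=3, protected_fraction=0.12,
                       swamp_fraction=0.04),
        territories={
            "west": dict(pop0=60_000.0, pop_growth=500.0, gdp0=2.0e9),
            "east": dict(pop0=40_000.0, pop_growth=350.0, gdp0=1.2e9),
        },
        planted_gm=dict(
            theta0_gm={"west": -10.9, "east": -9.6},
            theta_v={"west": 1.5, "east": 1.3},
            sigma_gm=0.25,
            theta0_dem=-6.0, theta1_dem=0.8, sigma_dem=0.25,
        ),
        history=dict(noise_sigma=0.5, patch_px=5, min_patch_px=3,
                     gold_weights={"dist_greenstone": -3.5, "dist_stream_small": -1.0}),
        preprocess=dict(threshold=75.0, window=3, min_neighbors=2),
        gold_attribution_km=1.5,   # landscape is ~9 km across
        location_model=dict(n_estimators=200),
        n_draws=10_000,
    )
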