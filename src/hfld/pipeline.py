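"""End-to-end driver: synthesis -> preprocessing -> scenarios -> maps -> credits.

The pipeline is deterministic given (config, seed): every stage draws from a
generator derived from the run seed, and the manifest records seeds,
package versions and SHA-256 checksums of each CSV output.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from contextlib import contextmanager
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, allocation, crediting, preprocess, scenarios, synthetic
from .config import RunConfig
from .errors import HFLDError
from .raster_io import write_raster


class PipelineStageError(HFLDError):
    """Wraps a stage failure with the stage name; original in __cause__."""


@contextmanager
def _stage(name: str):
    try:
        yield
    except HFLDError as e:
        raise PipelineStageError(f"stage '{name}': {e}") from e


@dataclass
class PipelineResult:
    landscape: synthetic.Landscape
    observed: pd.DataFrame                  # year, territory, area_ha (post-filter)
    trajectories: dict                      # scenario -> territory -> trajectory
    trajectory_table: pd.DataFrame
    credits: pd.DataFrame
    importance: pd.DataFrame                # model, covariate, mdg
    maps: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def _territory_zones(shape: tuple[int, int], names: list[str]):
    """Vertical strips partitioning the grid, one per territory."""
    zones = np.zeros(shape, dtype=np.int32)
    cols = shape[1]
    bounds = np.linspace(0, cols, len(names) + 1).astype(int)
    for i in range(len(names)):
        zones[:, bounds[i]:bounds[i + 1]] = i
    return zones, {i: n for i, n in enumerate(names)}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, output_dir: str | Path | None = None
                 ) -> PipelineResult:
    """Run the whole analysis on a synthetic landscape; optionally write files."""
    seed = int(config.seed)
    terr_names = list(config.territories)

    with _stage("simulate-landscape"):
        landscape = synthetic.generate_landscape(config.landscape_spec())
    zones, zone_names = _territory_zones(landscape.tree_cover.shape, terr_names)

    with _stage("simulate-series"):
        gmp_true = scenarios.GMParams(
            popch={t: float(c["pop_growth"]) for t, c in config.territories.items()},
            **config.planted_gm)
        bundle, planted_def = synthetic.generate_series(
            config.territories, synthetic.CALIBRATION_YEARS, gmp_true, seed + 1)

    with _stage("simulate-history"):
        loss = np.zeros(landscape.tree_cover.shape, dtype=np.int16)
        for i, terr in enumerate(terr_names):
            sub = planted_def[planted_def["territory"] == terr].sort_values("year")
            spec = synthetic.HistorySpec(
                annual_ha=tuple(sub["area_ha"]),
                annual_gold_ha=tuple(sub["gold_ha"]),
                **config.history)
            hist = synthetic.generate_history(landscape, spec, seed + 10 + i,
                                              pool_mask=zones == i)
            loss = np.maximum(loss, hist.loss_year)

    pp = {"threshold": 75.0, "window": 3, "min_neighbors": 2, **config.preprocess}
    with _stage("preprocess"):
        fm = preprocess.forest_mask(landscape.tree_cover, pp["threshold"],
                                    landscape.spec.pixel_size)
        loss_f = preprocess.majority_filter(loss, pp["window"], pp["min_neighbors"])
        loss_f = preprocess.apply_exclusion_mask(loss_f, landscape.swamp)
        observed = preprocess.tabulate_annual(loss_f, fm, zones, zone_names)

    with _stage("attribute-gold"):
        stack = landscape.covariates()
        gold_attr = (loss_f > 0) & (
            stack.layers["dist_greenstone"] <= config.gold_attribution_km * 1000.0)
        pa = fm.pixel_area_ha
        rows = []
        for year in synthetic.CALIBRATION_YEARS:
            hit = (loss_f == year - 2000) & fm.mask
            for i, terr in zone_names.items():
                inz = hit & (zones == i)
                rows.append({"year": year, "territory": terr,
                             "gold_ha": float((inz & gold_attr).sum() * pa),
                             "area_ha": float(inz.sum() * pa)})
        attrib = pd.DataFrame(rows)
        attrib["nongold_ha"] = attrib["area_ha"] - attrib["gold_ha"]

    with _stage("calibrate"):
        ha_params = {}
        for terr in terr_names:
            series = observed[observed["territory"] == terr].sort_values("year")
            ha_params[terr] = scenarios.calibrate_ha(series["area_ha"].values)
        gm_params = scenarios.calibrate_gm(
            attrib.rename(columns={"area_ha": "total"})
                  .rename(columns={"gold_ha": "area_ha"})[["year", "territory", "area_ha"]],
            attrib.rename(columns={"area_ha": "total"})
                  .rename(columns={"nongold_ha": "area_ha"})[["year", "territory", "area_ha"]],
            bundle.gold_price, bundle.population)

    with _stage("project"):
        price_low = scenarios.gm_low_price(bundle.gold_price)
        price_high = scenarios.gm_high_price(bundle.gold_price)
        trajectories: dict[str, dict] = {s: {} for s in config.scenarios}
        fc0, available = {}, {}
        for i, terr in zone_names.items():
            inz = fm.mask & (zones == i)
            fc0[terr] = float(inz.sum() * pa)
            available[terr] = float((inz & ~landscape.protected).sum() * pa)
            sigma = ha_params[terr].sigma
            for s in config.scenarios:
                tags = dict(scenario=s, territory=terr)
                if s == "HA":
                    traj = scenarios.project_ha(ha_params[terr], **tags)
                elif s == "ERB":
                    traj = scenarios.project_erb(
                        scenarios.ERBParams(available[terr]), sigma, **tags)
                elif s in ("JRC2050", "JRC2100"):
                    params = scenarios.JRCParams.from_zero_year(fc0[terr], int(s[3:]))
                    traj = scenarios.project_jrc(params, sigma, **tags)
                elif s.startswith("CI_"):
                    traj = scenarios.project_ci(
                        scenarios.CIParams(fc0[terr]), s[3:], sigma, **tags)
                elif s in ("GM_low", "GM_high"):
                    price = price_low if s == "GM_low" else price_high
                    traj = scenarios.project_gm(
                        gm_params, terr, price, n_draws=config.n_draws,
                        seed=seed + 200 + i, scenario=s)
                trajectories[s][terr] = traj
        trajectory_table = pd.concat(
            [trajectories[s][t].envelope() for s in config.scenarios
             for t in terr_names], ignore_index=True)

    importance_rows, maps = [], {}
    if config.maps_for:
        with _stage("train-location"):
            loc_cfg = config.location_config()
            model_ha = allocation.train_location_model(
                stack, loss_f > 0, fm.mask, loc_cfg, seed=seed + 300)
            for cov, v in model_ha.importance.items():
                importance_rows.append({"model": "HA", "covariate": cov, "mdg": v})
            model_gmm = model_ngmm = None
            if gold_attr.any() and ((loss_f > 0) & ~gold_attr).any():
                model_gmm = allocation.train_location_model(
                    stack, (loss_f > 0) & gold_attr, fm.mask, loc_cfg, seed=seed + 301)
                model_ngmm = allocation.train_location_model(
                    stack, (loss_f > 0) & ~gold_attr, fm.mask, loc_cfg, seed=seed + 302)
                for name, m in (("GMM", model_gmm), ("NGMM", model_ngmm)):
                    for cov, v in m.importance.items():
                        importance_rows.append({"model": name, "covariate": cov, "mdg": v})

        with _stage("maps"):
            forest_2014 = fm.mask & (loss_f == 0)
            risk_ha = allocation.predict_risk(model_ha, stack, forest_2014)
            for s in config.maps_for:
                total_median = sum(np.asarray(trajectories[s][t].median)
                                   for t in terr_names)
                annual = allocation.annual_increments(total_median)
                if s in ("GM_low", "GM_high") and model_gmm is not None:
                    price = price_low if s == "GM_low" else price_high
                    gold_annual = sum(
                        np.exp(gm_params.theta0_gm[t]
                               + gm_params.theta_v[t] * np.log(price))
                        for t in terr_names) * np.ones(scenarios.HORIZON)
                    dem_annual = np.maximum(annual - gold_annual, 0.0)
                    comp = {"gold": gold_annual, "dem": dem_annual}
                    risks = {"gold": allocation.predict_risk(model_gmm, stack, forest_2014),
                             "dem": allocation.predict_risk(model_ngmm, stack, forest_2014)}
                    allowed = None
                else:
                    comp = {"all": annual}
                    risks = {"all": risk_ha}
                    allowed = ~landscape.protected if s == "ERB" else None
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")  # ERB exhausts the pool by design
                    maps[s] = allocation.project_maps(
                        comp, risks, forest_2014, pa, seed=seed + 400,
                        allowed_mask=allowed)

    with _stage("credit"):
        carbon = config.carbon_config()
        estimates = []
        for terr in terr_names:
            gdp = bundle.gdp[bundle.gdp["territory"] == terr]["value"].values
            for s in config.scenarios:
                if s == "HA":
                    continue
                estimates.extend(crediting.credit_estimate(
                    trajectories[s][terr], trajectories["HA"][terr], gdp, carbon))
        credits = crediting.credits_frame(estimates)

    importance = pd.DataFrame(importance_rows)
    result = PipelineResult(landscape=landscape, observed=observed,
                            trajectories=trajectories,
                            trajectory_table=trajectory_table,
                            credits=credits, importance=importance, maps=maps)
    result.manifest = {
        "seed": seed,
        "hfld_version": __version__,
        "config": asdict(config) | {"scenarios": list(config.scenarios),
                                    "maps_for": list(config.maps_for)},
        "fc0_ha": fc0, "available_ha": available,
    }

    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        checksums = {}
        for name, df in (("series.csv", observed),
                         ("trajectories.csv", trajectory_table),
                         ("credits.csv", credits),
                         ("importance.csv", importance)):
            p = out / name
            df.to_csv(p, index=False)
            checksums[name] = _sha256(p)
        for s, arr in maps.items():
            write_raster(out / f"map_{s}.tif", arr, landscape.spec.pixel_size)
        result.manifest["checksums"] = checksums
        (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2))
        if config.figures:
            from . import figures
            figures.make_all(result, out)
    return result
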