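"""Synthetic-data analogues of the study's summary figures.

All panels are produced from pipeline outputs on synthetic landscapes and
are labelled as such; they illustrate the qualitative patterns (scenario
spread, trajectory envelopes, covariate-importance contrast, GDP shares),
not any real geography.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def scenario_spread(trajectory_table, path: Path) -> None:
    """Terminal-year mean cumulative deforestation per scenario/territory (log y)."""
    last = trajectory_table.groupby(["scenario", "territory"]).tail(1)
    fig, ax = plt.subplots(figsize=(8, 4))
    for terr, grp in last.groupby("territory"):
        order = np.argsort(grp["mean"].values)
        g = grp.iloc[order]
        x = np.arange(len(g))
        ax.errorbar(x, g["mean"], yerr=[g["mean"] - g["lo95"], g["hi95"] - g["mean"]],
                    fmt="o", capsize=3, label=terr)
        ax.set_xticks(x, g["scenario"], rotation=45, ha="right")
    ax.set_yscale("log")
    ax.set_ylabel("cumulative deforestation 2050 (ha)")
    ax.set_title("Scenario spread (synthetic data)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def trajectory_envelopes(trajectory_table, path: Path) -> None:
    """Cumulative mean with 95 % envelope per scenario, pooled territories."""
    fig, ax = plt.subplots(figsize=(7, 5))
    pooled = trajectory_table.groupby(["scenario", "year"]).sum(numeric_only=True).reset_index()
    for s, grp in pooled.groupby("scenario"):
        ax.plot(grp["year"], grp["mean"], label=s)
        ax.fill_between(grp["year"], grp["lo95"], grp["hi95"], alpha=0.15)
    ax.set_yscale("log")
    ax.set_xlabel("year")
    ax.set_ylabel("cumulative deforestation (ha)")
    ax.set_title("Reference-level trajectories (synthetic data)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def importance_ranking(importance, path: Path) -> None:
    """MDG bars per location model (historical / gold-mining / no-gold-mining)."""
    models = importance["model"].unique()
    fig, axes = plt.subplots(1, len(models), figsize=(4 * len(models), 4), squeeze=False)
    for ax, m in zip(axes[0], models):
        grp = importance[importance["model"] == m].sort_values("mdg")
        ax.barh(grp["covariate"], grp["mdg"])
        ax.set_title(f"{m} (synthetic)")
        ax.set_xlabel("Mean Decrease in Gini")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def gdp_shares(credits, path: Path) -> None:
    """Credit value as % of mean yearly GDP, low-to-high carbon price ranges."""
    fig, ax = plt.subplots(figsize=(8, 4))
    piv = credits.pivot_table(index=["territory", "scenario"], columns="price_usd",
                              values="gdp_share_pct").reset_index()
    labels = piv["territory"] + ":" + piv["scenario"]
    lo, hi = piv.iloc[:, 2], piv.iloc[:, 3]
    x = np.arange(len(piv))
    ax.vlines(x, lo, hi, lw=4, alpha=0.6)
    ax.set_xticks(x, labels, rotation=60, ha="right", fontsize=7)
    ax.set_ylabel("% of mean yearly GDP 2001-2014")
    ax.set_title("Carbon-credit value range across carbon prices (synthetic)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def make_all(result, outdir: Path) -> list[Path]:
    outdir = Path(outdir)
    paths = []
    jobs = [(scenario_spread, result.trajectory_table, "fig_scenario_spread.png"),
            (trajectory_envelopes, result.trajectory_table, "fig_trajectories.png")]
    if len(result.importance):
        jobs.append((importance_ranking, result.importance, "fig_importance.png"))
    if len(result.credits):
        jobs.append((gdp_shares, result.credits, "fig_gdp_shares.png"))
    for fn, data, name in jobs:
        p = outdir / name
        fn(data, p)
        paths.append(p)
    return paths
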