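"""Figures for fitted heteroplasmy models.

Each plotting helper also returns the plotted numbers as DataFrames so a CSV
twin of every figure can be written (the CLI does this automatically).
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .inference import FIT_FEATURES, HeteroplasmyResults
from .model import normalized_predictions

_FEATURE_LABELS = {
    "M_ETC": "ETC mRNA (fold-change)",
    "P_plus": "ETC protein (fold-change)",
    "M_gly": "glycolysis mRNA (fold-change)",
    "V": "cell volume (fold-change)",
    "G": "growth rate (fold-change)",
    "R_max": "max. respiratory capacity (fold-change)",
    "density": "wild-type mtDNA density N+/V",
    "delta_m": "ETC mRNA degradation rate",
    "oxphos_fraction": "OXPHOS share of power supply",
}


def plot_feature_fits(
    result: HeteroplasmyResults,
    h_grid=None,
    features: tuple[str, ...] = FIT_FEATURES,
    quantiles: tuple[float, float] = (25.0, 75.0),
):
    """Per-feature panels: MAP line, posterior-mean line, credible band, data.

    Data points above the fitted domain (h > 0.9) are drawn in grey — they
    are shown but were not used to train the model.

    Returns (figure, dict of per-feature DataFrames with plotted numbers).
    """
    if h_grid is None:
        h_grid = np.linspace(0.0, 1.0, 101)
    h_grid = np.asarray(h_grid, dtype=float)
    table = result.model.feature_table
    map_pred = normalized_predictions(h_grid, result.map_params)
    mean_pred = normalized_predictions(h_grid, result.mean_params)

    ncols = 3
    nrows = int(np.ceil(len(features) / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(4 * ncols, 3 * nrows), squeeze=False)
    csv_twins: dict[str, pd.DataFrame] = {}
    for ax, feature in zip(axes.ravel(), features):
        band = result.credible_band(h_grid, feature, quantiles)
        ax.fill_between(band["h"], band["lo"], band["hi"], color="pink", alpha=0.7,
                        label=f"{quantiles[0]:g}-{quantiles[1]:g}% CI")
        ax.plot(h_grid, map_pred[feature], "k-", lw=1.5, label="MAP")
        ax.plot(h_grid, mean_pred[feature], "r-", lw=1.0, label="posterior mean")
        sub = table[table["feature"] == feature]
        for grey, sel in ((False, ~sub["excluded_from_fit"]), (True, sub["excluded_from_fit"])):
            pts = sub[sel.astype(bool)]
            if len(pts):
                ax.errorbar(pts["h"], pts["value"], yerr=pts["uncertainty"],
                            fmt="o", ms=4, color="grey" if grey else "C0",
                            label="data (h = 1, unfitted)" if grey else "data")
        ax.set_xlabel("heteroplasmy h")
        ax.set_ylabel(_FEATURE_LABELS.get(feature, feature))
        csv_twins[feature] = pd.DataFrame(
            {"h": h_grid, "map": map_pred[feature].to_numpy(),
             "mean": mean_pred[feature].to_numpy(),
             "lo": band["lo"], "hi": band["hi"]}
        )
    for ax in axes.ravel()[len(features):]:
        ax.set_visible(False)
    axes[0, 0].legend(fontsize=7)
    fig.tight_layout()
    return fig, csv_twins


def plot_derived_trajectories(
    result: HeteroplasmyResults,
    h_grid=None,
    quantiles: tuple[float, float] = (25.0, 75.0),
):
    """Panels for N+/V density homeostasis and the degradation-rate posterior.

    Returns (figure, dict of per-feature DataFrames with plotted numbers).
    """
    if h_grid is None:
        h_grid = np.linspace(0.0, 0.9, 91)
    derived = result.derived_posteriors(h_grid, quantiles)
    fig, axes = plt.subplots(1, len(derived), figsize=(4 * len(derived), 3))
    for ax, (feature, band) in zip(np.atleast_1d(axes), derived.items()):
        ax.fill_between(band["h"], band["lo"], band["hi"], color="pink", alpha=0.7)
        ax.plot(band["h"], band["median"], "k-", lw=1.5)
        ax.set_xlabel("heteroplasmy h")
        ax.set_ylabel(_FEATURE_LABELS.get(feature, feature))
    fig.tight_layout()
    return fig, derived


def plot_h_star_posterior(result: HeteroplasmyResults):
    """Histogram of the critical-heteroplasmy posterior with CI markers."""
    fig, ax = plt.subplots(figsize=(4, 3))
    draws = result.draws["h_star"]
    ax.hist(draws, bins=40, density=True, color="C0", alpha=0.8)
    for q, style in (((25, 75), "k-"), ((5, 95), "k--")):
        lo, hi = result.h_star_interval(q)
        for x in (lo, hi):
            ax.axvline(x, ls=style[1:], color="k", lw=1)
    ax.set_xlabel("critical heteroplasmy h*")
    ax.set_ylabel("posterior density")
    fig.tight_layout()
    return fig, pd.DataFrame({"h_star": draws})


def save_figure_with_csv(fig, tables, stem: str | Path) -> None:
    """Write <stem>.png plus one CSV per plotted table (the figure's twin)."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(stem.with_suffix(".png"), dpi=150)
    plt.close(fig)
    if isinstance(tables, pd.DataFrame):
        tables.to_csv(stem.with_suffix(".csv"), index=False)
    else:
        for name, df in tables.items():
            df.to_csv(stem.parent / f"{stem.name}_{name}.csv", index=False)
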