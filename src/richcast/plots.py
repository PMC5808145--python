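"""Diagnostic figures for hindcast experiments.

Analogues of the standard verification views: observed-vs-predicted
scatter, per-forecast skill distributions, horizon curves, MSE
decomposition bars, and before/after observer-correction arrows.  Each
function writes one image file and returns the path.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from . import evaluation

__all__ = [
    "plot_obs_vs_pred",
    "plot_skill_distributions",
    "plot_horizon_curves",
    "plot_decomposition",
    "plot_correction_arrows",
]


def plot_obs_vs_pred(forecast_sets, observed, path):
    models = sorted({m for m, _ in forecast_sets})
    fig, axes = plt.subplots(1, len(models), figsize=(3 * len(models), 3),
                             squeeze=False)
    for ax, model in zip(axes[0], models):
        fc = forecast_sets.get((model, False))
        if fc is None:
            fc = forecast_sets[(model, True)]
        m = evaluation.joined(fc, observed)
        ax.scatter(m["mean"], m["richness"], s=4, alpha=0.4)
        lim = [min(m["mean"].min(), m["richness"].min()),
               max(m["mean"].max(), m["richness"].max())]
        ax.plot(lim, lim, color="k", lw=0.8)
        ax.set_title(model)
        ax.set_xlabel("predicted")
    axes[0][0].set_ylabel("observed richness")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_skill_distributions(skills, path):
    fig, ax = plt.subplots(figsize=(6, 3.5))
    labels, data = [], []
    for (model, corrected), frame in sorted(skills.items()):
        labels.append(f"{model}{'+obs' if corrected else ''}")
        data.append(frame["d_abs_error"].to_numpy())
    ax.boxplot(data, tick_labels=labels, showfliers=False)
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_ylabel("|error| - baseline |error| (species)")
    plt.setp(ax.get_xticklabels(), rotation=45, ha="right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_horizon_curves(horizon_metrics, path, metric="rmse"):
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for (model, corrected), grp in horizon_metrics.groupby(["model", "corrected"]):
        ax.plot(grp["horizon"], grp[metric], marker="o", ms=3,
                label=f"{model}{'+obs' if corrected else ''}")
    if metric == "coverage95":
        ax.axhline(0.95, color="k", lw=0.8)
    ax.set_xlabel("forecast horizon (years)")
    ax.set_ylabel(metric)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_decomposition(decompositions, path):
    fig, ax = plt.subplots(figsize=(6, 3.5))
    labels = [f"{m}{'+obs' if c else ''}" for m, c in sorted(decompositions)]
    site = [decompositions[k].site_component for k in sorted(decompositions)]
    annual = [decompositions[k].annual_component for k in sorted(decompositions)]
    x = np.arange(len(labels))
    ax.bar(x - 0.2, site, width=0.4, label="site-level mean")
    ax.bar(x + 0.2, annual, width=0.4, label="annual fluctuation")
    ax.set_xticks(x, labels, rotation=45, ha="right")
    ax.set_ylabel("squared error (species$^2$)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_correction_arrows(metrics, path, metric="rmse"):
    """Arrows from uncorrected to observer-corrected metric values per model."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    pooled = metrics[metrics["horizon"] == "pooled"] if "horizon" in metrics else metrics
    models = sorted(pooled["model"].unique())
    for i, model in enumerate(models):
        sub = pooled[pooled["model"] == model]
        try:
            v0 = float(sub.loc[~sub["corrected"], metric].iloc[0])
            v1 = float(sub.loc[sub["corrected"].astype(bool), metric].iloc[0])
        except IndexError:
            continue
        ax.annotate("", xy=(i, v1), xytext=(i, v0),
                    arrowprops=dict(arrowstyle="->", color="C0"))
        ax.plot([i], [v0], "o", color="grey", ms=4)
    if metric == "coverage95":
        ax.axhline(0.95, color="k", lw=0.8)
    ax.set_xticks(range(len(models)), models, rotation=45, ha="right")
    ax.set_ylabel(metric)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
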