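"""Matplotlib figures for packaging-trajectory analyses."""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_trace", "plot_velocity_fit", "plot_pwd",
           "plot_step_histogram", "plot_slip_violins"]


def plot_trace(trace, packaged=None, ax=None, decimate=10):
    """Raw extension (and optionally packaged length) vs time."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3))
    sl = slice(None, None, decimate)
    if packaged is None:
        ax.plot(trace.time[sl], trace.extension[sl], lw=0.4, color="0.6")
        ax.set_ylabel("extension (nm)")
    else:
        ax.plot(trace.time[sl], packaged[sl], lw=0.4,
                color="tab:blue")
        ax.set_ylabel("packaged length (nm)")
    ax.set_xlabel("time (s)")
    ax.set_title(trace.meta.get("substrate_name", ""))
    return ax


def plot_velocity_fit(centers, density, fit, ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    ax.bar(centers, density, width=centers[1] - centers[0], color="0.8")
    x = np.linspace(centers.min(), centers.max(), 400)
    g0 = fit.zero_weight / (fit.zero_mean_sigma * np.sqrt(2 * np.pi)) \
        * np.exp(-0.5 * (x / fit.zero_mean_sigma) ** 2)
    g1 = fit.packaging_weight / (fit.packaging_sigma * np.sqrt(2 * np.pi)) \
        * np.exp(-0.5 * ((x - fit.packaging_mean) / fit.packaging_sigma) ** 2)
    ax.plot(x, g0, "k:", label="pausing")
    ax.plot(x, g1, "k--", label="packaging")
    ax.plot(x, g0 + g1, "k-", lw=1)
    ax.axvline(fit.packaging_mean, ls=":", color="tab:red")
    ax.set_xlabel("velocity (nm/s)")
    ax.set_ylabel("density")
    ax.legend(fontsize=7)
    return ax


def plot_pwd(result, ax=None):
    """Selectively averaged pairwise-distance distribution with peaks."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    ax.plot(result.distance_grid, result.all_trace_average, color="0.7",
            lw=0.8, label="all traces")
    ax.plot(result.distance_grid, result.averaged_density, color="tab:blue",
            lw=1.2, label="top 30%")
    for k in range(1, 5):
        ax.axvline(k * result.burst_size, ls="--", color="0.4", lw=0.6)
    ax.set_xlabel("pairwise distance (nm)")
    ax.set_ylabel("density")
    ax.set_title(f"burst = {result.burst_size:.2f} "
                 f"$\\pm$ {result.burst_size_se:.2f} nm")
    ax.legend(fontsize=7)
    return ax


def plot_step_histogram(centers, density, ax=None, label=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    ax.step(centers, density, where="mid", label=label)
    ax.axvline(0.85, ls="--", color="k", lw=0.6)
    ax.set_xlabel("step size (nm)")
    ax.set_ylabel("density")
    return ax


def plot_slip_violins(stats_by_label, fields=("start_dwell", "end_dwell",
                                              "mid_time", "total_length"),
                      axs=None):
    """Violin plots of slip-event statistics for several cohorts."""
    if axs is None:
        _, axs = plt.subplots(1, len(fields), figsize=(3 * len(fields), 3))
    labels = list(stats_by_label)
    for ax, field in zip(np.atleast_1d(axs), fields):
        data = [stats_by_label[lab].raw[field][
                    np.isfinite(stats_by_label[lab].raw[field])]
                for lab in labels]
        data = [d if d.size else np.array([0.0]) for d in data]
        ax.violinplot(data, showmedians=True)
        ax.set_xticks(range(1, len(labels) + 1), labels, fontsize=7,
                      rotation=20)
        ax.set_title(field, fontsize=8)
    return axs
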