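"""Small plotting helpers (PNG output, Agg-safe)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_sweep", "plot_logistic_fit", "plot_spectrum", "plot_heatmap"]


def plot_sweep(result, path, *, xlabel="parameter factor"):
    """Rolled length vs sweep factor, with the critical factor marked."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(result.factors, result.rolled_lengths * 1e6, "o-")
    if np.isfinite(result.critical_factor):
        ax.axvline(result.critical_factor, color="crimson", ls="--", lw=1)
    ax.set_xlabel(xlabel)
    ax.set_ylabel("rolled length L* (um)")
    ax.set_yscale("log")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_logistic_fit(trace, fit, path):
    """Cumulative rolled area with the fitted logistic overlay."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(trace.times, trace.cumulative_area, "o", ms=3, label="measured")
    tt = np.linspace(trace.times[0], trace.times[-1], 400)
    ax.plot(tt, fit.predict(tt), "-", color="crimson",
            label=f"logistic, tau = {fit.tau:.1f} s")
    ax.axvline(fit.onset_time, color="grey", ls=":", lw=1)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("cumulative rolled area (um$^2$)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_spectrum(result, path):
    """Radially averaged power spectrum with detected peak radius."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.semilogy(result.radial_frequencies, np.maximum(result.radial_power, 1e-12))
    if np.isfinite(result.period):
        ax.axvline(1.0 / result.period, color="crimson", ls="--", lw=1,
                   label=f"period {result.period:.2f} nm")
        ax.legend()
    ax.set_xlabel("spatial frequency (1/nm)")
    ax.set_ylabel("radial power")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_heatmap(grid, path, *, cmap="RdBu_r", label=""):
    """Symmetric-scale heatmap (curvature fields, segmentations, heights)."""
    fig, ax = plt.subplots(figsize=(4.5, 4))
    vmax = float(np.nanmax(np.abs(grid))) or 1.0
    im = ax.imshow(grid, cmap=cmap, vmin=-vmax, vmax=vmax, origin="lower")
    fig.colorbar(im, ax=ax, label=label)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
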