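"""Plot helpers mirroring the standard figure layouts.

All functions take an optional matplotlib Axes and return it; files are only
written when a path is given. matplotlib is imported lazily so headless
pipelines pay nothing for it.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np


def _get_ax(ax):
    if ax is not None:
        return ax
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_radial_profile(profile, cutoffs=None, ax=None, path: str | Path | None = None):
    """Mirrored radial intensity profile with optional cutoff markers."""
    ax = _get_ax(ax)
    r = np.concatenate([-profile.radii[::-1], profile.radii])
    v = np.concatenate([profile.mean_intensity[::-1], profile.mean_intensity])
    ax.plot(r, v, lw=1.5)
    if cutoffs is not None:
        for frac, radius in ((0.5, cutoffs.r50), (0.2, cutoffs.r20), (0.1, cutoffs.r10)):
            ax.axhline(frac, ls=":", color="gray", lw=0.8)
            ax.axvline(radius, ls=":", color="gray", lw=0.8)
            ax.axvline(-radius, ls=":", color="gray", lw=0.8)
    ax.set_xlabel("radial distance (Å)")
    ax.set_ylabel("mean intensity (normalized)")
    if path:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax


def plot_separation_histogram(hist, ax=None, path: str | Path | None = None):
    """2 Å-binned separation counts; bars left-aligned to the lower edge,
    x labels on the upper edge."""
    ax = _get_ax(ax)
    width = np.diff(hist.bin_lower_edges).mean() if len(hist.bin_lower_edges) > 1 else 2.0
    ax.bar(hist.bin_lower_edges, hist.counts, width=width, align="edge", edgecolor="black")
    ax.set_xticks(hist.bin_lower_edges + width)
    ax.set_xlabel("center-to-center separation, bin upper edge (Å)")
    ax.set_ylabel("particles")
    if path:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax


def plot_pddf(results: dict, ax=None, path: str | Path | None = None):
    """Overlay of pair-distance distributions, keyed by label."""
    ax = _get_ax(ax)
    for label, res in results.items():
        ax.plot(res.r, res.p_r / res.p_r.max(), label=f"{label} (Dmax {res.dmax:.0f} Å)")
    ax.set_xlabel("r (Å)")
    ax.set_ylabel("p(r), normalized")
    ax.legend()
    if path:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax
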