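"""Diagnostic plots: the trait space and distance-vs-feedback panels."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_root_economics_space(space, path=None):
    """Scatter of oriented species scores with strategy quadrants."""
    fig, ax = plt.subplots(figsize=(5, 5))
    strategies = space.strategies["strategy"]
    colors = {"OS": "tab:olive", "OF": "tab:orange", "DS": "tab:green", "DF": "tab:red"}
    for strat, group in space.scores.groupby(strategies):
        ax.scatter(group["collab"], group["cons"], label=strat,
                   color=colors.get(strat, "gray"), s=25)
    ax.axhline(0, color="k", lw=0.5)
    ax.axvline(0, color="k", lw=0.5)
    ve = space.variance_explained
    ax.set_xlabel(f"collaboration (DIY ->) [{ve['collab']:.0f}%]")
    ax.set_ylabel(f"conservation (fast ->) [{ve['cons']:.0f}%]")
    ax.legend(title="strategy", fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_distance_vs_psf(geometry, path=None):
    """Feedback value against the signed distance along each axis."""
    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
    for ax, col, label in zip(axes, ["coll_dist", "cons_dist"],
                              ["collaboration distance", "conservation distance"]):
        ax.scatter(geometry[col], geometry["psf_value"], s=15, alpha=0.6)
        ax.axhline(0, color="k", lw=0.5)
        ax.axvline(0, color="k", lw=0.5)
        ax.set_xlabel(f"{label} (away - home)")
    axes[0].set_ylabel("PSF_home/away")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
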