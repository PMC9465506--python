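"""Small matplotlib helpers for decline curves and CJS estimates."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .cjs import CJSResults
from .curves import DeclineCurve

__all__ = ["plot_decline_curve", "plot_estimates"]


def plot_decline_curve(curve: DeclineCurve, ax=None):
    """Absolute (top) and relative (bottom) cumulative-locality decline."""
    if ax is None:
        fig, axes = plt.subplots(2, 1, sharex=True, figsize=(7, 5))
    else:
        fig, axes = ax.figure, [ax]
    x = np.arange(len(curve.decades))
    axes[0].step(x, curve.cumulative_counts, where="mid")
    axes[0].set_ylabel("localities")
    axes[0].set_title(f"Cumulative locality decline — {curve.stratum}")
    if len(axes) > 1 and curve.relative_percent is not None:
        axes[1].step(x, curve.relative_percent, where="mid", color="tab:red")
        axes[1].set_ylabel("% of earliest decade")
        axes[1].set_ylim(0, 105)
    axes[-1].set_xticks(x)
    axes[-1].set_xticklabels(curve.decades, rotation=45, ha="right")
    fig.tight_layout()
    return fig


def plot_estimates(results: CJSResults, ax=None):
    """Per-decade persistence and detection estimates with +-1 SE bars.

    Boundary / confounded estimates are left out, mirroring how an
    inestimable terminal detection parameter is conventionally not plotted.
    """
    if ax is None:
        fig, ax = plt.subplots(figsize=(7, 4))
    else:
        fig = ax.figure
    frame = results.estimates_frame()
    for param, color in (("phi", "tab:blue"), ("p", "tab:orange")):
        sub = frame[(frame["parameter"] == param) & ~frame["boundary"]]
        ax.errorbar(
            sub["index"],
            sub["estimate"],
            yerr=sub["se"],
            marker="o",
            linestyle="-",
            color=color,
            label="persistence (phi)" if param == "phi" else "detection (p)",
        )
    ax.set_ylim(0, 1)
    ax.set_xlabel("occasion")
    ax.set_ylabel("probability per decade")
    ax.set_title(results.spec.name)
    ax.legend()
    fig.tight_layout()
    return fig
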