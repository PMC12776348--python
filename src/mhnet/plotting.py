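"""Heatmap visualization of a trained MHN parameter matrix.

The display is multiplicative (exp of the stored log parameters): a separate
left column with the base rates, the n x n matrix of rate multipliers (rows =
affected event, columns = influencing event), and — for observation-aware
models — a bottom row with each event's multiplier on the observation rate.
Colors diverge around multiplier 1 (no effect), annotations are rounded to
two decimals.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import TwoSlopeNorm

from .model import MutualHazardNetwork

__all__ = ["render_heatmap"]


def _annotate(ax, values, norm, cmap) -> None:
    for (r, c), v in np.ndenumerate(values):
        lum = np.array(cmap(norm(np.log(v)))[:3]) @ [0.299, 0.587, 0.114]
        ax.text(
            c, r, f"{v:.2f}", ha="center", va="center",
            fontsize=7, color="black" if lum > 0.5 else "white",
        )


def render_heatmap(model: MutualHazardNetwork, path: str | Path, dpi: int = 150) -> None:
    """Write the model heatmap to ``path`` (format from the file suffix)."""
    n = model.n
    names = list(model.catalog.names)
    mult = model.multipliers()
    base = np.exp(np.diag(model.log_theta[:n]))
    inter = mult[:n].copy()
    np.fill_diagonal(inter, 1.0)  # diagonal shown separately as base rates
    with_obs = model.kind != "classic"

    # symmetric color range around log-multiplier 0
    span = max(np.abs(np.log(inter)).max(), np.abs(model.log_theta[n]).max()
               if with_obs else 0.0, np.abs(np.log(base)).max(), 0.5)
    norm = TwoSlopeNorm(vmin=-span, vcenter=0.0, vmax=span)
    cmap = plt.get_cmap("RdBu_r")

    nrows = n + (1 if with_obs else 0)
    fig_w = 1.2 + 0.45 * (n + 1)
    fig_h = 1.2 + 0.45 * nrows
    fig, axes = plt.subplots(
        1 + int(with_obs), 2,
        figsize=(fig_w, fig_h),
        gridspec_kw={
            "width_ratios": [1, n],
            "height_ratios": [n, 1] if with_obs else [n],
            "wspace": 0.05, "hspace": 0.05,
        },
        squeeze=False,
    )
    ax_base, ax_int = axes[0]
    ax_base.imshow(np.log(base)[:, None], cmap=cmap, norm=norm, aspect="auto")
    _annotate(ax_base, base[:, None], norm, cmap)
    ax_base.set_xticks([0], ["base rate"], rotation=90)
    ax_base.set_yticks(range(n), names)
    ax_base.xaxis.tick_top()

    ax_int.imshow(np.log(inter), cmap=cmap, norm=norm, aspect="auto")
    _annotate(ax_int, inter, norm, cmap)
    ax_int.set_xticks(range(n), names, rotation=90)
    ax_int.xaxis.tick_top()
    ax_int.set_yticks([])

    if with_obs:
        axes[1][0].axis("off")
        ax_obs = axes[1][1]
        obs = mult[n][None, :]
        ax_obs.imshow(np.log(obs), cmap=cmap, norm=norm, aspect="auto")
        _annotate(ax_obs, obs, norm, cmap)
        ax_obs.set_xticks([])
        ax_obs.set_yticks([0], ["observation"])

    fig.suptitle("Base rates and rate multipliers", y=0.99, fontsize=10)
    fig.savefig(path, dpi=dpi, bbox_inches="tight")
    plt.close(fig)
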