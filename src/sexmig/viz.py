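"""Rendering of likelihood surfaces as heatmaps.

Plots mirror the standard presentation for this analysis: probability of
the observed pattern over total migration rate 2Nm (abscissa, log scale)
and female fraction of migrants p (ordinate), lighter = more likely, with
the equal-rate null line dashed at p = 0.5 and the 95% likelihood-ratio
confidence region outlined.  Rendering is headless-safe and purely an
artifact: no decision depends on it.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .inference import LikelihoodSurface

__all__ = ["plot_surface"]


def plot_surface(
    surface: LikelihoodSurface,
    path: str | Path | None = None,
    title: str | None = None,
    ax: plt.Axes | None = None,
) -> plt.Axes:
    """Heatmap of the pattern probability with null line and CI contour."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    mig = surface.grid.mig_values
    p = surface.grid.p_values
    with np.errstate(over="ignore"):
        prob = np.exp(surface.loglik)
    mesh = ax.pcolormesh(mig, p, prob.T, cmap="gray", shading="nearest")
    ax.figure.colorbar(mesh, ax=ax, label="pattern probability")
    ax.contour(
        mig, p, surface.ci_mask.T.astype(float), levels=[0.5], colors="tab:blue"
    )
    ax.axhline(0.5, linestyle="--", color="tab:red", linewidth=1)
    for m_hat, p_hat in surface.mle:
        ax.plot(m_hat, p_hat, "r*", markersize=8)
    ax.set_xscale("log")
    ax.set_xlabel("total migration rate $2Nm$")
    ax.set_ylabel("female fraction of migrants $m_F/(m_F+m_M)$")
    if title:
        ax.set_title(title)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
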