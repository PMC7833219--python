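"""Matplotlib views of the analysis objects.

Three panels mirror the method's standard figures: the stress-prediction
diagram (partitioned complexity domain with labelled segment points), the
step-function view of a complexity track, and the power-law curve over its
(τ, bE) scatter.
"""

from __future__ import annotations

import numpy as np

__all__ = ["plot_stress_diagram", "plot_complexity_track", "plot_power_law"]


def _get_ax(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots(figsize=(6, 5))
    return ax


def plot_stress_diagram(partition, points=None, labels=None, ax=None):
    """Partitioned effective domain: normoxemia regions in yellow,
    hypoxemia in blue, hull boundaries outlined, points overlaid (green
    γ=+1, red γ=−1)."""
    import matplotlib.tri as mtri

    ax = _get_ax(ax)
    mesh = partition.mesh_points
    tri = mtri.Triangulation(mesh[:, 0], mesh[:, 1], partition.simplices)
    ax.tripcolor(
        tri, facecolors=partition.triangle_classes.astype(float),
        cmap="cividis_r", vmin=-1.4, vmax=1.4, alpha=0.6,
    )
    for geoms, color in ((partition.positive_polygons, "darkgoldenrod"),
                         (partition.negative_polygons, "navy")):
        for g in geoms:
            if g.geom_type == "Polygon":
                xs, ys = np.asarray(g.exterior.coords).T
                ax.plot(xs, ys, color=color, lw=1.5)
    if points is not None:
        points = np.asarray(points)
        labels = np.asarray(labels)
        pos = labels == 1
        ax.scatter(points[pos, 0], points[pos, 1], c="green", s=40,
                   edgecolor="k", zorder=3, label="γ = +1 (normoxemia)")
        ax.scatter(points[~pos, 0], points[~pos, 1], c="red", s=40,
                   edgecolor="k", zorder=3, label="γ = −1 (hypoxemia)")
        ax.legend(loc="best", fontsize=8)
    ax.set_xlabel("H(HRV)")
    ax.set_ylabel("H(SF)")
    ax.set_title("Stress prediction diagram")
    return ax


def plot_complexity_track(track, ax=None, **step_kw):
    """Per-segment Hurst exponents as a step function over the segment
    boundaries, with the track mean (the perceptron threshold) dashed."""
    ax = _get_ax(ax)
    b = track.segmentation.boundaries
    vals = np.append(track.values, track.values[-1])
    ax.step(b, vals, where="post", **step_kw)
    ax.axhline(track.mean(), ls="--", color="orange", lw=1,
               label=f"E[H] = {track.mean():.3f}")
    ax.set_xlabel("time [s]")
    ax.set_ylabel(f"H({track.label})")
    ax.set_ylim(0, 1)
    ax.legend(fontsize=8)
    return ax


def plot_power_law(fit, ax=None):
    """Fitted α·τ^β curve over its (τ, bE) scatter."""
    ax = _get_ax(ax)
    ax.scatter(fit.tau, fit.be, s=25, c="k", label="observed")
    grid = np.linspace(max(1e-3, fit.tau.min()), fit.tau.max(), 200)
    ax.plot(grid, fit.amplitude * grid**fit.exponent, "r-",
            label=f"{fit.amplitude:.3g}·τ^{fit.exponent:.3g}")
    ax.set_xlabel("pGSI (τ)")
    ax.set_ylabel("bE")
    ax.legend(fontsize=8)
    return ax
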