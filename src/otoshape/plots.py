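"""Figure helpers: mean shapes, per-angle coefficient variation, ordination
clusters and reconstruction-quality curves.  All functions draw on a
matplotlib Axes and return it, so they compose with user figures; the CLI
saves them to PNG/SVG with the Agg backend."""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .reconstruction import ReconstructionCurve, find_threshold_level  # noqa: E402
from .stats import CapResult  # noqa: E402


def plot_mean_shapes(
    shapes: dict[str, np.ndarray], ax=None, show_angle: bool = True, **line_kw
):
    """Overlay per-group mean outlines with the polar-angle annotations."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    for group, pts in shapes.items():
        closed = np.vstack([pts, pts[:1]])
        ax.plot(closed[:, 0], closed[:, 1], label=str(group), **line_kw)
    if show_angle:
        rmax = max(np.abs(p).max() for p in shapes.values())
        ax.axhline(0.0, color="0.7", lw=0.8)
        ax.axvline(0.0, color="0.7", lw=0.8)
        for ang, (ha, va) in zip(
            (0, 90, 180, 270),
            (("left", "center"), ("center", "bottom"), ("right", "center"), ("center", "top")),
        ):
            r = 1.12 * rmax
            ax.text(r * np.cos(np.radians(ang)), r * np.sin(np.radians(ang)),
                    f"{ang}\N{DEGREE SIGN}", ha=ha, va=va)
    ax.set_aspect("equal")
    ax.legend()
    ax.set_axis_off()
    return ax


def plot_angle_variance(icc_table: pd.DataFrame, ax=None, band: str = "sd"):
    """Coefficient mean +/- band against angle, with the ICC curve."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    ang = icc_table["angle"].to_numpy()
    mean = icc_table["mean"].to_numpy()
    half = icc_table[band].to_numpy()
    ax.errorbar(ang, mean, yerr=half, fmt="o", ms=3, lw=1, capsize=2,
                color="0.4", label=f"coefficient mean ± {band}")
    ax2 = ax.twinx()
    ax2.plot(ang, icc_table["icc"], "k-", label="ICC")
    ax2.set_ylabel("ICC (among-group variance proportion)")
    ax2.set_ylim(0, 1)
    ax.set_xlabel("angle (\N{DEGREE SIGN})")
    ax.set_ylabel("wavelet coefficient")
    ax.legend(loc="upper left")
    return ax


def plot_cluster(cap_result: CapResult, classes, cluster_data: pd.DataFrame, ax=None):
    """CAP ordination: individual fish as small letters, group means +/- 1 SE."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    classes = np.asarray(classes)
    scores = cap_result.site_scores
    for group in cap_result.groups:
        sel = scores[classes == group]
        ax.scatter(sel[:, 0], sel[:, 1], s=12, alpha=0.5, label=str(group))
    for _, row in cluster_data.iterrows():
        ax.errorbar(row["mean1"], row["mean2"], xerr=row["se1"], yerr=row["se2"],
                    fmt="none", ecolor="k", capsize=3, lw=1.5)
        ax.annotate(str(row["group"]), (row["mean1"], row["mean2"]),
                    fontsize=12, fontweight="bold", ha="center", va="center")
    labels = cluster_data.attrs.get("axis_labels", ["CAP1", "CAP2"])
    ax.set_xlabel(labels[0])
    if len(labels) > 1:
        ax.set_ylabel(labels[1])
    ax.legend(loc="best", fontsize=8)
    return ax


def plot_reconstruction(
    curves: tuple[ReconstructionCurve, ReconstructionCurve],
    target_pct: float | None = 98.5,
    axes=None,
):
    """Accuracy-vs-resolution panels; a red line marks the target level."""
    if axes is None:
        _, axes = plt.subplots(1, 2, figsize=(10, 4))
    for ax, curve, xlabel in zip(
        axes, curves, ("wavelet level", "number of Fourier harmonics")
    ):
        ax.plot(curve.x, curve.accuracy, "o-", ms=4)
        if target_pct is not None:
            hit = find_threshold_level(curve, target_pct)
            if hit is not None:
                ax.axvline(hit, color="red", lw=1)
            ax.axhline(target_pct, color="red", lw=0.6, ls=":")
        ax.set_xlabel(xlabel)
        ax.set_ylabel("reconstruction accuracy (%)")
        ax.set_title(curve.method)
    return axes
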