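"""Overlay and corridor figures (SVG/PNG via matplotlib).

Colour semantics follow the field convention: red/pink for the anteriorly
angulated tunnels (borders/central), dark/light blue for the posteriorly
angulated tunnels, green for the center-center orientation.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

COLORS = {
    "anterior_border": "#c62828",  # red
    "anterior_central": "#f48fb1",  # pink
    "posterior_border": "#1a237e",  # dark blue
    "posterior_central": "#81d4fa",  # light blue
    "center_center": "#2e7d32",  # green
}


def _plot_section(ax, cs, alpha=0.25, lw=0.8, color="0.4"):
    closed = np.vstack([cs.fibula_contour, cs.fibula_contour[:1]])
    ax.plot(closed[:, 0], closed[:, 1], color=color, alpha=alpha, lw=lw)
    if cs.tibia_contour is not None:
        tib = np.vstack([cs.tibia_contour, cs.tibia_contour[:1]])
        ax.plot(tib[:, 0], tib[:, 1], color=color, alpha=alpha * 0.6, lw=lw)


def _plot_solution(ax, cs, sols, alpha=0.35):
    for orientation, keys in (
        ("anterior_angulated", ("anterior_border", "anterior_central")),
        ("posterior_angulated", ("posterior_border", "posterior_central")),
    ):
        sol = sols.get(orientation)
        if sol is None or not sol.feasible:
            continue
        anchor = (
            cs.landmarks.anterior_anchor
            if orientation == "anterior_angulated"
            else cs.landmarks.posterior_anchor
        )
        for border in (sol.anterior_border, sol.posterior_border):
            if border is not None:
                seg = np.vstack([anchor, border.exit_point])
                ax.plot(seg[:, 0], seg[:, 1], color=COLORS[keys[0]], alpha=alpha, lw=0.7)
        if sol.central is not None:
            seg = np.vstack([anchor, sol.central.exit_point])
            ax.plot(seg[:, 0], seg[:, 1], color=COLORS[keys[1]], alpha=alpha, lw=0.9)
    cc = sols.get("center_center")
    if cc is not None and cc.feasible and cc.central is not None:
        seg = np.vstack([cs.landmarks.tibial_center, cc.central.exit_point])
        ax.plot(seg[:, 0], seg[:, 1], color=COLORS["center_center"], alpha=alpha, lw=0.9)


def overlay_figure(path, raw, transformed, solutions_raw, solutions_reg, reference_cs=None):
    """Pre-/post-registration panels of contours, landmarks and tunnels."""
    fig, axes = plt.subplots(1, 2, figsize=(10, 5), sharex=True, sharey=True)
    for ax, cohort, sols, title in (
        (axes[0], raw, solutions_raw, "before registration"),
        (axes[1], transformed, solutions_reg, "after registration"),
    ):
        for cs in cohort:
            _plot_section(ax, cs)
            sol = sols.get(cs.subject_id)
            if sol:
                _plot_solution(ax, cs, sol)
            ax.plot(*cs.landmarks.apex_array().T, "k.", ms=2, alpha=0.4)
        if reference_cs is not None and title.startswith("after"):
            _plot_section(ax, reference_cs, alpha=1.0, lw=1.5, color="k")
        ax.set_title(title)
        ax.set_aspect("equal")
        ax.set_xlabel("anterior (mm)")
    axes[0].set_ylabel("lateral (mm)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def corridor_figure(path, reference_cs, report):
    """Corridors drawn on a reference fibula outline.

    Each corridor is shown as a thick arc along the lateral cortex between
    its signed-percent bounds.
    """
    from .geometry import lateral_cortex_paths

    fig, ax = plt.subplots(figsize=(6, 6))
    _plot_section(ax, reference_cs, alpha=1.0, lw=1.2, color="k")
    anterior, posterior = lateral_cortex_paths(reference_cs)

    def arc_points(lo, hi, n=40):
        pts = []
        for v in np.linspace(lo, hi, n):
            if v >= 0:
                p = anterior.line.interpolate(v / 100.0 * anterior.length)
            else:
                p = posterior.line.interpolate(-v / 100.0 * posterior.length)
            pts.append([p.x, p.y])
        return np.array(pts)

    offsets = {"anterior_angulated": 0.8, "posterior_angulated": 1.6, "center_center": 2.4}
    colors = {
        "anterior_angulated": COLORS["anterior_border"],
        "posterior_angulated": COLORS["posterior_border"],
        "center_center": COLORS["center_center"],
    }
    for orientation, corr in report.corridors.items():
        if corr.empty:
            continue
        pts = arc_points(corr.lower, corr.upper)
        # push the band outward from the section centroid for visibility
        centroid = reference_cs.fibula_contour.mean(axis=0)
        d = pts - centroid
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        pts_off = pts + offsets[orientation] * d
        ax.plot(
            pts_off[:, 0],
            pts_off[:, 1],
            color=colors[orientation],
            lw=4,
            solid_capstyle="round",
            label=f"{orientation}: [{corr.lower:.0f}%, {corr.upper:.0f}%]",
        )
    ax.legend(loc="lower left", fontsize=8)
    ax.set_aspect("equal")
    ax.set_xlabel("anterior (mm)")
    ax.set_ylabel("lateral (mm)")
    ax.set_title("cohort safe corridors on the lateral fibular cortex")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
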