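"""Finite-diameter drill-tunnel simulation on a fibular cross-section.

Three device orientations are simulated.  The anteriorly and posteriorly
angulated orientations each pivot about a fixed medial tibial anchor
(points 1 and 4); the single degree of freedom is the axis angle.  For a
drill of diameter *d* the feasible angles form an interval whose endpoints
are reached when the strip of width *d* becomes tangent to the anterior
(7) or posterior (8) cortical apex.  The *extreme borders* are the
lateral-cortex exits of those two limiting axes; the *central* (ideal)
axis runs from the anchor through the midpoint M of the apex-to-apex
chord.  The center-center orientation is a single fixed axis through the
midpoint of the two anchors (point 10) and the midpoint of the apexes
(point 11).

For convex sections the limiting angles are solved in closed form (the
tangent lines from the anchor to the circle of radius d/2 around each
apex); non-convex sections fall back to an angular sweep with bisection
refinement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import InfeasibleTunnelError, NoLateralExitError, LocationOffCortexError
from .geometry import (
    CrossSection,
    ExitLocation,
    TunnelAxis,
    TunnelSpec,
    axis_entry_is_medial as _entry_is_medial,
    intersect_axis_with_lateral_cortex,
    signed_location,
    strip_within_fibula,
)

__all__ = [
    "TunnelSolution",
    "CentralResult",
    "exit_location",
    "extreme_tunnels",
    "ideal_tunnel",
    "center_center_axis",
    "solve_subject",
]

ORIENTATIONS = ("anterior_angulated", "posterior_angulated", "center_center")

#: Angular resolution (deg) of the bisection refinement for non-convex sweeps.
SWEEP_REFINE_DEG = 1e-4
SWEEP_STEP_DEG = 0.25


@dataclass
class CentralResult:
    location: Optional[ExitLocation]
    axis: Optional[TunnelAxis]
    feasible: bool
    note: str = ""


@dataclass
class TunnelSolution:
    """Per-subject result for one drill-tunnel orientation."""

    orientation: str
    diameter: float
    feasible: bool
    anterior_border: Optional[ExitLocation] = None
    posterior_border: Optional[ExitLocation] = None
    central: Optional[ExitLocation] = None
    central_feasible: bool = True
    axes: dict = field(default_factory=dict)
    note: str = ""

    @property
    def interval(self) -> Optional[tuple[float, float]]:
        """Feasible exit interval as (posterior value, anterior value)."""
        if self.anterior_border is None or self.posterior_border is None:
            return None
        return (self.posterior_border.value, self.anterior_border.value)


def exit_location(
    cs: CrossSection, axis: TunnelAxis, normalization: str = "arc"
) -> ExitLocation:
    """Signed lateral-cortex exit of an axis."""
    p = intersect_axis_with_lateral_cortex(cs, axis)
    return signed_location(cs, p, tol=1e-6, normalization=normalization)


def _tangent_candidates(
    cs: CrossSection, anchor: np.ndarray, r: float
) -> list[tuple[TunnelAxis, Optional[np.ndarray]]]:
    """Axes through the anchor tangent to the apex circles of radius r.

    Returns (axis, apex) pairs; for r = 0 the axis runs exactly through
    the apex (built from the two points, avoiding a trig round-trip that
    would put a grazing line on the wrong side of the vertex).
    """
    out: list[tuple[TunnelAxis, Optional[np.ndarray]]] = []
    for which in ("anterior", "posterior"):
        apex = cs.apex(which)
        v = apex - anchor
        L = float(np.linalg.norm(v))
        if L <= r:
            continue  # anchor inside the apex clearance circle
        if r == 0.0:
            out.append((TunnelAxis.from_points(anchor, apex), apex))
            continue
        base = math.atan2(v[1], v[0])
        delta = math.asin(r / L)
        out.append((TunnelAxis.from_angle(anchor, base + delta), None))
        out.append((TunnelAxis.from_angle(anchor, base - delta), None))
    return out


def _feasible(cs, anchor, phi, d, eps) -> bool:
    return strip_within_fibula(cs, TunnelAxis.from_angle(anchor, phi), d, eps=eps)


def _sweep_extreme(
    cs: CrossSection,
    anchor: np.ndarray,
    d: float,
    phi0: float,
    direction: int,
    eps: float,
) -> float:
    """Walk from a feasible angle until infeasible, then bisect the boundary."""
    step = math.radians(SWEEP_STEP_DEG) * direction
    lo = phi0
    hi = None
    for _ in range(int(2 * math.pi / abs(step)) + 1):
        cand = lo + step
        if _feasible(cs, anchor, cand, d, eps):
            lo = cand
        else:
            hi = cand
            break
    if hi is None:
        raise InfeasibleTunnelError("feasible set spans the full circle")
    tol = math.radians(SWEEP_REFINE_DEG)
    while abs(hi - lo) > tol:
        mid = 0.5 * (lo + hi)
        if _feasible(cs, anchor, mid, d, eps):
            lo = mid
        else:
            hi = mid
    return lo


def _seed_angle(cs: CrossSection, anchor: np.ndarray, d: float, eps: float) -> float:
    v = cs.apex("lateral") - anchor
    phi = math.atan2(v[1], v[0])
    if _feasible(cs, anchor, phi, d, eps):
        return phi
    for k in range(1, 721):
        for sgn in (1, -1):
            cand = phi + sgn * k * math.radians(0.5)
            if _feasible(cs, anchor, cand, d, eps):
                return cand
    raise InfeasibleTunnelError(
        f"{cs.subject_id}: no feasible axis for diameter {d} mm"
    )


def extreme_tunnels(
    cs: CrossSection,
    spec: TunnelSpec,
    eps: float = 1e-9,
    normalization: str = "arc",
) -> tuple[ExitLocation, ExitLocation, TunnelAxis, TunnelAxis]:
    """Most anterior and most posterior feasible tunnel exits.

    Returns ``(anterior_border, posterior_border, anterior_axis,
    posterior_axis)``.  The borders are the lateral-cortex exits of the two
    extreme axes for which the drill strip still fits without breaching
    the cortex at either apex (tangency counts as feasible).
    """
    anchor = spec.anchor
    d = spec.diameter
    results: list[tuple[TunnelAxis, ExitLocation]] = []
    if cs.is_convex():
        for axis, apex in _tangent_candidates(cs, anchor, 0.5 * d):
            if apex is not None:
                # zero-diameter limit: the axis runs exactly through the
                # apex.  When it also passes through the bone the exit is
                # the far crossing; when it merely grazes the vertex (a
                # tangent line, degenerate for exact intersection tests)
                # the apex itself is the limiting exit.
                try:
                    if strip_within_fibula(cs, axis, d, eps=max(eps, 1e-7)):
                        loc = exit_location(cs, axis, normalization)
                    else:
                        loc = signed_location(
                            cs, apex, tol=1e-6, normalization=normalization
                        )
                except (NoLateralExitError, LocationOffCortexError):
                    loc = signed_location(cs, apex, tol=1e-6, normalization=normalization)
                results.append((axis, loc))
                continue
            # finite diameter: inner tangency at an apex, tolerate float
            # noise at exact tangency
            if not strip_within_fibula(cs, axis, d, eps=max(eps, 1e-7)):
                continue
            try:
                loc = exit_location(cs, axis, normalization)
            except (NoLateralExitError, LocationOffCortexError):
                continue
            results.append((axis, loc))
    if not results:
        # non-convex contour, or no valid tangency: authoritative sweep
        phi0 = _seed_angle(cs, anchor, d, eps)
        for direction in (+1, -1):
            phi = _sweep_extreme(cs, anchor, d, phi0, direction, eps)
            axis = TunnelAxis.from_angle(anchor, phi)
            try:
                loc = exit_location(cs, axis, normalization)
            except (NoLateralExitError, LocationOffCortexError):
                continue
            results.append((axis, loc))
    if not results:
        raise InfeasibleTunnelError(
            f"{cs.subject_id}: no feasible tunnel of diameter {d} mm from {anchor}"
        )
    axes, locs = zip(*results)
    i_ant = int(np.argmax([l.value for l in locs]))
    i_post = int(np.argmin([l.value for l in locs]))
    if locs[i_ant].value < locs[i_post].value:
        raise InfeasibleTunnelError(f"{cs.subject_id}: inverted feasible interval")
    return (locs[i_ant], locs[i_post], axes[i_ant], axes[i_post])


def apex_chord_midpoint(cs: CrossSection) -> np.ndarray:
    """Point M: midpoint of the anteroposterior apex chord 7-8."""
    return 0.5 * (cs.apex("anterior") + cs.apex("posterior"))


def ideal_tunnel(
    cs: CrossSection,
    spec: TunnelSpec,
    eps: float = 1e-9,
    normalization: str = "arc",
    midpoint: str = "apex_chord",
) -> CentralResult:
    """Central (ideal) tunnel: anchor through the fibular-width bisector M.

    ``midpoint="apex_chord"`` takes M as the midpoint of the 7-8 chord
    (default); ``"axis_chord"`` refines M once to the midpoint of the
    polygon chord cut by the anchor->M line.  An infeasible central axis is
    flagged, not fatal.
    """
    m = apex_chord_midpoint(cs)
    if midpoint == "axis_chord":
        axis0 = TunnelAxis.from_points(spec.anchor, m)
        from shapely.geometry import LineString

        seg = LineString(
            [spec.anchor - 500 * axis0.direction, spec.anchor + 500 * axis0.direction]
        )
        chord = seg.intersection(cs.polygon)
        if not chord.is_empty and chord.geom_type == "LineString":
            c = np.asarray(chord.coords, dtype=float)
            m = 0.5 * (c[0] + c[-1])
    elif midpoint != "apex_chord":
        raise ValueError(f"unknown midpoint policy {midpoint!r}")
    if np.allclose(m, spec.anchor):
        return CentralResult(None, None, False, note="anchor coincides with M")
    axis = TunnelAxis.from_points(spec.anchor, m)
    try:
        loc = exit_location(cs, axis, normalization)
    except (NoLateralExitError, LocationOffCortexError):
        return CentralResult(None, axis, False, note="central axis misses lateral cortex")
    feasible = strip_within_fibula(cs, axis, spec.diameter, eps=max(eps, 1e-7))
    return CentralResult(loc, axis, feasible)


def center_center_axis(
    cs: CrossSection, normalization: str = "arc"
) -> tuple[ExitLocation, TunnelAxis]:
    """Center-center orientation: through points 10 and 11.

    Point 10 bisects the two tibial anchors; point 11 bisects the anterior
    and posterior apexes.  The axis through both is intersected with the
    lateral cortex and its signed location returned.
    """
    p10 = cs.landmarks.tibial_center
    p11 = cs.landmarks.fibular_center
    axis = TunnelAxis.from_points(p10, p11)
    loc = exit_location(cs, axis, normalization)
    return loc, axis


def solve_subject(
    cs: CrossSection,
    diameter: float = 3.5,
    eps: float = 1e-9,
    normalization: str = "arc",
) -> dict[str, TunnelSolution]:
    """All three orientations for one subject.

    Infeasibility in one orientation is recorded on its solution without
    aborting the others.
    """
    out: dict[str, TunnelSolution] = {}
    for orientation, anchor in (
        ("anterior_angulated", cs.landmarks.anterior_anchor),
        ("posterior_angulated", cs.landmarks.posterior_anchor),
    ):
        spec = TunnelSpec(anchor=anchor, diameter=diameter)
        try:
            ant, post, ax_ant, ax_post = extreme_tunnels(cs, spec, eps, normalization)
            central = ideal_tunnel(cs, spec, eps, normalization)
            out[orientation] = TunnelSolution(
                orientation=orientation,
                diameter=diameter,
                feasible=True,
                anterior_border=ant,
                posterior_border=post,
                central=central.location,
                central_feasible=central.feasible,
                axes={
                    "anterior": ax_ant,
                    "posterior": ax_post,
                    "central": central.axis,
                },
            )
        except InfeasibleTunnelError as exc:
            out[orientation] = TunnelSolution(
                orientation=orientation,
                diameter=diameter,
                feasible=False,
                note=str(exc),
            )
    try:
        loc, axis = center_center_axis(cs, normalization)
        out["center_center"] = TunnelSolution(
            orientation="center_center",
            diameter=diameter,
            feasible=True,
            central=loc,
            central_feasible=strip_within_fibula(
                cs, axis, diameter, eps=max(eps, 1e-7)
            ),
            axes={"central": axis},
        )
    except (NoLateralExitError, LocationOffCortexError) as exc:
        out["center_center"] = TunnelSolution(
            orientation="center_center",
            diameter=diameter,
            feasible=False,
            note=str(exc),
        )
    return out
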