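"""Planar cross-section model of the distal fibula.

All analysis happens in a canonical right-sided frame: +x points anterior,
+y points lateral, units are millimetres.  A subject's axial slice is a
simple closed polygon (the fibular cortex outline), a set of named
landmarks, and optional slice-height metadata.  Landmark numbering follows
the field convention for syndesmotic drill-tunnel planning:

* point 1 — anteromedial tibial anchor (landing zone of the anteriorly
  angulated device),
* point 4 — posteromedial tibial anchor,
* points 7/8/9 — anterior / posterior / lateral cortical apexes of the
  fibula,
* point 10 — midpoint of the two tibial anchors (derived),
* point 11 — midpoint of the anterior and posterior apexes (derived).

The lateral cortex decomposes into an anterior edge (lateral apex 9 to
anterior apex 7) and a posterior edge (9 to 8).  Exit points of drill axes
are reported as *signed normalized locations*: percent of the respective
edge's arc length from the lateral apex, positive on the anterior edge and
negative on the posterior edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional

import numpy as np
from shapely.geometry import LineString, Point, Polygon
from shapely.ops import substring

from .errors import (
    DegenerateContourError,
    LandmarkMismatchError,
    LocationOffCortexError,
    NoLateralExitError,
)

__all__ = [
    "SNAP_TOL_MM",
    "GEOM_EPS",
    "LandmarkSet",
    "CrossSection",
    "TunnelSpec",
    "TunnelAxis",
    "ExitLocation",
    "CortexPath",
    "as_point",
    "mirror_x",
    "ensure_ccw",
    "polyline_length",
    "lateral_cortex_paths",
    "medial_path",
    "signed_location",
    "intersect_axis_with_lateral_cortex",
    "strip_within_fibula",
    "point_axis_distance",
]

#: Default tolerance (mm) for snapping annotated apexes onto the contour.
#: Chosen as ~5 sd of the default manual-annotation jitter (0.3 mm).
SNAP_TOL_MM = 1.5

#: Geometric tolerance for intersection / tangency tests (mm).
GEOM_EPS = 1e-9

Side = Literal["left", "right"]
ShapeClass = Literal["triangular_convex", "triangular", "quadrilateral", "irregular"]


def as_point(p: Iterable[float]) -> np.ndarray:
    """Coerce to a finite (2,) float array."""
    a = np.asarray(p, dtype=float).reshape(2)
    if not np.all(np.isfinite(a)):
        raise ValueError(f"non-finite coordinates: {a}")
    return a


def mirror_x(points: np.ndarray) -> np.ndarray:
    """Mirror about the y-axis (left/right side canonicalization)."""
    out = np.array(points, dtype=float, copy=True)
    out[..., 0] *= -1.0
    return out


def ensure_ccw(contour: np.ndarray) -> np.ndarray:
    """Return the contour with counter-clockwise vertex order."""
    ring = Polygon(contour)
    if not ring.exterior.is_ccw:
        return contour[::-1].copy()
    return contour


def polyline_length(points: np.ndarray) -> float:
    return float(np.sum(np.linalg.norm(np.diff(points, axis=0), axis=1)))


@dataclass
class LandmarkSet:
    """Named landmarks of one axial slice (annotated positions, mm).

    Anchors are tibial-side points outside the fibula; apexes lie on (or,
    if annotated with jitter, near) the fibular contour.  ``tibial_center``
    (point 10) and ``fibular_center`` (point 11) are derived midpoints and
    are filled in by :class:`CrossSection` when absent.
    """

    anterior_anchor: np.ndarray  # point 1
    posterior_anchor: np.ndarray  # point 4
    anterior_apex: np.ndarray  # point 7
    posterior_apex: np.ndarray  # point 8
    lateral_apex: np.ndarray  # point 9
    tibial_center: Optional[np.ndarray] = None  # point 10
    fibular_center: Optional[np.ndarray] = None  # point 11

    def __post_init__(self) -> None:
        for name in (
            "anterior_anchor",
            "posterior_anchor",
            "anterior_apex",
            "posterior_apex",
            "lateral_apex",
        ):
            setattr(self, name, as_point(getattr(self, name)))
        for name in ("tibial_center", "fibular_center"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, as_point(v))

    def apex_array(self) -> np.ndarray:
        """Apexes 7, 8, 9 stacked as a (3, 2) array (annotated positions)."""
        return np.vstack(
            [self.anterior_apex, self.posterior_apex, self.lateral_apex]
        )

    def transformed(self, fn) -> "LandmarkSet":
        """Apply a point-wise coordinate map to every landmark."""
        def t(v):
            return None if v is None else as_point(fn(v.reshape(1, 2)).reshape(2))

        return LandmarkSet(
            anterior_anchor=t(self.anterior_anchor),
            posterior_anchor=t(self.posterior_anchor),
            anterior_apex=t(self.anterior_apex),
            posterior_apex=t(self.posterior_apex),
            lateral_apex=t(self.lateral_apex),
            tibial_center=t(self.tibial_center),
            fibular_center=t(self.fibular_center),
        )


@dataclass
class TunnelSpec:
    """A drill tunnel: fixed medial anchor point plus finite diameter (mm)."""

    anchor: np.ndarray
    diameter: float = 3.5

    def __post_init__(self) -> None:
        self.anchor = as_point(self.anchor)
        if not np.isfinite(self.diameter) or self.diameter < 0:
            raise ValueError(f"diameter must be >= 0, got {self.diameter}")


@dataclass
class TunnelAxis:
    """Oriented guide-wire line: passes through ``through`` along ``direction``."""

    through: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        self.through = as_point(self.through)
        d = np.asarray(self.direction, dtype=float).reshape(2)
        n = np.linalg.norm(d)
        if not np.isfinite(n) or n == 0.0:
            raise ValueError("axis direction must be a nonzero vector")
        self.direction = d / n

    @classmethod
    def from_points(cls, a, b) -> "TunnelAxis":
        a = as_point(a)
        b = as_point(b)
        return cls(through=a, direction=b - a)

    @classmethod
    def from_angle(cls, through, angle_rad: float) -> "TunnelAxis":
        return cls(
            through=through,
            direction=np.array([np.cos(angle_rad), np.sin(angle_rad)]),
        )

    @property
    def angle_deg(self) -> float:
        """Axis angle in degrees from the anteroposterior (+x) axis."""
        return float(np.degrees(np.arctan2(self.direction[1], self.direction[0])))


@dataclass
class ExitLocation:
    """Signed normalized exit position on the lateral fibular cortex.

    ``value`` is percent of the cortical edge arc length measured from the
    lateral apex: positive on the anterior edge, negative on the posterior
    edge, exactly 0 at the lateral apex itself.
    """

    value: float
    cortex: Literal["anterior", "posterior", "apex"]
    exit_point: np.ndarray

    def __post_init__(self) -> None:
        self.exit_point = as_point(self.exit_point)
        if not -100.0 <= self.value <= 100.0:
            raise ValueError(f"signed location out of range: {self.value}")
        if self.cortex == "anterior" and not self.value > 0:
            raise ValueError("anterior locations must be positive")
        if self.cortex == "posterior" and not self.value < 0:
            raise ValueError("posterior locations must be negative")
        if self.cortex == "apex" and self.value != 0.0:
            raise ValueError("apex location must be exactly 0")


@dataclass
class CortexPath:
    """One lateral cortical edge as an ordered polyline from the lateral apex."""

    points: np.ndarray  # (M, 2), points[0] == lateral apex
    line: LineString = field(repr=False)
    length: float = 0.0

    @classmethod
    def from_points(cls, points: np.ndarray) -> "CortexPath":
        line = LineString(points)
        return cls(points=points, line=line, length=float(line.length))


@dataclass
class CrossSection:
    """One subject's axial slice in the canonical right-sided frame.

    The fibular contour is stored counter-clockwise without a repeated
    closing vertex.  Annotated apexes are snapped onto the contour at
    construction (tolerance ``snap_tol`` mm); geometric operations use the
    snapped copies while ``landmarks`` keeps the annotated positions for
    registration.
    """

    subject_id: str
    side: Side
    fibula_contour: np.ndarray
    landmarks: LandmarkSet
    tibia_contour: Optional[np.ndarray] = None
    shape_class: Optional[ShapeClass] = None
    height_from_plafond: Optional[float] = None  # Y, mm above the tibial plafond
    height_from_fibular_tip: Optional[float] = None  # X, mm above the fibular tip
    snap_tol: float = SNAP_TOL_MM

    # caches, filled in __post_init__
    _ring: LineString = field(init=False, repr=False)
    _perimeter: float = field(init=False, repr=False)
    _apex_params: dict = field(init=False, repr=False)
    _apexes_snapped: dict = field(init=False, repr=False)
    _paths: Optional[tuple] = field(init=False, default=None, repr=False)

    def __post_init__(self) -> None:
        contour = np.asarray(self.fibula_contour, dtype=float)
        if contour.ndim != 2 or contour.shape[1] != 2 or contour.shape[0] < 3:
            raise DegenerateContourError(
                f"{self.subject_id}: contour needs >= 3 (x, y) vertices"
            )
        if not np.all(np.isfinite(contour)):
            raise DegenerateContourError(f"{self.subject_id}: non-finite contour")
        # drop an explicit closing vertex
        if np.allclose(contour[0], contour[-1]):
            contour = contour[:-1]
        poly = Polygon(contour)
        if not poly.is_valid or poly.area <= 0:
            raise DegenerateContourError(
                f"{self.subject_id}: contour must be simple with positive area"
            )
        contour = ensure_ccw(contour)
        self.fibula_contour = contour
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        for h in (self.height_from_plafond, self.height_from_fibular_tip):
            if h is not None and h <= 0:
                raise ValueError(f"slice heights must be positive, got {h}")
        if self.tibia_contour is not None:
            self.tibia_contour = np.asarray(self.tibia_contour, dtype=float)

        closed = np.vstack([contour, contour[:1]])
        self._ring = LineString(closed)
        self._perimeter = float(self._ring.length)
        if self._perimeter <= 0:
            raise DegenerateContourError(f"{self.subject_id}: zero perimeter")

        self._apex_params = {}
        self._apexes_snapped = {}
        for name, p in (
            ("anterior", self.landmarks.anterior_apex),
            ("posterior", self.landmarks.posterior_apex),
            ("lateral", self.landmarks.lateral_apex),
        ):
            s = float(self._ring.project(Point(p)))
            q = self._ring.interpolate(s)
            snapped = np.array([q.x, q.y])
            dist = float(np.linalg.norm(snapped - p))
            if dist > self.snap_tol:
                raise LandmarkMismatchError(
                    f"{self.subject_id}: {name} apex is {dist:.3f} mm off the "
                    f"contour (snap tolerance {self.snap_tol} mm)"
                )
            self._apex_params[name] = s % self._perimeter
            self._apexes_snapped[name] = snapped

        params = self._apex_params
        if (
            min(
                abs(params["anterior"] - params["posterior"]),
                abs(params["anterior"] - params["lateral"]),
                abs(params["posterior"] - params["lateral"]),
            )
            < GEOM_EPS
        ):
            raise LandmarkMismatchError(
                f"{self.subject_id}: apexes must be pairwise distinct on the contour"
            )

        for name, anchor in (
            ("anterior", self.landmarks.anterior_anchor),
            ("posterior", self.landmarks.posterior_anchor),
        ):
            if poly.buffer(-GEOM_EPS).contains(Point(anchor)):
                raise LandmarkMismatchError(
                    f"{self.subject_id}: {name} anchor lies inside the fibula"
                )

        if self.landmarks.tibial_center is None:
            self.landmarks.tibial_center = 0.5 * (
                self.landmarks.anterior_anchor + self.landmarks.posterior_anchor
            )
        if self.landmarks.fibular_center is None:
            self.landmarks.fibular_center = 0.5 * (
                self._apexes_snapped["anterior"] + self._apexes_snapped["posterior"]
            )

    # -- geometry accessors -------------------------------------------------

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.fibula_contour)

    @property
    def perimeter(self) -> float:
        return self._perimeter

    def apex(self, which: Literal["anterior", "posterior", "lateral"]) -> np.ndarray:
        """Snapped (on-contour) apex coordinates."""
        return self._apexes_snapped[which].copy()

    def is_convex(self, rel_tol: float = 1e-9) -> bool:
        poly = self.polygon
        return poly.area >= poly.convex_hull.area * (1.0 - rel_tol)

    def _arc_substring(self, s0: float, s1: float) -> np.ndarray:
        """Vertices of the contour arc from parameter s0 forward (CCW) to s1."""
        P = self._perimeter
        s0 %= P
        s1 %= P
        if s1 >= s0:
            seg = substring(self._ring, s0, s1)
            return np.asarray(seg.coords, dtype=float)
        a = np.asarray(substring(self._ring, s0, P).coords, dtype=float)
        b = np.asarray(substring(self._ring, 0.0, s1).coords, dtype=float)
        return np.vstack([a, b[1:]])

    def _forward_arc_contains(self, s: float, a: float, b: float) -> bool:
        """True if parameter s lies on the forward (CCW) arc from a to b."""
        P = self._perimeter
        return ((s - a) % P) < ((b - a) % P)


# -- operations -------------------------------------------------------------


def lateral_cortex_paths(cs: CrossSection) -> tuple[CortexPath, CortexPath]:
    """Split the lateral cortex into its anterior and posterior edges.

    Returns ``(anterior_path, posterior_path)``: ordered polylines running
    along the contour from the lateral apex (9) to the anterior apex (7)
    and to the posterior apex (8).  Each is the contour arc between the
    two apexes that does not pass through the third apex.
    """
    if cs._paths is not None:
        return cs._paths
    s7 = cs._apex_params["anterior"]
    s8 = cs._apex_params["posterior"]
    s9 = cs._apex_params["lateral"]

    def arc_avoiding(start: float, stop: float, avoid: float) -> np.ndarray:
        if not cs._forward_arc_contains(avoid, start, stop):
            return cs._arc_substring(start, stop)
        # take the other way around, reversed so the path starts at `start`
        return cs._arc_substring(stop, start)[::-1]

    ant_pts = arc_avoiding(s9, s7, s8)
    post_pts = arc_avoiding(s9, s8, s7)
    anterior = CortexPath.from_points(ant_pts)
    posterior = CortexPath.from_points(post_pts)
    if anterior.length <= 0 or posterior.length <= 0:
        raise DegenerateContourError(
            f"{cs.subject_id}: zero-length lateral cortical edge"
        )
    cs._paths = (anterior, posterior)
    return cs._paths


def medial_path(cs: CrossSection) -> np.ndarray:
    """The medial contour arc from apex 7 to apex 8 (not through apex 9)."""
    s7 = cs._apex_params["anterior"]
    s8 = cs._apex_params["posterior"]
    s9 = cs._apex_params["lateral"]
    if not cs._forward_arc_contains(s9, s7, s8):
        return cs._arc_substring(s7, s8)
    return cs._arc_substring(s8, s7)[::-1]


def _medial_line(cs: CrossSection) -> LineString:
    line = getattr(cs, "_medial_line_cache", None)
    if line is None:
        line = LineString(medial_path(cs))
        cs._medial_line_cache = line
    return line


def signed_location(
    cs: CrossSection, p, tol: float = 1e-6, normalization: str = "arc"
) -> ExitLocation:
    """Signed normalized location of a lateral-cortex point.

    ``normalization="arc"`` (default) divides by the arc length of the
    cortical edge; ``"chord"`` divides by the straight apex-to-apex chord
    while still measuring position by arc length (values may then exceed
    the nominal +/-100 range and are clipped).
    """
    p = as_point(p)
    anterior, posterior = lateral_cortex_paths(cs)
    pt = Point(p)
    d_ant = anterior.line.distance(pt)
    d_post = posterior.line.distance(pt)
    if min(d_ant, d_post) > tol:
        raise LocationOffCortexError(
            f"{cs.subject_id}: point {p} is {min(d_ant, d_post):.4g} mm off "
            f"both lateral cortical edges (tol {tol})"
        )
    path, sign, cortex = (
        (anterior, 1.0, "anterior")
        if d_ant <= d_post
        else (posterior, -1.0, "posterior")
    )
    s = float(path.line.project(pt))
    # snap exact endpoints so apex locations are bit-exact 0 / +-100
    endpoint_tol = 1e-7 * max(1.0, path.length)
    if s < endpoint_tol:
        s = 0.0
    elif abs(s - path.length) < endpoint_tol:
        s = path.length
    if normalization == "arc":
        denom = path.length
    elif normalization == "chord":
        denom = float(np.linalg.norm(path.points[-1] - path.points[0]))
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    frac = s / denom
    value = float(np.clip(sign * 100.0 * frac, -100.0, 100.0))
    q = path.line.interpolate(s)
    if value == 0.0:
        return ExitLocation(value=0.0, cortex="apex", exit_point=np.array([q.x, q.y]))
    return ExitLocation(value=value, cortex=cortex, exit_point=np.array([q.x, q.y]))


def _axis_segment(cs: CrossSection, axis: TunnelAxis) -> LineString:
    """A finite segment long enough to stand in for the infinite axis line."""
    span = cs.perimeter + float(
        np.linalg.norm(axis.through - cs.fibula_contour.mean(axis=0))
    )
    reach = 4.0 * span + 10.0
    a = axis.through - reach * axis.direction
    b = axis.through + reach * axis.direction
    return LineString([a, b])


def _collect_points(geom) -> list[np.ndarray]:
    if geom.is_empty:
        return []
    gt = geom.geom_type
    if gt == "Point":
        return [np.array([geom.x, geom.y])]
    if gt in ("MultiPoint", "GeometryCollection"):
        out = []
        for g in geom.geoms:
            out.extend(_collect_points(g))
        return out
    if gt in ("LineString", "LinearRing"):
        c = np.asarray(geom.coords, dtype=float)
        return [c[0], c[-1]]
    if gt == "MultiLineString":
        out = []
        for g in geom.geoms:
            out.extend(_collect_points(g))
        return out
    raise TypeError(f"unexpected intersection geometry {gt}")


def intersect_axis_with_lateral_cortex(cs: CrossSection, axis: TunnelAxis) -> np.ndarray:
    """Exit point of an axis on the lateral cortex.

    If the axis crosses the lateral cortex more than once the crossing
    farthest from the anchor is returned — the drill exits the far cortex.
    """
    seg = _axis_segment(cs, axis)
    anterior, posterior = lateral_cortex_paths(cs)
    candidates: list[np.ndarray] = []
    for path in (anterior, posterior):
        candidates.extend(_collect_points(seg.intersection(path.line)))
    if not candidates:
        raise NoLateralExitError(
            f"{cs.subject_id}: axis through {axis.through} misses the lateral cortex"
        )
    dists = [float(np.linalg.norm(c - axis.through)) for c in candidates]
    return candidates[int(np.argmax(dists))]


def point_axis_distance(axis: TunnelAxis, p) -> float:
    """Perpendicular distance from a point to the (infinite) axis line."""
    p = as_point(p)
    w = p - axis.through
    return float(abs(axis.direction[0] * w[1] - axis.direction[1] * w[0]))


def axis_entry_is_medial(cs: CrossSection, axis: TunnelAxis, tol: float = 1e-7) -> bool:
    """True if the axis crossing nearest the anchor lies on the medial 7-8 arc.

    The drill runs from the lateral cortex through the fibula toward the
    tibial landing zone, so the bone crossing on the anchor side must be
    the medial face (an apex counts: it bounds the medial arc).
    """
    seg = _axis_segment(cs, axis)
    crossings = _collect_points(seg.intersection(cs._ring))
    if not crossings:
        return False
    nearest = min(crossings, key=lambda c: float(np.linalg.norm(c - axis.through)))
    return _medial_line(cs).distance(Point(nearest)) <= tol


def strip_within_fibula(
    cs: CrossSection, axis: TunnelAxis, d: float, eps: float = GEOM_EPS
) -> bool:
    """Can a drill of diameter ``d`` run along ``axis`` without cortical breach?

    The drill hole is modelled as the strip of width ``d`` centred on the
    axis.  The tunnel is safe iff

    1. the axis crosses the bone entering through the medial face — the
       boundary crossing nearest the anchor lies on the medial 7-8 arc
       (the drill must pass toward the tibial landing zone),
    2. the axis exits through the lateral cortex, and
    3. neither the anterior (7) nor the posterior (8) cortical apex lies
       inside the open strip — no part of the hole emerges from bone
       anterior to apex 7 or posterior to apex 8.

    Tangency (apex exactly on the strip boundary, or entry exactly at an
    apex) counts as safe.  Returns False on degenerate input.
    """
    if not np.isfinite(d) or d < 0:
        return False
    if not axis_entry_is_medial(cs, axis):
        return False  # drill would enter/exit through a lateral cortical edge
    try:
        intersect_axis_with_lateral_cortex(cs, axis)
    except NoLateralExitError:
        return False
    r = 0.5 * d
    for which in ("anterior", "posterior"):
        if point_axis_distance(axis, cs.apex(which)) < r - eps:
            return False
    return True
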