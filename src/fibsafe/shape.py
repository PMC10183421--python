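"""Cross-sectional shape classification and lateral aspect ratio.

The distal fibula at the level of syndesmotic stabilization is classified
into four morphologies: *triangular convex* (three cortical apexes with a
medially convex hypotenuse facing the tibial incisura), *triangular*
(straight medial edge), *quadrilateral* (four dominant corners), and
*irregular* (everything else — round, pentagonal, or wavy outlines).

Because visual classification criteria are not quantitative, the rules
here are a declared operationalization: a "corner" is a contour vertex
whose integrated turning angle over a 2 mm arc window exceeds 35 degrees,
and edge straightness / medial convexity are judged by maximal
perpendicular deviation from the apex-to-apex chord (thresholds are
configurable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DetectionFailureError
from .geometry import CrossSection, lateral_cortex_paths, medial_path

__all__ = [
    "Corner",
    "ShapeReport",
    "dominant_corners",
    "detect_apexes",
    "classify_shape",
    "aspect_ratio",
]

CORNER_TURN_DEG = 35.0
CORNER_WINDOW_MM = 2.0
MEDIAL_STRAIGHT_FRAC = 0.04
LATERAL_STRAIGHT_FRAC = 0.04


@dataclass
class Corner:
    index: int
    point: np.ndarray
    turn_deg: float  # integrated turning angle over the window


@dataclass
class ShapeReport:
    subject_id: str
    shape_class: str
    aspect_ratio: float
    anterolateral_mm: float
    posterolateral_mm: float


def _turning_angles(contour: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Signed exterior angle at each vertex of a closed CCW polyline (deg)."""
    d = np.roll(contour, -1, axis=0) - contour  # edge i: vertex i -> i+1
    ang = np.arctan2(d[:, 1], d[:, 0])
    turn = np.roll(ang, -1) - ang  # turn at vertex i+1
    turn = (turn + np.pi) % (2 * np.pi) - np.pi
    turn = np.roll(turn, 1)  # align: turn[i] is the turn at vertex i
    seg_len = np.linalg.norm(d, axis=1)
    return np.degrees(turn), seg_len


def dominant_corners(
    contour: np.ndarray,
    threshold_deg: float = CORNER_TURN_DEG,
    window_mm: float = CORNER_WINDOW_MM,
) -> list[Corner]:
    """Convex corners: windowed turning angle above the threshold.

    The signed turning of all vertices within ``window_mm/2`` arc length of
    a vertex is summed; clusters of super-threshold vertices are merged
    (the sharpest vertex represents each cluster).
    """
    turn, seg_len = _turning_angles(contour)
    n = len(contour)
    # arc distance between vertex i and j walking forward
    half = window_mm / 2.0
    windowed = np.empty(n)
    for i in range(n):
        total = turn[i]
        # forward
        acc = 0.0
        j = i
        while True:
            acc += seg_len[j]
            j = (j + 1) % n
            if acc > half or j == i:
                break
            total += turn[j]
        # backward
        acc = 0.0
        j = i
        while True:
            j = (j - 1) % n
            acc += seg_len[j]
            if acc > half or j == i:
                break
            total += turn[j]
        windowed[i] = total
    hot = windowed > threshold_deg
    if not np.any(hot):
        return []
    # merge consecutive hot vertices into clusters, but only when they are
    # within the arc window of each other (hot vertices a long edge apart
    # are distinct corners)
    idx = np.flatnonzero(hot)
    clusters = [[idx[0]]]
    for k in idx[1:]:
        last = clusters[-1][-1]
        if k == last + 1 and seg_len[last] <= window_mm:
            clusters[-1].append(k)
        else:
            clusters.append([k])
    if (
        len(clusters) > 1
        and clusters[0][0] == 0
        and clusters[-1][-1] == n - 1
        and seg_len[n - 1] <= window_mm
    ):
        clusters[0] = clusters.pop() + clusters[0]
    corners = []
    for cl in clusters:
        best = max(cl, key=lambda i: windowed[i])
        corners.append(Corner(index=best, point=contour[best].copy(), turn_deg=float(windowed[best])))
    return corners


def detect_apexes(
    contour: np.ndarray,
    threshold_deg: float = CORNER_TURN_DEG,
    window_mm: float = CORNER_WINDOW_MM,
) -> dict:
    """Automatic apex proposal for unlandmarked contours (canonical frame).

    The lateral apex is the contour point of maximal lateral (+y)
    coordinate; the anterior and posterior apexes are the corner vertices
    of maximal / minimal anterior (+x) coordinate, ties broken by larger
    turning angle.  Raises :class:`DetectionFailureError` when fewer than
    three corners exist (e.g. a circle) — supply landmarks instead.
    """
    contour = np.asarray(contour, dtype=float)
    corners = dominant_corners(contour, threshold_deg, window_mm)
    if len(corners) < 3:
        raise DetectionFailureError(
            f"only {len(corners)} corner(s) detected; landmarks required"
        )
    lateral = contour[int(np.argmax(contour[:, 1]))].copy()
    by_x = sorted(corners, key=lambda c: (c.point[0], c.turn_deg))
    anterior = by_x[-1].point
    posterior = by_x[0].point
    return {"anterior": anterior, "posterior": posterior, "lateral": lateral}


def _chord_deviations(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Signed perpendicular deviations of a polyline from its end chord.

    Positive sign is to the left of the chord direction.
    """
    p0, p1 = points[0], points[-1]
    chord = p1 - p0
    L = np.linalg.norm(chord)
    if L == 0:
        return np.zeros(len(points)), 0.0
    n = np.array([-chord[1], chord[0]]) / L
    dev = (points - p0) @ n
    return dev, float(L)


def _trim_ends(points: np.ndarray, trim_mm: float) -> np.ndarray:
    """Drop points within ``trim_mm`` arc length of either end.

    Annotated apexes jittered along the cortex shift the path split by a
    fraction of a millimetre, folding a stub of the neighbouring edge into
    the path; trimming the ends keeps the straightness tests about the
    edge itself.  Falls back to the full polyline when too short.
    """
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total <= 3 * trim_mm:
        return points
    keep = (cum >= trim_mm) & (cum <= total - trim_mm)
    if keep.sum() < 3:
        return points
    return points[keep]


def classify_shape(
    cs: CrossSection,
    threshold_deg: float = CORNER_TURN_DEG,
    window_mm: float = CORNER_WINDOW_MM,
    medial_straight_frac: float = MEDIAL_STRAIGHT_FRAC,
    lateral_straight_frac: float = LATERAL_STRAIGHT_FRAC,
) -> str:
    """Rule-based shape label from corner count and edge geometry.

    * 3 corners, straight lateral edges, straight medial edge -> triangular
    * 3 corners, straight lateral edges, medially convex medial edge
      -> triangular_convex
    * 4 corners, all straight edges -> quadrilateral
    * anything else -> irregular
    """
    corners = dominant_corners(cs.fibula_contour, threshold_deg, window_mm)
    ncorners = len(corners)

    anterior, posterior = lateral_cortex_paths(cs)
    lateral_straight = True
    for path in (anterior, posterior):
        dev, chord = _chord_deviations(_trim_ends(path.points, window_mm))
        if chord == 0 or np.max(np.abs(dev)) > lateral_straight_frac * chord:
            lateral_straight = False

    med = _trim_ends(medial_path(cs), window_mm)
    dev, chord = _chord_deviations(med)
    if chord == 0:
        return "irregular"
    # orient deviations so positive = away from the lateral apex (medially out)
    apex_dev, _ = _chord_deviations(
        np.vstack([med[0], cs.apex("lateral"), med[-1]])
    )
    apex_side = np.sign(apex_dev[1]) or 1.0
    dev = -apex_side * dev
    medial_straight = np.max(np.abs(dev)) < medial_straight_frac * chord
    # the inflection allowance (2.5% of the chord) absorbs the path-split
    # shift caused by annotation jitter on the apexes without admitting
    # genuinely wavy medial edges
    medial_convex = (
        np.max(dev) >= medial_straight_frac * chord
        and np.min(dev) >= -0.025 * chord
    )

    if ncorners == 3 and lateral_straight:
        if medial_straight:
            return "triangular"
        if medial_convex:
            return "triangular_convex"
        return "irregular"
    if ncorners == 4 and medial_straight:
        # all four edges between consecutive corners must be straight
        idxs = sorted(c.index for c in corners)
        contour = cs.fibula_contour
        n = len(contour)
        for a, b in zip(idxs, idxs[1:] + [idxs[0] + n]):
            seg = contour[np.arange(a, b + 1) % n]
            d, c = _chord_deviations(seg)
            if c > 0 and np.max(np.abs(d)) > lateral_straight_frac * c:
                return "irregular"
        return "quadrilateral"
    return "irregular"


def aspect_ratio(cs: CrossSection, normalization: str = "arc") -> ShapeReport:
    """Lateral aspect ratio: anterolateral / posterolateral edge length.

    ``normalization="arc"`` uses arc length along the cortex (default);
    ``"chord"`` uses the straight apex-to-apex chords.
    """
    anterior, posterior = lateral_cortex_paths(cs)
    if normalization == "arc":
        ant, post = anterior.length, posterior.length
    elif normalization == "chord":
        ant = float(np.linalg.norm(anterior.points[-1] - anterior.points[0]))
        post = float(np.linalg.norm(posterior.points[-1] - posterior.points[0]))
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    label = cs.shape_class or classify_shape(cs)
    return ShapeReport(
        subject_id=cs.subject_id,
        shape_class=label,
        aspect_ratio=ant / post,
        anterolateral_mm=ant,
        posterolateral_mm=post,
    )
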