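"""Landmark-based Procrustes superimposition onto a reference section.

Each subject is registered to a reference by the direct (non-reflecting)
2-D similarity transform — rotation, uniform scale, translation —
minimizing the sum of squared distances between the three fibular apex
landmarks (anterior, posterior, lateral).  Registration quality is the
mean distance of the transformed apexes to the reference apexes.
Reflection is excluded because left-sided inputs are mirrored into the
canonical right-sided frame at ingest.

Signed percent locations on the lateral cortex are ratios of arc lengths
and therefore invariant under these transforms; registration serves
pooled visual overlay and quality control, not the corridor numbers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateConfigurationError, FibsafeError
from .geometry import CrossSection

__all__ = [
    "SimilarityTransform",
    "RegistrationResult",
    "procrustes_align",
    "apply_to_subject",
    "register_cohort",
]


@dataclass
class SimilarityTransform:
    """Direct planar similarity: x -> scale * R(rotation) x + translation."""

    rotation: float  # radians
    scale: float
    translation: np.ndarray  # (2,)
    reflected: bool = False  # kept for completeness; always False here

    def __post_init__(self) -> None:
        self.translation = np.asarray(self.translation, dtype=float).reshape(2)
        if not self.scale > 0:
            raise ValueError(f"scale must be > 0, got {self.scale}")
        if self.reflected:
            raise ValueError("reflections are excluded; canonicalize sides at ingest")

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls(rotation=0.0, scale=1.0, translation=np.zeros(2))

    @property
    def matrix(self) -> np.ndarray:
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        return self.scale * np.array([[c, -s], [s, c]])

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.matrix.T + self.translation

    def inverse(self) -> "SimilarityTransform":
        inv_rot = -self.rotation
        inv_scale = 1.0 / self.scale
        c, s = np.cos(inv_rot), np.sin(inv_rot)
        m = inv_scale * np.array([[c, -s], [s, c]])
        return SimilarityTransform(
            rotation=inv_rot, scale=inv_scale, translation=-(m @ self.translation)
        )


@dataclass
class RegistrationResult:
    subject_id: str
    transform: SimilarityTransform
    mean_distance_error: float  # mm, after transformation
    per_landmark_residuals: np.ndarray  # (3,) mm, order: anterior, posterior, lateral


def procrustes_align(
    source: np.ndarray,
    reference: np.ndarray,
    allow_scaling: bool = True,
    subject_id: str = "",
) -> RegistrationResult:
    """Least-squares direct similarity fit of matched landmark sets.

    ``source`` and ``reference`` are (n, 2) arrays of matched landmarks
    (n >= 3, non-collinear).  With ``allow_scaling=False`` a rigid
    (rotation + translation) fit is computed instead.
    """
    X = np.asarray(source, dtype=float)
    Y = np.asarray(reference, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 2 or X.shape[0] < 3:
        raise ValueError("source and reference must be matching (n, 2) arrays with n >= 3")
    z = X[:, 0] + 1j * X[:, 1]
    w = Y[:, 0] + 1j * Y[:, 1]
    zc = z - z.mean()
    wc = w - w.mean()
    denom = float(np.sum(np.abs(zc) ** 2))
    size = float(np.sqrt(np.sum(np.abs(wc) ** 2)))
    if denom < 1e-20 or _collinear(X) or _collinear(Y):
        raise DegenerateConfigurationError(
            f"{subject_id}: landmark configuration is degenerate (collinear)"
        )
    a = np.sum(wc * np.conj(zc)) / denom
    if not allow_scaling:
        a = a / np.abs(a)
    t = w.mean() - a * z.mean()
    fitted = a * z + t
    residuals = np.abs(fitted - w)
    transform = SimilarityTransform(
        rotation=float(np.angle(a)),
        scale=float(np.abs(a)),
        translation=np.array([t.real, t.imag]),
    )
    return RegistrationResult(
        subject_id=subject_id,
        transform=transform,
        mean_distance_error=float(residuals.mean()),
        per_landmark_residuals=residuals,
    )


def _collinear(pts: np.ndarray, tol: float = 1e-9) -> bool:
    p = pts - pts.mean(axis=0)
    sv = np.linalg.svd(p, compute_uv=False)
    scale = sv[0] if sv[0] > 0 else 1.0
    return bool(sv[-1] / scale < tol)


def apply_to_subject(cs: CrossSection, t: SimilarityTransform) -> CrossSection:
    """Transform every coordinate of a subject consistently.

    Contours and all landmarks move under the similarity; signed percent
    locations are unchanged by construction (arc-length ratios).
    """
    lm = cs.landmarks.transformed(t.apply)
    return CrossSection(
        subject_id=cs.subject_id,
        side=cs.side,
        fibula_contour=t.apply(cs.fibula_contour),
        landmarks=lm,
        tibia_contour=None if cs.tibia_contour is None else t.apply(cs.tibia_contour),
        shape_class=cs.shape_class,
        height_from_plafond=cs.height_from_plafond,
        height_from_fibular_tip=cs.height_from_fibular_tip,
        snap_tol=max(cs.snap_tol, cs.snap_tol * t.scale),
    )


def _landmark_triple(cs: CrossSection) -> np.ndarray:
    """Annotated apex coordinates (7, 8, 9) used for registration."""
    return cs.landmarks.apex_array()


def register_cohort(
    cohort: list[CrossSection],
    reference_policy: str = "mean",
    allow_scaling: bool = True,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> tuple[list[RegistrationResult], np.ndarray, list[CrossSection]]:
    """Register every subject onto a reference.

    ``reference_policy``: ``"first"`` (first subject's landmarks),
    ``"id:<subject_id>"`` (a named subject, the single-reference-image
    convention), or ``"mean"`` (iterated mean shape, i.e. generalized
    Procrustes; the converged mean is rescaled to the cohort's mean
    centroid size so errors stay in mm).

    Returns per-subject results, the reference landmark array (3, 2), and
    the transformed subjects for pooled overlay.
    """
    if not cohort:
        raise FibsafeError("register_cohort requires at least one subject")
    triples = [_landmark_triple(cs) for cs in cohort]

    if reference_policy == "first":
        reference = triples[0].copy()
    elif reference_policy.startswith("id:"):
        sid = reference_policy[3:]
        matches = [t for cs, t in zip(cohort, triples) if cs.subject_id == sid]
        if not matches:
            raise FibsafeError(f"reference subject {sid!r} not in cohort")
        reference = matches[0].copy()
    elif reference_policy == "mean":
        reference = _mean_shape(triples, allow_scaling, max_iter, tol)
    else:
        raise ValueError(f"unknown reference policy {reference_policy!r}")

    results = []
    transformed = []
    for cs, triple in zip(cohort, triples):
        res = procrustes_align(triple, reference, allow_scaling, subject_id=cs.subject_id)
        results.append(res)
        transformed.append(apply_to_subject(cs, res.transform))
    return results, reference, transformed


def _centroid_size(pts: np.ndarray) -> float:
    return float(np.linalg.norm(pts - pts.mean(axis=0)))


def _mean_shape(triples, allow_scaling, max_iter, tol) -> np.ndarray:
    """Generalized Procrustes mean of the landmark configurations."""
    sizes = [_centroid_size(t) for t in triples]
    target_size = float(np.mean(sizes))
    ref = triples[0] - triples[0].mean(axis=0)
    ref = ref / _centroid_size(ref) * target_size
    for _ in range(max_iter):
        aligned = [
            procrustes_align(t, ref, allow_scaling).transform.apply(t) for t in triples
        ]
        new = np.mean(aligned, axis=0)
        new = new - new.mean(axis=0)
        size = _centroid_size(new)
        if size <= 0:
            raise DegenerateConfigurationError("mean shape collapsed")
        new = new / size * target_size
        delta = float(np.linalg.norm(new - ref)) / target_size
        ref = new
        if delta < tol:
            break
    return ref
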