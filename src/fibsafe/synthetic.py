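"""Synthetic cohorts of distal-fibula cross-sections.

The generator emulates the statistical structure a corridor analysis
consumes, so every downstream stage is testable without patient CT data:

* a shape-class mixture dominated by the triangular-convex morphology
  (lateral-based triangle whose medial edge bulges toward the tibial
  incisura), with quadrilateral, truly triangular, and irregular shapes
  as minority classes;
* a lateral aspect ratio (anterolateral / posterolateral edge length)
  drawn from a truncated normal, 1.0 +/- 0.2 within [0.7, 1.5] by default;
* tibial anchor points placed along the extension of the respective
  lateral cortical edge beyond its apex — the anteromedial anchor roughly
  in line with the anterolateral surface, the posteromedial anchor with
  the posterolateral surface — 10-25 mm medial of the fibula;
* slice heights for the simulated (contralateral) and operated sides
  correlated with a synthetic patient-height covariate;
* isotropic Gaussian jitter on landmark annotations, emulating manual
  marking, separate from the contour itself.

Every generated section is bit-reproducible given the seed and passes the
:class:`~fibsafe.geometry.CrossSection` invariants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps
from shapely.geometry import Point, Polygon

from .errors import ParameterError
from .geometry import CrossSection, LandmarkSet, as_point

__all__ = ["HeightParams", "CohortParams", "generate_cross_section", "generate_cohort"]

SHAPE_CLASSES = ("triangular_convex", "triangular", "quadrilateral", "irregular")


@dataclass
class HeightParams:
    """Slice-height and patient-height distribution parameters.

    ``yc``/``xc`` are the simulated-side tunnel heights above the tibial
    plafond / fibular tip; ``yi``/``xi`` the operated-side equivalents.
    Each is (mean, sd, low, high) in mm, truncated at low/high.
    ``r_contralateral``/``r_operated`` are the target Pearson correlations
    between patient height and the respective tunnel heights.
    """

    yc: tuple = (19.0, 3.0, 14.0, 25.0)
    xc: tuple = (44.0, 4.0, 34.0, 53.0)
    yi: tuple = (23.0, 6.0, 7.0, 48.0)
    xi: tuple = (48.0, 7.0, 32.0, 72.0)
    patient_height_cm: tuple = (172.0, 9.0)
    r_contralateral: float = 0.42
    r_operated: float = 0.15


@dataclass
class CohortParams:
    """Parameters of the synthetic cohort generator."""

    n_subjects: int = 96
    shape_mixture: dict = field(
        default_factory=lambda: {
            "triangular_convex": 0.81,
            "triangular": 0.01,
            "quadrilateral": 0.08,
            "irregular": 0.10,
        }
    )
    aspect_ratio_mean: float = 1.0
    aspect_ratio_sd: float = 0.2
    aspect_ratio_bounds: tuple = (0.7, 1.5)
    fibula_ap_width_mm: tuple = (25.0, 2.0)  # apex 7 to apex 8 distance
    fibula_depth_mm: tuple = (15.0, 1.5)  # chord-to-lateral-apex distance
    sagitta_frac: float = 0.15  # medial bulge depth as fraction of the 7-8 chord
    tunnel_diameter_mm: float = 3.5
    landmark_noise_sd_mm: float = 0.3
    anchor_distance_mm: tuple = (18.0, 4.0, 10.0, 25.0)  # mean, sd, low, high
    anchor_jitter_sd_mm: float = 1.5
    left_fraction: float = 0.54
    heights: HeightParams = field(default_factory=HeightParams)
    snap_tol_mm: float = 1.5
    include_tibia: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.heights, dict):
            self.heights = HeightParams(**self.heights)
        if self.n_subjects < 1:
            raise ParameterError("n_subjects must be >= 1")
        probs = [self.shape_mixture.get(c, 0.0) for c in SHAPE_CLASSES]
        if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ParameterError(
                f"shape_mixture must be non-negative and sum to 1, got {self.shape_mixture}"
            )
        lo, hi = self.aspect_ratio_bounds
        if not lo < hi:
            raise ParameterError("aspect_ratio_bounds must be (low, high) with low < high")
        if not lo <= self.aspect_ratio_mean <= hi:
            raise ParameterError("aspect_ratio_mean must lie within aspect_ratio_bounds")
        for name in ("aspect_ratio_sd", "landmark_noise_sd_mm", "anchor_jitter_sd_mm"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if not 0.0 <= self.left_fraction <= 1.0:
            raise ParameterError("left_fraction must be in [0, 1]")
        if self.tunnel_diameter_mm < 0:
            raise ParameterError("tunnel_diameter_mm must be >= 0")

    @property
    def mixture_probs(self) -> np.ndarray:
        return np.array([self.shape_mixture.get(c, 0.0) for c in SHAPE_CLASSES])

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortParams":
        return cls(**d)


# -- low-level draws --------------------------------------------------------


def _trunc_normal(rng, mean, sd, lo, hi):
    if sd == 0.0:
        if not lo <= mean <= hi:
            raise ParameterError("degenerate truncated normal outside its bounds")
        return float(mean)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(sps.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def _solve_lateral_apex_x(a: float, h: float, r: float) -> float:
    """Anterior coordinate of the lateral apex for target aspect ratio ``r``.

    With the anterior apex at (a, 0) and posterior apex at (-a, 0), solve
    |apex9 - apex7| / |apex9 - apex8| = r for apex9 = (x, h):
    (1 - r^2) x^2 - 2 a (1 + r^2) x + (1 - r^2)(a^2 + h^2) = 0.
    """
    c2 = 1.0 - r * r
    if abs(c2) < 1e-12:
        return 0.0
    c1 = -2.0 * a * (1.0 + r * r)
    c0 = c2 * (a * a + h * h)
    disc = c1 * c1 - 4.0 * c2 * c0
    roots = np.array([(-c1 - math.sqrt(disc)) / (2 * c2), (-c1 + math.sqrt(disc)) / (2 * c2)])
    inside = roots[np.abs(roots) < a]
    if inside.size == 0:
        raise ParameterError(f"no lateral apex position realizes aspect ratio {r}")
    return float(inside[np.argmin(np.abs(inside))])


def _subdivide(p, q, step=1.5):
    """Points from p to q (q excluded) at roughly ``step`` mm spacing."""
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    n = max(1, int(math.ceil(np.linalg.norm(q - p) / step)))
    t = np.arange(n) / n
    return p[None, :] * (1 - t[:, None]) + q[None, :] * t[:, None]


def _medial_arc(p7, p8, sagitta, step=1.0):
    """Circular arc from apex 8 to apex 7 bulging medially (toward -y).

    Apexes are assumed to sit at (+-a, 0); the returned points exclude both
    endpoints.
    """
    a = p7[0]
    chord = p7[0] - p8[0]
    if sagitta <= 0:
        return _subdivide(p8, p7, step)[1:]
    R = (chord * chord / 4.0 + sagitta * sagitta) / (2.0 * sagitta)
    cy = R - sagitta  # circle centre on the symmetry axis, above the bulge
    th8 = math.atan2(-cy, -a)
    th7 = math.atan2(-cy, a)
    if th8 > th7:
        th8 -= 2 * math.pi
    arc_len = R * (th7 - th8)
    n = max(4, int(math.ceil(arc_len / step)))
    th = np.linspace(th8, th7, n + 1)[1:-1]
    return np.column_stack([R * np.cos(th), cy + R * np.sin(th)])


def _contour_path_lengths(contour, i9, i7, i8):
    """Arc lengths from vertex i9 to i7 and to i8, each avoiding the third.

    Ground-truth computation on the generating polyline (closed, CCW),
    independent of the shapely-based measurement path.
    """
    n = len(contour)
    seg = np.linalg.norm(np.roll(contour, -1, axis=0) - contour, axis=1)

    def forward(i, j):  # arc length walking i -> j in index order
        if j >= i:
            return float(seg[i:j].sum())
        return float(seg[i:].sum() + seg[:j].sum())

    def between(i, j, avoid):
        fwd = forward(i, j)
        if _index_on_forward_arc(avoid, i, j, n):
            return float(seg.sum()) - fwd
        return fwd

    return between(i9, i7, i8), between(i9, i8, i7)


def _index_on_forward_arc(k, i, j, n):
    return ((k - i) % n) < ((j - i) % n)


# -- contour builders -------------------------------------------------------


def _build_triangular(rng, params: CohortParams, convex_medial: bool):
    a = 0.5 * _trunc_normal(rng, *params.fibula_ap_width_mm, *(params.fibula_ap_width_mm[0] + np.array([-3, 3]) * params.fibula_ap_width_mm[1]))
    h = _trunc_normal(rng, *params.fibula_depth_mm, *(params.fibula_depth_mm[0] + np.array([-3, 3]) * params.fibula_depth_mm[1]))
    r = _trunc_normal(
        rng,
        params.aspect_ratio_mean,
        params.aspect_ratio_sd,
        *params.aspect_ratio_bounds,
    )
    x9 = _solve_lateral_apex_x(a, h, r)
    v7 = np.array([a, 0.0])
    v8 = np.array([-a, 0.0])
    v9 = np.array([x9, h])
    pts = [v7, *_subdivide(v7, v9)[1:], v9, *_subdivide(v9, v8)[1:]]
    if convex_medial:
        sag = params.sagitta_frac * (2 * a)
        pts.extend([v8, *_medial_arc(v7, v8, sag)])
    else:
        pts.extend([v8, *_subdivide(v8, v7)[1:]])
    contour = np.array(pts)
    return contour, {"anterior": v7, "posterior": v8, "lateral": v9}, r


def _build_quadrilateral(rng, params: CohortParams):
    contour, apexes, _ = _build_triangular(rng, params, convex_medial=False)
    v7, v8, v9 = apexes["anterior"], apexes["posterior"], apexes["lateral"]
    for _ in range(50):
        f1, f2 = rng.uniform(0.18, 0.32, size=2)
        g1, g2 = rng.uniform(1.05, 1.14, size=2)
        l1 = v9 + f1 * (v7 - v9)
        l2 = v9 + f2 * (v8 - v9)
        l1[1] *= g1
        l2[1] *= g2
        if abs(l1[1] - l2[1]) > 0.15:
            break
    lateral = l1 if l1[1] > l2[1] else l2
    pts = [
        v7,
        *_subdivide(v7, l1)[1:],
        l1,
        *_subdivide(l1, l2)[1:],
        l2,
        *_subdivide(l2, v8)[1:],
        v8,
        *_subdivide(v8, v7)[1:],
    ]
    contour = np.array(pts)
    # ground-truth edge lengths from the construction
    if lateral is l1:
        ant = np.linalg.norm(l1 - v7)
        post = np.linalg.norm(l1 - l2) + np.linalg.norm(l2 - v8)
    else:
        ant = np.linalg.norm(l2 - l1) + np.linalg.norm(l1 - v7)
        post = np.linalg.norm(l2 - v8)
    return contour, {"anterior": v7, "posterior": v8, "lateral": lateral}, ant / post


def _build_pentagon(rng, params: CohortParams):
    a = 0.5 * _trunc_normal(rng, *params.fibula_ap_width_mm, *(params.fibula_ap_width_mm[0] + np.array([-3, 3]) * params.fibula_ap_width_mm[1]))
    h = _trunc_normal(rng, *params.fibula_depth_mm, *(params.fibula_depth_mm[0] + np.array([-3, 3]) * params.fibula_depth_mm[1]))
    v7 = np.array([a, 0.0])
    v8 = np.array([-a, 0.0])
    v9 = np.array([rng.uniform(-0.2, 0.2) * a, h * rng.uniform(1.0, 1.1)])
    pa = np.array([a * rng.uniform(0.52, 0.62), h * rng.uniform(0.62, 0.72)])
    pp = np.array([-a * rng.uniform(0.52, 0.62), h * rng.uniform(0.62, 0.72)])
    pts = [
        v7,
        *_subdivide(v7, pa)[1:],
        pa,
        *_subdivide(pa, v9)[1:],
        v9,
        *_subdivide(v9, pp)[1:],
        pp,
        *_subdivide(pp, v8)[1:],
        v8,
        *_subdivide(v8, v7)[1:],
    ]
    return np.array(pts), {"anterior": v7, "posterior": v8, "lateral": v9}


def _build_blob(rng, params: CohortParams):
    a = 0.45 * _trunc_normal(rng, *params.fibula_ap_width_mm, *(params.fibula_ap_width_mm[0] + np.array([-3, 3]) * params.fibula_ap_width_mm[1]))
    h = _trunc_normal(rng, *params.fibula_depth_mm, *(params.fibula_depth_mm[0] + np.array([-3, 3]) * params.fibula_depth_mm[1]))
    b = 0.55 * h
    cy = 0.5 * h
    phi = np.linspace(0.0, 2 * math.pi, 96, endpoint=False)
    wobble = 1.0 + 0.04 * np.cos(2 * phi + rng.uniform(0, 2 * math.pi)) + 0.03 * np.cos(
        3 * phi + rng.uniform(0, 2 * math.pi)
    )
    x = a * wobble * np.cos(phi)
    y = cy + b * wobble * np.sin(phi)
    contour = np.column_stack([x, y])
    apexes = {
        "anterior": contour[np.argmax(x)].copy(),
        "posterior": contour[np.argmin(x)].copy(),
        "lateral": contour[np.argmax(y)].copy(),
    }
    return contour, apexes


def _build_wavy_triangle(rng, params: CohortParams):
    for _ in range(50):
        contour, apexes, _ = _build_triangular(rng, params, convex_medial=False)
        centroid = np.array(Polygon(contour).centroid.coords[0])
        rel = contour - centroid
        theta = np.arctan2(rel[:, 1], rel[:, 0])
        scale = np.ones(len(contour))
        total_amp = rng.uniform(0.09, 0.14)
        ks = (3, 4, 5)
        amps = rng.dirichlet(np.ones(len(ks))) * total_amp
        for k, amp in zip(ks, amps):
            scale += amp * np.cos(k * theta + rng.uniform(0, 2 * math.pi))
        wavy = centroid + rel * scale[:, None]
        if not Polygon(wavy).is_valid:
            continue
        # apexes ride along with the radial map via their contour index
        new_apex = {}
        for name, p in apexes.items():
            idx = int(np.argmin(np.linalg.norm(contour - p, axis=1)))
            new_apex[name] = wavy[idx].copy()
        return wavy, new_apex
    raise ParameterError("could not generate a simple irregular contour")


def _build_irregular(rng, params: CohortParams):
    sub = rng.choice(["pentagon", "blob", "wavy"], p=[0.4, 0.3, 0.3])
    if sub == "pentagon":
        contour, apexes = _build_pentagon(rng, params)
    elif sub == "blob":
        contour, apexes = _build_blob(rng, params)
    else:
        contour, apexes = _build_wavy_triangle(rng, params)
    return contour, apexes, sub


# -- public API -------------------------------------------------------------


def generate_cross_section(
    params: CohortParams,
    shape_class: str,
    rng: np.random.Generator,
    subject_id: str = "S000",
    side: str = "right",
    heights: Optional[dict] = None,
) -> tuple[CrossSection, dict]:
    """Generate one cross-section of the requested shape class.

    Returns the :class:`CrossSection` (canonical right-sided frame) and a
    ground-truth record of the generating parameters.
    """
    if shape_class not in SHAPE_CLASSES:
        raise ParameterError(f"unknown shape class {shape_class!r}")

    subtype = shape_class
    if shape_class == "triangular_convex":
        contour, apexes, _ = _build_triangular(rng, params, convex_medial=True)
    elif shape_class == "triangular":
        contour, apexes, _ = _build_triangular(rng, params, convex_medial=False)
    elif shape_class == "quadrilateral":
        contour, apexes, _ = _build_quadrilateral(rng, params)
    else:
        contour, apexes, subtype = _build_irregular(rng, params)
        subtype = f"irregular:{subtype}"

    # ground-truth lateral edge lengths measured on the generating polyline
    idx = {
        k: int(np.argmin(np.linalg.norm(contour - p, axis=1)))
        for k, p in apexes.items()
    }
    ant_len, post_len = _contour_path_lengths(
        contour, idx["lateral"], idx["anterior"], idx["posterior"]
    )
    true_ratio = ant_len / post_len

    # anchors: along the extension of each lateral edge beyond its apex
    anchors = {}
    poly = Polygon(contour)
    for name, apex_key in (("anterior", "anterior"), ("posterior", "posterior")):
        apex = apexes[apex_key]
        u = apex - apexes["lateral"]
        u = u / np.linalg.norm(u)
        for _ in range(50):
            dist = _trunc_normal(rng, *params.anchor_distance_mm)
            jitter = rng.normal(0.0, params.anchor_jitter_sd_mm, size=2)
            cand = apex + dist * u + jitter
            if not poly.buffer(1.0).contains(Point(cand)) and cand[1] < apexes["lateral"][1]:
                anchors[name] = cand
                break
        else:
            raise ParameterError("could not place an anchor outside the fibula")

    # annotated landmarks: true positions plus isotropic marking jitter
    sd = params.landmark_noise_sd_mm
    noise = lambda: rng.normal(0.0, sd, size=2) if sd > 0 else np.zeros(2)
    lm = LandmarkSet(
        anterior_anchor=anchors["anterior"] + noise(),
        posterior_anchor=anchors["posterior"] + noise(),
        anterior_apex=apexes["anterior"] + noise(),
        posterior_apex=apexes["posterior"] + noise(),
        lateral_apex=apexes["lateral"] + noise(),
    )

    tibia = _tibia_outline(contour, apexes) if params.include_tibia else None
    heights = heights or {}
    cs = CrossSection(
        subject_id=subject_id,
        side=side,
        fibula_contour=contour,
        landmarks=lm,
        tibia_contour=tibia,
        shape_class=shape_class,
        height_from_plafond=heights.get("yc"),
        height_from_fibular_tip=heights.get("xc"),
        snap_tol=params.snap_tol_mm,
    )
    truth = {
        "subject_id": subject_id,
        "side": side,
        "shape_class": shape_class,
        "shape_subtype": subtype,
        "aspect_ratio_true": true_ratio,
        "anterolateral_mm_true": ant_len,
        "posterolateral_mm_true": post_len,
        "x7": apexes["anterior"][0],
        "y7": apexes["anterior"][1],
        "x8": apexes["posterior"][0],
        "y8": apexes["posterior"][1],
        "x9": apexes["lateral"][0],
        "y9": apexes["lateral"][1],
        "anchor1_x": anchors["anterior"][0],
        "anchor1_y": anchors["anterior"][1],
        "anchor4_x": anchors["posterior"][0],
        "anchor4_y": anchors["posterior"][1],
        "tunnel_diameter_mm": params.tunnel_diameter_mm,
    }
    return cs, truth


def _tibia_outline(contour, apexes):
    """A crude tibial outline whose incisura mirrors the fibular medial face."""
    v7, v8 = apexes["anterior"], apexes["posterior"]
    gap = 2.0
    medial_y = contour[:, 1].min()
    top = np.array(
        [
            [v7[0] + 4.0, v7[1] - gap],
            [0.0, medial_y - gap],
            [v8[0] - 4.0, v8[1] - gap],
        ]
    )
    base_y = medial_y - 32.0
    pts = np.vstack(
        [
            top,
            [[v8[0] - 10.0, base_y], [v7[0] + 10.0, base_y]],
        ]
    )
    return pts


def _correlated_height(rng, z_height, spec, rho):
    mean, sd, lo, hi = spec
    eps = rng.normal()
    z = rho * z_height + math.sqrt(max(0.0, 1.0 - rho * rho)) * eps
    return float(np.clip(mean + sd * z, lo, hi))


def generate_cohort(params: CohortParams) -> tuple[list[CrossSection], pd.DataFrame]:
    """Generate a cohort plus its ground-truth table.

    Shape classes are multinomial draws from the mixture, sides Bernoulli
    (``left_fraction``), and the simulated/operated slice heights share a
    latent patient-height covariate with the configured correlations.
    """
    rng = np.random.default_rng(params.seed)
    classes = rng.choice(len(SHAPE_CLASSES), size=params.n_subjects, p=params.mixture_probs)
    sides = np.where(rng.random(params.n_subjects) < params.left_fraction, "left", "right")
    sections: list[CrossSection] = []
    rows = []
    hp = params.heights
    for i in range(params.n_subjects):
        sid = f"S{i + 1:03d}"
        z = rng.normal()
        patient_height = hp.patient_height_cm[0] + hp.patient_height_cm[1] * z
        heights = {
            "yc": _correlated_height(rng, z, hp.yc, hp.r_contralateral),
            "xc": _correlated_height(rng, z, hp.xc, hp.r_contralateral),
            "yi": _correlated_height(rng, z, hp.yi, hp.r_operated),
            "xi": _correlated_height(rng, z, hp.xi, hp.r_operated),
        }
        cs, truth = generate_cross_section(
            params,
            SHAPE_CLASSES[classes[i]],
            rng,
            subject_id=sid,
            side=str(sides[i]),
            heights=heights,
        )
        truth.update(
            {
                "height_yc_mm": heights["yc"],
                "height_xc_mm": heights["xc"],
                "height_yi_mm": heights["yi"],
                "height_xi_mm": heights["xi"],
                "patient_height_cm": patient_height,
            }
        )
        sections.append(cs)
        rows.append(truth)
    truth_df = pd.DataFrame(rows).set_index("subject_id", drop=False)
    return sections, truth_df
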