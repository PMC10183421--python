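"""Reading and writing cross-section data.

On disk a subject consists of a contour JSON file and landmark rows in a
CSV table.  Files store *native-side* coordinates; left-sided subjects are
mirrored about the y-axis at ingest so all in-memory analysis happens in
the canonical right-sided frame (+x anterior, +y lateral, mm).

Formats
-------
Contour JSON::

    {"subject_id": "S001", "side": "left", "pixel_spacing_mm": 1.0,
     "fibula_contour": [[x, y], ...], "tibia_contour": [[x, y], ...]}

The fibula contour may alternatively be given as WKT ``POLYGON`` text
under the key ``"fibula_wkt"``.

Landmark CSV: columns ``subject_id, point_id, x, y`` with point ids
1 (anteromedial anchor), 4 (posteromedial anchor), 7/8/9 (anterior /
posterior / lateral apex).  An ImageJ-style multi-point measurement CSV
(columns ``X``, ``Y``, one row per click) is accepted given the row-order
mapping of point ids.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from shapely import wkt as shapely_wkt

from .errors import ParameterError
from .geometry import CrossSection, LandmarkSet, mirror_x, SNAP_TOL_MM

__all__ = [
    "POINT_IDS",
    "write_contour_json",
    "read_contour_json",
    "write_landmark_csv",
    "read_landmark_csv",
    "read_imagej_landmark_csv",
    "landmark_set_from_points",
    "load_cross_section",
    "write_cohort",
    "load_cohort",
]

#: point-id convention: 1/4 anchors, 7/8/9 apexes
POINT_IDS = {
    1: "anterior_anchor",
    4: "posterior_anchor",
    7: "anterior_apex",
    8: "posterior_apex",
    9: "lateral_apex",
}


def _to_native(points: np.ndarray, side: str) -> np.ndarray:
    return mirror_x(points) if side == "left" else np.asarray(points, dtype=float)


def write_contour_json(
    path,
    subject_id: str,
    side: str,
    fibula_contour: np.ndarray,
    tibia_contour: Optional[np.ndarray] = None,
    pixel_spacing_mm: float = 1.0,
) -> None:
    """Write a contour file (canonical-frame input; stored native-side)."""
    doc = {
        "subject_id": subject_id,
        "side": side,
        "pixel_spacing_mm": pixel_spacing_mm,
        "fibula_contour": (_to_native(fibula_contour, side) / pixel_spacing_mm).tolist(),
    }
    if tibia_contour is not None:
        doc["tibia_contour"] = (_to_native(tibia_contour, side) / pixel_spacing_mm).tolist()
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def read_contour_json(path) -> dict:
    """Read a contour file into canonical-frame arrays (mm)."""
    doc = json.loads(Path(path).read_text())
    side = doc.get("side", "right")
    spacing = float(doc.get("pixel_spacing_mm", 1.0))
    if "fibula_contour" in doc:
        fib = np.asarray(doc["fibula_contour"], dtype=float) * spacing
    elif "fibula_wkt" in doc:
        poly = shapely_wkt.loads(doc["fibula_wkt"])
        fib = np.asarray(poly.exterior.coords, dtype=float)[:-1] * spacing
    else:
        raise ParameterError(f"{path}: no fibula contour found")
    out = {
        "subject_id": doc.get("subject_id", Path(path).stem),
        "side": side,
        "fibula_contour": _to_native(fib, side),  # mirror back to canonical
    }
    if "tibia_contour" in doc:
        out["tibia_contour"] = _to_native(
            np.asarray(doc["tibia_contour"], dtype=float) * spacing, side
        )
    return out


def write_landmark_csv(path, rows: Sequence[dict]) -> None:
    """Write landmark rows: each {subject_id, side, landmarks: LandmarkSet}."""
    records = []
    for row in rows:
        lm: LandmarkSet = row["landmarks"]
        side = row.get("side", "right")
        for pid, attr in POINT_IDS.items():
            p = getattr(lm, attr)
            q = _to_native(p.reshape(1, 2), side).reshape(2)
            records.append(
                {
                    "subject_id": row["subject_id"],
                    "point_id": pid,
                    "x": q[0],
                    "y": q[1],
                }
            )
    pd.DataFrame(records).to_csv(path, index=False)


def read_landmark_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"subject_id", "point_id", "x", "y"}
    if not required.issubset(df.columns):
        raise ParameterError(f"{path}: landmark CSV needs columns {sorted(required)}")
    return df


def read_imagej_landmark_csv(path, row_order: Sequence[int], subject_id: str) -> pd.DataFrame:
    """Read an ImageJ multi-point measurement CSV.

    ImageJ exports one row per click with upper-case ``X``/``Y`` columns
    (plus an unnamed index).  ``row_order`` maps click order to point ids,
    e.g. ``[1, 4, 7, 8, 9]``.
    """
    df = pd.read_csv(path)
    cols = {c.strip().upper(): c for c in df.columns}
    if "X" not in cols or "Y" not in cols:
        raise ParameterError(f"{path}: ImageJ CSV needs X and Y columns")
    if len(df) != len(row_order):
        raise ParameterError(
            f"{path}: {len(df)} rows but row_order maps {len(row_order)} points"
        )
    return pd.DataFrame(
        {
            "subject_id": subject_id,
            "point_id": list(row_order),
            "x": df[cols["X"]].to_numpy(dtype=float),
            "y": df[cols["Y"]].to_numpy(dtype=float),
        }
    )


def landmark_set_from_points(points: dict[int, np.ndarray]) -> LandmarkSet:
    missing = [pid for pid in POINT_IDS if pid not in points]
    if missing:
        raise ParameterError(f"missing landmark point ids: {missing}")
    return LandmarkSet(
        **{attr: np.asarray(points[pid], dtype=float) for pid, attr in POINT_IDS.items()}
    )


def load_cross_section(
    contour_path,
    landmarks: pd.DataFrame,
    snap_tol: float = SNAP_TOL_MM,
    heights: Optional[dict] = None,
) -> CrossSection:
    """Assemble one subject from a contour file plus its landmark rows."""
    doc = read_contour_json(contour_path)
    side = doc["side"]
    sub = landmarks[landmarks["subject_id"] == doc["subject_id"]]
    pts = {}
    for _, r in sub.iterrows():
        p = np.array([r["x"], r["y"]], dtype=float)
        if side == "left":
            p = p * np.array([-1.0, 1.0])
        pts[int(r["point_id"])] = p
    lm = landmark_set_from_points(pts)
    heights = heights or {}
    return CrossSection(
        subject_id=doc["subject_id"],
        side=side,
        fibula_contour=doc["fibula_contour"],
        landmarks=lm,
        tibia_contour=doc.get("tibia_contour"),
        height_from_plafond=heights.get("yc"),
        height_from_fibular_tip=heights.get("xc"),
        snap_tol=snap_tol,
    )


def write_cohort(out_dir, sections, truth: Optional[pd.DataFrame] = None) -> None:
    """Write a cohort: one contour JSON per subject plus shared tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for cs in sections:
        write_contour_json(
            out / f"{cs.subject_id}_contour.json",
            cs.subject_id,
            cs.side,
            cs.fibula_contour,
            cs.tibia_contour,
        )
        rows.append({"subject_id": cs.subject_id, "side": cs.side, "landmarks": cs.landmarks})
    write_landmark_csv(out / "landmarks.csv", rows)
    meta = pd.DataFrame(
        [
            {
                "subject_id": cs.subject_id,
                "side": cs.side,
                "shape_class": cs.shape_class or "",
                "height_yc_mm": cs.height_from_plafond,
                "height_xc_mm": cs.height_from_fibular_tip,
            }
            for cs in sections
        ]
    )
    meta.to_csv(out / "subjects.csv", index=False)
    if truth is not None:
        truth.to_csv(out / "ground_truth.csv", index=False)


def load_cohort(in_dir, snap_tol: float = SNAP_TOL_MM) -> list[CrossSection]:
    """Load a cohort written by :func:`write_cohort` (or hand-assembled)."""
    src = Path(in_dir)
    landmarks = read_landmark_csv(src / "landmarks.csv")
    meta_path = src / "subjects.csv"
    heights: dict[str, dict] = {}
    if meta_path.exists():
        meta = pd.read_csv(meta_path)
        for _, r in meta.iterrows():
            heights[str(r["subject_id"])] = {
                "yc": None if pd.isna(r.get("height_yc_mm")) else float(r["height_yc_mm"]),
                "xc": None if pd.isna(r.get("height_xc_mm")) else float(r["height_xc_mm"]),
            }
    sections = []
    for path in sorted(src.glob("*_contour.json")):
        doc_id = json.loads(path.read_text()).get("subject_id", path.stem)
        cs = load_cross_section(
            path, landmarks, snap_tol=snap_tol, heights=heights.get(doc_id)
        )
        sections.append(cs)
    if not sections:
        raise ParameterError(f"no *_contour.json files under {src}")
    return sections
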