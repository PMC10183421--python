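"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written without the package's geometry
primitives (no shapely): plain segment arithmetic, cumulative-sum arc
lengths, and rasterized point containment, so the tests compare two
independent routes to the same quantities.
"""

from __future__ import annotations

import math

import numpy as np
from matplotlib.path import Path as MplPath
from scipy.optimize import least_squares


# -- segment / polyline primitives -----------------------------------------


def line_segment_intersections(p, d, polyline):
    """Intersections of the infinite line p + t*d with a polyline.

    Returns a list of (t, point) pairs, one per crossed segment.
    """
    p = np.asarray(p, float)
    d = np.asarray(d, float)
    out = []
    for a, b in zip(polyline[:-1], polyline[1:]):
        e = b - a
        denom = d[0] * e[1] - d[1] * e[0]
        if abs(denom) < 1e-14:
            continue
        w = a - p
        t = (w[0] * e[1] - w[1] * e[0]) / denom
        s = (w[0] * d[1] - w[1] * d[0]) / denom
        if -1e-12 <= s <= 1 + 1e-12:
            out.append((t, p + t * d))
    return out


def point_polyline_distance(q, polyline):
    q = np.asarray(q, float)
    best = np.inf
    for a, b in zip(polyline[:-1], polyline[1:]):
        e = b - a
        L2 = float(e @ e)
        t = 0.0 if L2 == 0 else float(np.clip((q - a) @ e / L2, 0.0, 1.0))
        best = min(best, float(np.linalg.norm(a + t * e - q)))
    return best


def arc_position(polyline, q, tol=1e-6):
    """Arc length from polyline[0] to the on-polyline point q (or None)."""
    q = np.asarray(q, float)
    acc = 0.0
    for a, b in zip(polyline[:-1], polyline[1:]):
        e = b - a
        L = float(np.linalg.norm(e))
        if L == 0:
            continue
        t = float(np.clip((q - a) @ e / (L * L), 0.0, 1.0))
        if np.linalg.norm(a + t * e - q) < tol:
            return acc + t * L
        acc += L
    return None


# -- paths reconstructed by index walking (generator ground truth) ----------


def contour_paths_by_index(contour, i9, i7, i8):
    """(anterior, posterior) polylines from apex 9, walking contour indices."""
    n = len(contour)

    def on_forward(k, i, j):
        return ((k - i) % n) < ((j - i) % n)

    def walk(i, j):
        idx = [i]
        k = i
        while k != j:
            k = (k + 1) % n
            idx.append(k)
        return contour[idx]

    def path(i, j, avoid):
        fwd = walk(i, j)
        if on_forward(avoid, i, j):
            return walk(j, i)[::-1]
        return fwd

    return path(i9, i7, i8), path(i9, i8, i7)


def signed_exit_value(anterior, posterior, q, tol=1e-6):
    """Signed percent location of q on the reconstructed lateral paths."""
    s = arc_position(anterior, q, tol)
    if s is not None:
        L = float(np.sum(np.linalg.norm(np.diff(anterior, axis=0), axis=1)))
        return 100.0 * s / L
    s = arc_position(posterior, q, tol)
    if s is not None:
        L = float(np.sum(np.linalg.norm(np.diff(posterior, axis=0), axis=1)))
        return -100.0 * s / L
    return None


# -- rasterized strip-feasibility oracle ------------------------------------


class RasterTunnelOracle:
    """Brute-force feasibility and extreme-angle finder for one section.

    A drill axis is feasible when sampling shows: the bone crossing nearest
    the anchor is on the medial face, the far crossing is on the lateral
    cortex, and no sampled point of the drill strip inside the bone extent
    lies outside the bone anterior to apex 7 / posterior to apex 8.
    """

    def __init__(self, contour, apex7, apex8, apex9, i7, i8, i9, step=0.05):
        self.contour = np.asarray(contour, float)
        closed = np.vstack([self.contour, self.contour[:1]])
        self.closed = closed
        self.path = MplPath(closed)
        self.apex7 = np.asarray(apex7, float)
        self.apex8 = np.asarray(apex8, float)
        self.apex9 = np.asarray(apex9, float)
        self.step = step
        ant, post = contour_paths_by_index(self.contour, i9, i7, i8)
        self.anterior = ant
        self.posterior = post
        # the 7 -> 8 arc avoiding 9 is the medial face
        self.medial = contour_paths_by_index(self.contour, i7, i8, i9)[0]

    def feasible(self, anchor, phi, d, corner="raster"):
        """Feasibility of one axis angle.

        ``corner="raster"`` detects a cortical breach by sampled strip
        points lying outside bone beyond an apex; ``corner="exact"``
        replaces only that corner event by the exact point-to-line
        clearance (a 0.05 mm raster cannot resolve the micron-deep breach
        sliver right at tangency), keeping the raster for entry/exit-face
        classification.
        """
        anchor = np.asarray(anchor, float)
        u = np.array([math.cos(phi), math.sin(phi)])
        nvec = np.array([-u[1], u[0]])
        span = float(np.max(np.linalg.norm(self.contour - anchor, axis=1))) + 5.0
        t = np.arange(0.0, span, self.step)
        center = anchor + t[:, None] * u
        inside = self.path.contains_points(center)
        if not inside.any():
            return False
        t_in = t[inside]
        u1, u2 = float(t_in.min()), float(t_in.max())
        entry = anchor + u1 * u
        exitp = anchor + u2 * u
        tol = 4 * self.step
        if point_polyline_distance(entry, self.medial) > tol:
            return False
        if min(
            point_polyline_distance(exitp, self.anterior),
            point_polyline_distance(exitp, self.posterior),
        ) > tol:
            return False
        if d <= 0:
            return True
        if corner == "exact":
            for apex in (self.apex7, self.apex8):
                w = apex - anchor
                if abs(u[0] * w[1] - u[1] * w[0]) < d / 2:
                    return False
            return True
        # raster corner test on the drill-hole extent (strip within the
        # bone-contact range of the axis, with margin for oblique exits)
        us = np.arange(max(0.0, u1 - 6.0), u2 + 6.0, self.step)
        vs = np.arange(-d / 2, d / 2 + self.step / 2, self.step)
        pts = (
            anchor[None, None, :]
            + us[:, None, None] * u[None, None, :]
            + vs[None, :, None] * nvec[None, None, :]
        ).reshape(-1, 2)
        inside_grid = self.path.contains_points(pts)
        grid = inside_grid.reshape(len(us), len(vs))
        rows = np.flatnonzero(grid.any(axis=1))
        if rows.size == 0:
            return False
        lo, hi = rows.min(), rows.max()
        hole = np.zeros_like(grid, dtype=bool)
        hole[lo : hi + 1, :] = True
        bad = hole.ravel() & ~inside_grid
        if bad.any():
            p = pts[bad]
            htol = self.step
            if np.any(p[:, 0] > self.apex7[0] + htol) or np.any(
                p[:, 0] < self.apex8[0] - htol
            ):
                return False
        return True

    def extreme_angle(self, anchor, d, direction, coarse_deg=0.5, corner="exact"):
        """Last feasible angle on a 0.01-degree lattice, rotating ``direction``.

        Walks from a feasible seed in coarse steps, then refines the
        feasibility boundary down to the 0.01-degree sweep lattice.
        """
        anchor = np.asarray(anchor, float)
        v = self.apex9 - anchor
        phi0 = math.atan2(v[1], v[0])
        if not self.feasible(anchor, phi0, d, corner):
            found = False
            for k in range(1, 180):
                for sgn in (1, -1):
                    cand = phi0 + sgn * math.radians(0.5) * k
                    if self.feasible(anchor, cand, d, corner):
                        phi0 = cand
                        found = True
                        break
                if found:
                    break
            if not found:
                return None
        step = math.radians(coarse_deg) * direction
        lo = phi0
        hi = None
        for _ in range(int(2 * math.pi / abs(step))):
            cand = lo + step
            if self.feasible(anchor, cand, d, corner):
                lo = cand
            else:
                hi = cand
                break
        if hi is None:
            return None
        for fine_deg in (0.1, 0.01):
            fine = math.radians(fine_deg) * direction
            while True:
                cand = lo + fine
                if (cand - hi) * direction >= 0 or not self.feasible(
                    anchor, cand, d, corner
                ):
                    break
                lo = cand
        return lo

    def exit_value(self, anchor, phi):
        u = np.array([math.cos(phi), math.sin(phi)])
        hits = []
        for poly in (self.anterior, self.posterior):
            hits.extend(line_segment_intersections(anchor, u, poly))
        if not hits:
            return None
        t, q = max(hits, key=lambda h: abs(h[0]))
        return signed_exit_value(self.anterior, self.posterior, q, tol=1e-6)


# -- independent similarity-fit oracle --------------------------------------


def lsq_similarity_fit(source, reference):
    """4-parameter (angle, log-scale, tx, ty) least-squares similarity fit.

    Numerical optimization, independent of the closed-form estimator.
    Returns the mean distance error at the optimum.
    """
    X = np.asarray(source, float)
    Y = np.asarray(reference, float)

    def resid(p):
        ang, logs, tx, ty = p
        c, s = math.cos(ang), math.sin(ang)
        R = math.exp(logs) * np.array([[c, -s], [s, c]])
        return (X @ R.T + [tx, ty] - Y).ravel()

    best = None
    for ang0 in (0.0, 2.0, -2.0):
        fit = least_squares(
            resid, x0=[ang0, 0.0, 0.0, 0.0], xtol=1e-15, ftol=1e-15, gtol=1e-15
        )
        if best is None or fit.cost < best.cost:
            best = fit
    errs = np.linalg.norm(best.fun.reshape(-1, 2), axis=1)
    return float(errs.mean()), best.x
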