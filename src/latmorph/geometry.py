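"""Planar geometry for the triangularity (Pareto) test.

The t-ratio compares the area of the convex hull of the embedded maps with
the area of the minimal-area triangle enclosing them.  The minimal
enclosing triangle is found exactly: a classical result (Klee & Laskowski;
O'Rourke et al.) guarantees that some side of an optimal triangle is flush
with a hull edge, and that for a fixed flush side each remaining side is,
at the optimum, either flush with a hull edge or touched by the hull at
its midpoint.  Both conditions yield closed-form candidates, which are
enumerated (vectorised) per flush edge; the smallest valid candidate is
the global optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError

_EPS = 1e-12


@dataclass
class TRatioResult:
    """Triangularity of a 2-D point cloud, optionally with its null test."""

    subspace: tuple[int, int]
    hull_area: float
    triangle_area: float
    triangle_vertices: np.ndarray = field(repr=False, default=None)  # 3 x 2
    t_ratio: float = np.nan
    null_t_ratios: np.ndarray | None = field(repr=False, default=None)
    p_value: float | None = None
    significant: bool | None = None


def _hull_vertices(points: np.ndarray) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 points in 2-D")
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise ValueError(f"degenerate (collinear or duplicate) input points: {exc}") from exc
    return pts[hull.vertices]  # counter-clockwise


def convex_hull_area(points: np.ndarray) -> float:
    """Area of the 2-D convex hull of a point set (shoelace on hull vertices)."""
    v = _hull_vertices(points)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def _min_triangle_for_base(rot: np.ndarray) -> tuple[float, np.ndarray] | None:
    """Minimal triangle with one side on the x-axis containing points ``rot``.

    ``rot`` are hull vertices in a frame where the flush edge lies on the
    x-axis and the hull is in ``y >= 0``.  Sides are parametrised by their
    "slope" ``t`` (the line ``x = a + t*y``); for slopes ``(t1, t2)`` the
    tightest supporting lines have ``a1 = min(x - t1*y)`` (left) and
    ``a2 = max(x - t2*y)`` (right), and the triangle area is
    ``(a2 - a1)^2 / (2*(t1 - t2))``.
    """
    x, y = rot[:, 0], rot[:, 1]
    scale = max(np.ptp(x), np.ptp(y), _EPS)
    eps = 1e-9 * scale

    nxt = np.roll(np.arange(len(rot)), -1)
    dy = y[nxt] - y
    with np.errstate(divide="ignore", invalid="ignore"):
        slopes = (x[nxt] - x) / dy
    T = slopes[np.abs(dy) > eps]  # flush-side candidates (non-parallel to base)
    if T.size == 0:
        return None
    up = y > eps  # vertices usable as midpoint contacts

    cand1: list[np.ndarray] = [np.repeat(T, T.size)]
    cand2: list[np.ndarray] = [np.tile(T, T.size)]
    if np.any(up):
        xv, yv = x[up], y[up]
        # side1 flush at t1, side2 midpoint-stationary at vertex v:
        #   t2 = 2*t1 - (xv - a1(t1)) / yv
        a1_T = np.min(x[None, :] - T[:, None] * y[None, :], axis=1)
        t2_stat = 2.0 * T[:, None] - (xv[None, :] - a1_T[:, None]) / yv[None, :]
        cand1.append(np.repeat(T, xv.size))
        cand2.append(t2_stat.ravel())
        # side2 flush at t2, side1 midpoint-stationary at vertex v:
        #   t1 = (a2(t2) - xv) / yv + 2*t2
        a2_T = np.max(x[None, :] - T[:, None] * y[None, :], axis=1)
        t1_stat = (a2_T[:, None] - xv[None, :]) / yv[None, :] + 2.0 * T[:, None]
        cand1.append(t1_stat.ravel())
        cand2.append(np.tile(T, xv.size))
    t1 = np.concatenate(cand1)
    t2 = np.concatenate(cand2)
    ok = np.isfinite(t1) & np.isfinite(t2) & (t1 - t2 > eps / scale)
    if not np.any(ok):
        return None
    t1, t2 = t1[ok], t2[ok]

    a1 = np.min(x[None, :] - t1[:, None] * y[None, :], axis=1)
    a2 = np.max(x[None, :] - t2[:, None] * y[None, :], axis=1)
    w0 = a2 - a1
    valid = w0 > eps
    if not np.any(valid):
        return None
    area = np.full(t1.shape, np.inf)
    area[valid] = 0.5 * w0[valid] ** 2 / (t1[valid] - t2[valid])
    i = int(np.argmin(area))
    if not np.isfinite(area[i]):
        return None
    yc = w0[i] / (t1[i] - t2[i])
    verts = np.array(
        [[a1[i], 0.0], [a2[i], 0.0], [a1[i] + t1[i] * yc, yc]]
    )
    return float(area[i]), verts


def min_enclosing_triangle(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Minimal-area triangle enclosing a 2-D point set.

    Returns ``(vertices, area)`` with ``vertices`` of shape (3, 2).  At
    least one triangle side is flush with a convex-hull edge; every hull
    point lies inside the triangle (up to rounding).
    """
    hull = _hull_vertices(points)
    h = len(hull)
    best_area = np.inf
    best_verts = None
    for i in range(h):
        p0, p1 = hull[i], hull[(i + 1) % h]
        edge = p1 - p0
        norm = np.hypot(*edge)
        if norm < _EPS:
            continue
        u = edge / norm
        nvec = np.array([-u[1], u[0]])  # inward normal for a CCW hull
        rel = hull - p0
        rot = np.column_stack([rel @ u, rel @ nvec])
        rot[:, 1] = np.maximum(rot[:, 1], 0.0)  # clip rounding on the flush edge
        res = _min_triangle_for_base(rot)
        if res is None:
            continue
        area, verts = res
        if area < best_area:
            best_area = area
            best_verts = p0 + verts[:, :1] * u + verts[:, 1:] * nvec
    if best_verts is None:
        raise ValueError("could not construct an enclosing triangle (degenerate input)")
    return best_verts, float(best_area)


def t_ratio(points: np.ndarray, subspace: tuple[int, int] = (0, 1)) -> TRatioResult:
    """Hull area over minimal-enclosing-triangle area, in (0, 1]."""
    hull_area = convex_hull_area(points)
    verts, tri_area = min_enclosing_triangle(points)
    ratio = hull_area / tri_area
    return TRatioResult(
        subspace=tuple(subspace),
        hull_area=hull_area,
        triangle_area=tri_area,
        triangle_vertices=verts,
        t_ratio=min(float(ratio), 1.0),
    )
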