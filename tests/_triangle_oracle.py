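"""Brute-force oracle for the minimal enclosing triangle.

Independent of the package's candidate-enumeration algorithm: for every
convex-hull edge taken as the flush side, the areas of triangles formed by
two supporting lines are minimised numerically (Nelder-Mead from a grid of
slope starts), and flush-flush slope pairs are evaluated exhaustively.
Intended for small hulls only.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import ConvexHull


def _area_for_slopes(x, y, t1, t2):
    if t1 - t2 < 1e-9:
        return np.inf
    a1 = np.min(x - t1 * y)
    a2 = np.max(x - t2 * y)
    w = a2 - a1
    if w <= 0:
        return np.inf
    return 0.5 * w * w / (t1 - t2)


def min_triangle_area_oracle(points: np.ndarray) -> float:
    pts = np.asarray(points, dtype=float)
    hull = pts[ConvexHull(pts).vertices]
    h = len(hull)
    best = np.inf
    for i in range(h):
        p0, p1 = hull[i], hull[(i + 1) % h]
        e = p1 - p0
        u = e / np.hypot(*e)
        n = np.array([-u[1], u[0]])
        rel = hull - p0
        x = rel @ u
        y = np.maximum(rel @ n, 0.0)

        # flush-flush pairs
        nxt = np.roll(np.arange(h), -1)
        dy = y[nxt] - y
        with np.errstate(divide="ignore", invalid="ignore"):
            slopes = (x[nxt] - x) / dy
        slopes = slopes[np.isfinite(slopes)]
        for t1 in slopes:
            for t2 in slopes:
                best = min(best, _area_for_slopes(x, y, t1, t2))

        # numeric minimisation from a grid of starts
        fun = lambda t: _area_for_slopes(x, y, t[0], t[1])
        for s1 in np.linspace(-5, 5, 9):
            for s2 in np.linspace(-5, 5, 9):
                if s1 <= s2:
                    continue
                res = minimize(
                    fun, [s1, s2], method="Nelder-Mead",
                    options=dict(xatol=1e-12, fatol=1e-14, maxiter=3000),
                )
                best = min(best, res.fun)
    return float(best)
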