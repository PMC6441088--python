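"""Triangularity (Pareto-optimality) testing and archetype maps.

The embedded morphospace of lateralisation maps is tested for triangular
structure: the observed t-ratio (hull area over minimal-enclosing-triangle
area) in each 2-D subspace of the embedding is compared with t-ratios from
null map sets obtained by permuting the voxel order of each hemisphere map
before computing right-left differences.  Each null set is pushed through
the same machinery — PCA with the real data's retained-component count,
varimax, voxelwise GLM denoising, similarity, spectral embedding — so the
null preserves everything except the spatial alignment of the two
hemispheres.  Significance is Bonferroni-corrected over the tested
subspaces.

Archetype maps are reconstructed by regressing voxel values of the
denoised maps on the maps' embedding coordinates and evaluating the fit at
the vertices of the minimal enclosing triangle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from itertools import combinations

import numpy as np

from .components import fit_component_model
from .embedding import embed_li_matrix
from .geometry import TRatioResult, t_ratio

logger = logging.getLogger(__name__)

DEFAULT_DIM_PAIRS: tuple[tuple[int, int], ...] = tuple(combinations(range(5), 2))


@dataclass
class ArchetypeMap:
    """Predicted LI map at one vertex of the morphospace simplex."""

    vertex_coords: np.ndarray
    predicted_li: np.ndarray = field(repr=False, default=None)  # half-mask vector
    label: str = ""


def _tratios_of_li(
    li: np.ndarray,
    n_retained: int,
    dim_pairs: list[tuple[int, int]],
    n_dims: int,
    varimax_iter: int = 1000,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Run components -> denoise -> embed -> t-ratio per subspace.

    Returns (t-ratios per pair, embedding coords, denoised matrix).
    """
    model = fit_component_model(li, n_retained=n_retained, max_iter=varimax_iter)
    den, space = embed_li_matrix(li, model, n_dims=n_dims)
    ts = np.array([t_ratio(space.coords[:, pair]).t_ratio for pair in dim_pairs])
    return ts, space.coords, den


def t_ratio_null_test(
    left_matrix: np.ndarray,
    right_matrix: np.ndarray,
    n_retained: int,
    dim_pairs: list[tuple[int, int]] | None = None,
    n_sets: int = 2000,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
    n_dims: int | None = None,
    varimax_iter: int = 1000,
    max_resample: int = 50,
) -> list[TRatioResult]:
    """Voxel-permutation null test of morphospace triangularity.

    ``left_matrix`` and ``right_matrix`` are terms x half-voxels hemisphere
    matrices in homologous indexing (left already mirrored); their
    difference is the LI matrix.  Each null set permutes the voxel order of
    every hemisphere map independently before differencing, then reruns the
    embedding pipeline with the retained-component count fixed at
    ``n_retained``.  The permutation p-value per subspace is
    ``(1 + #{null t >= real t}) / (1 + n_sets)``; significance is assessed
    at ``alpha`` Bonferroni-corrected over the tested subspaces.  Null sets
    whose pipeline fails (e.g. a disconnected similarity graph) are logged
    and resampled.
    """
    if n_sets < 50:
        raise ValueError("n_sets must be at least 50")
    L = np.asarray(left_matrix, dtype=float)
    R = np.asarray(right_matrix, dtype=float)
    if L.shape != R.shape:
        raise ValueError("hemisphere matrices must have identical shapes")
    n_maps, n_vox = L.shape
    dim_pairs = list(DEFAULT_DIM_PAIRS if dim_pairs is None else map(tuple, dim_pairs))
    if n_dims is None:
        n_dims = max(max(p) for p in dim_pairs) + 1
    if n_dims >= n_maps:
        raise ValueError("embedding dimension too large for the number of maps")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    real_t, coords, den = _tratios_of_li(R - L, n_retained, dim_pairs, n_dims, varimax_iter)

    null_t = np.empty((n_sets, len(dim_pairs)))
    n_failed = 0
    i = 0
    while i < n_sets:
        Lp = np.take_along_axis(L, np.argsort(rng.random((n_maps, n_vox)), axis=1), axis=1)
        Rp = np.take_along_axis(R, np.argsort(rng.random((n_maps, n_vox)), axis=1), axis=1)
        try:
            null_t[i], _, _ = _tratios_of_li(
                Rp - Lp, n_retained, dim_pairs, n_dims, varimax_iter
            )
        except (ValueError, np.linalg.LinAlgError) as exc:
            n_failed += 1
            if n_failed > max_resample:
                raise RuntimeError(
                    f"more than {max_resample} null sets failed; last error: {exc}"
                ) from exc
            logger.warning("null set failed (%s); resampling", exc)
            continue
        i += 1
    if n_failed:
        logger.info("resampled %d failed null sets", n_failed)

    results = []
    n_tests = len(dim_pairs)
    for j, pair in enumerate(dim_pairs):
        geo = t_ratio(coords[:, pair], subspace=pair)
        p = (1.0 + np.sum(null_t[:, j] >= real_t[j])) / (1.0 + n_sets)
        results.append(
            replace(geo, null_t_ratios=null_t[:, j].copy(), p_value=float(p),
                    significant=bool(p <= alpha / n_tests))
        )
    return results


def archetype_maps(
    denoised: np.ndarray,
    coords: np.ndarray,
    vertices: np.ndarray,
    n_regress_dims: int | None = None,
    subspace: tuple[int, int] = (0, 1),
    labels: list[str] | None = None,
) -> list[ArchetypeMap]:
    """Reconstruct archetype LI maps at simplex vertices by regression.

    Voxel values across the denoised maps are regressed (OLS with
    intercept) on the maps' coordinates in the first ``n_regress_dims``
    embedding dimensions; the fit is evaluated at each vertex of the
    enclosing triangle, with coordinates outside the tested ``subspace``
    set to zero.  Vertices far outside the fitted coordinate range trigger
    an extrapolation warning.
    """
    den = np.asarray(denoised, dtype=float)
    C = np.asarray(coords, dtype=float)
    vertices = np.atleast_2d(np.asarray(vertices, dtype=float))
    if n_regress_dims is None:
        n_regress_dims = C.shape[1]
    if n_regress_dims > C.shape[1]:
        raise ValueError("n_regress_dims exceeds available embedding dimensions")
    used = C[:, :n_regress_dims]
    X = np.column_stack([np.ones(len(den)), used])
    coef, *_ = np.linalg.lstsq(X, den, rcond=None)  # (n_dims+1) x voxels

    lo, hi = used.min(axis=0), used.max(axis=0)
    span = np.maximum(hi - lo, 1e-30)
    out = []
    for v_idx, vert in enumerate(vertices):
        full = np.zeros(n_regress_dims)
        for axis, dim in enumerate(subspace):
            if dim < n_regress_dims:
                full[dim] = vert[axis]
        if np.any(full < lo - 0.5 * span) or np.any(full > hi + 0.5 * span):
            logger.warning("vertex %d lies far outside the fitted coordinate range "
                           "(extrapolation)", v_idx)
        pred = coef[0] + full @ coef[1:]
        label = labels[v_idx] if labels else f"archetype_{v_idx}"
        out.append(ArchetypeMap(vertex_coords=vert.copy(), predicted_li=pred, label=label))
    return out
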