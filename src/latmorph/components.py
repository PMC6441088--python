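"""Varimax-rotated PCA of LI maps and the permutation test for lateralised voxels.

The decomposition treats *terms* as variables and voxels as observations:
the eigendecomposition of the term-by-term covariance matrix (each term
centred over voxels) yields loadings on terms.  Components with eigenvalues
strictly above the grand average are retained and varimax-rotated with
Kaiser normalisation.  Spatial maps are obtained voxelwise by ordinary
least squares of the across-term LI vector on the rotated loadings.

Family-wise error control uses the maximal-statistic permutation scheme:
rows of the *unrotated* loading matrix are permuted, varimax is re-applied,
spatial maps recomputed, and the single largest and smallest map values are
recorded per permutation.  A voxel is significantly lateralised if its real
map value beats the permutation extremes in at least ``1 - alpha/2`` of
permutations (two-tailed FWE) and belongs to a cluster of at least
``cluster_min`` voxels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import linalg, ndimage

from .grid import GridSpec

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# PCA
# --------------------------------------------------------------------------


@dataclass
class ComponentModel:
    """PCA + varimax model of a terms x voxels LI matrix."""

    loadings_unrotated: np.ndarray  # terms x n_retained, eigvec * sqrt(eigval)
    loadings_rotated: np.ndarray | None  # terms x n_retained
    rotation: np.ndarray | None  # n_retained x n_retained orthogonal
    eigenvalues: np.ndarray  # all eigenvalues, descending
    n_retained: int
    variance_explained: float
    term_means: np.ndarray = field(repr=False, default=None)  # per-term mean over voxels
    betas: np.ndarray | None = field(repr=False, default=None)  # n_retained x voxels
    intercept: np.ndarray | None = field(repr=False, default=None)  # voxels
    z_maps: np.ndarray | None = field(repr=False, default=None)  # n_retained x voxels
    labels: list[str] | None = None
    varimax_converged: bool = True

    @property
    def spatial_maps(self) -> np.ndarray | None:
        return self.betas


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Make each column's largest-magnitude entry positive (determinism)."""
    idx = np.argmax(np.abs(vectors), axis=0)
    signs = np.sign(vectors[idx, np.arange(vectors.shape[1])])
    signs[signs == 0] = 1.0
    return vectors * signs


def fit_pca(
    li_matrix: np.ndarray,
    terms: list[str] | None = None,
    n_retained: int | None = None,
) -> ComponentModel:
    """Eigendecomposition of the term-by-term covariance of an LI matrix.

    Components whose eigenvalue strictly exceeds the grand-average
    eigenvalue are retained (unless ``n_retained`` overrides the rule, as
    null pipelines matching a real dataset's component count require);
    ``variance_explained`` is their share of the total eigenvalue sum.
    Loadings are eigenvectors scaled by the square root of their
    eigenvalue.
    """
    X = np.asarray(li_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("li_matrix must be 2-D with at least 3 terms")
    n_terms, n_vox = X.shape
    means = X.mean(axis=1)
    Xc = X - means[:, None]
    cov = (Xc @ Xc.T) / (n_vox - 1)
    evals, evecs = linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    total = evals.sum()
    if total <= 0:
        raise ValueError("rank-0 data: all eigenvalues are zero")
    if n_retained is None:
        n_retained = int(np.sum(evals > evals.mean()))
    else:
        n_retained = int(min(n_retained, n_terms))
    evecs = _fix_signs(evecs)
    loadings = evecs[:, :n_retained] * np.sqrt(evals[:n_retained])
    ve = float(evals[:n_retained].sum() / total)
    model = ComponentModel(
        loadings_unrotated=loadings,
        loadings_rotated=None,
        rotation=None,
        eigenvalues=evals,
        n_retained=n_retained,
        variance_explained=ve,
        term_means=means,
    )
    if terms is not None:
        model.labels = label_components(loadings, terms)
    return model


def label_components(loadings: np.ndarray, terms: list[str]) -> list[str]:
    """Name each component after its largest-|loading| term."""
    return [terms[int(np.argmax(np.abs(loadings[:, k])))] for k in range(loadings.shape[1])]


# --------------------------------------------------------------------------
# Varimax
# --------------------------------------------------------------------------


def varimax_criterion(loadings: np.ndarray) -> float:
    """Sum over components of the variance of squared loadings."""
    sq = np.asarray(loadings) ** 2
    return float(np.sum(sq.var(axis=0)))


def varimax(
    loadings: np.ndarray,
    max_iter: int = 1000,
    tol: float = 1e-6,
    kaiser: bool = True,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Varimax rotation with Kaiser row normalisation.

    Rows are scaled to unit communality before rotation and rescaled after.
    Returns ``(rotated, rotation, converged)`` with ``rotated = loadings @
    rotation`` and ``rotation`` orthogonal.  Non-convergence after
    ``max_iter`` iterations returns the best iterate with a warning.
    """
    L = np.asarray(loadings, dtype=float)
    if L.ndim != 2:
        raise ValueError("loadings must be 2-D")
    p, k = L.shape
    if k < 2:
        return L.copy(), np.eye(k), True
    if kaiser:
        h = np.sqrt((L**2).sum(axis=1))
        h[h == 0] = 1.0
    else:
        h = np.ones(p)
    A = L / h[:, None]
    R = np.eye(k)
    d_old = 0.0
    converged = False
    for _ in range(max_iter):
        B = A @ R
        # gradient of the varimax criterion (Lawley-Maxwell form)
        G = A.T @ (B**3 - B * (B**2).sum(axis=0) / p)
        u, s, vt = np.linalg.svd(G)
        R = u @ vt
        d = s.sum()
        if d_old != 0 and d < d_old * (1.0 + tol):
            converged = True
            break
        d_old = d
    else:  # pragma: no cover - pathological input
        logger.warning("varimax did not converge in %d iterations", max_iter)
    rotated = (A @ R) * h[:, None]
    return rotated, R, converged


def _batch_polar(G: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthogonal polar factors (U @ Vt of the SVD) of a stack of k x k
    matrices, plus their nuclear norms, via the batched eigendecomposition
    of the k x k Gram matrices (cheaper than a batched SVD)."""
    w, V = np.linalg.eigh(np.swapaxes(G, 1, 2) @ G)
    w = np.maximum(w, w[:, -1:] * 1e-28)
    sqrt_w = np.sqrt(w)
    X = G @ (V / sqrt_w[:, None, :]) @ np.swapaxes(V, 1, 2)
    return X, sqrt_w.sum(axis=1)


def varimax_batch(
    loadings_stack: np.ndarray,
    max_iter: int = 1000,
    tol: float = 1e-6,
    kaiser: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation of a stack of loading matrices at once.

    Same update as :func:`varimax`, vectorised over the leading axis (used
    by the permutation test, which rotates hundreds of row-permuted
    matrices).  Iterates until every matrix in the stack has converged.
    Returns ``(rotated_stack, rotation_stack)``.
    """
    L = np.asarray(loadings_stack, dtype=float)
    if L.ndim != 3:
        raise ValueError("loadings_stack must be 3-D (stack x terms x components)")
    n, p, k = L.shape
    if k < 2:
        return L.copy(), np.broadcast_to(np.eye(k), (n, k, k)).copy()
    if kaiser:
        h = np.sqrt((L**2).sum(axis=2, keepdims=True))
        h[h == 0] = 1.0
    else:
        h = np.ones((n, p, 1))
    A = L / h
    At = np.swapaxes(A, 1, 2).copy()
    R = np.broadcast_to(np.eye(k), (n, k, k)).copy()
    d_old = np.zeros(n)
    active = np.ones(n, dtype=bool)
    for _ in range(max_iter):
        B = A[active] @ R[active]
        B2 = B**2
        G = At[active] @ (B * B2 - B * (B2.sum(axis=1, keepdims=True) / p))
        R[active], d = _batch_polar(G)
        conv = (d_old[active] != 0) & (d < d_old[active] * (1.0 + tol))
        d_old[active] = d
        still = np.flatnonzero(active)
        active[still[conv]] = False
        if not active.any():
            break
    else:  # pragma: no cover - pathological input
        logger.warning("batched varimax: %d matrices did not converge", int(active.sum()))
    return (A @ R) * h, R


def rotate_model(model: ComponentModel, max_iter: int = 1000, tol: float = 1e-6) -> ComponentModel:
    """Apply varimax to a fitted model's retained loadings."""
    rotated, R, conv = varimax(model.loadings_unrotated, max_iter=max_iter, tol=tol)
    if rotated.size:
        idx = np.argmax(np.abs(rotated), axis=0)
        signs = np.sign(rotated[idx, np.arange(rotated.shape[1])])
        signs[signs == 0] = 1.0
        rotated = rotated * signs
        R = R * signs  # column sign flips keep R orthogonal
    return replace(model, loadings_rotated=rotated, rotation=R, varimax_converged=conv)


# --------------------------------------------------------------------------
# Voxelwise GLM
# --------------------------------------------------------------------------


def spatial_maps_glm(
    li_matrix: np.ndarray,
    loadings: np.ndarray,
    with_z: bool = True,
    intercept: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Voxelwise OLS of across-term LI values on component loadings.

    Returns ``(betas, intercept_map, z)`` where ``betas`` is components x
    voxels, ``intercept_map`` the per-voxel constant (zeros when
    ``intercept`` is False), and ``z`` the betas divided by their OLS
    standard errors (None when ``with_z`` is False or there are no
    residual degrees of freedom).

    The intercept is off by default: when term weights are (near-)convex
    the retained components contain a constant-in-terms direction, and an
    explicit intercept column is then almost collinear with the loadings,
    inflating every beta's standard error by orders of magnitude.
    """
    Y = np.asarray(li_matrix, dtype=float)
    L = np.asarray(loadings, dtype=float)
    n_terms, k = L.shape
    if Y.shape[0] != n_terms:
        raise ValueError("li_matrix and loadings disagree on the number of terms")
    X = np.column_stack([np.ones(n_terms), L]) if intercept else L
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the dependent columns via pivoted QR
        _, _, piv = linalg.qr(X, pivoting=True)
        bad = sorted(piv[rank:])
        if intercept:
            names = ["intercept" if j == 0 else f"component {j - 1}" for j in bad]
        else:
            names = [f"component {j}" for j in bad]
        raise ValueError(f"design matrix is rank deficient; offending columns: {names}")
    XtX_inv = linalg.inv(X.T @ X)
    coef = XtX_inv @ (X.T @ Y)
    if intercept:
        intercept_map, betas = coef[0], coef[1:]
        diag = np.diag(XtX_inv)[1:]
    else:
        intercept_map, betas = np.zeros(Y.shape[1]), coef
        diag = np.diag(XtX_inv)
    z = None
    dof = n_terms - X.shape[1]
    if with_z and dof > 0:
        resid = Y - X @ coef
        sigma2 = (resid**2).sum(axis=0) / dof
        se = np.sqrt(np.outer(diag, sigma2))
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(se > 0, betas / se, 0.0)
    return betas, intercept_map, z


def fit_component_model(
    li_matrix: np.ndarray,
    terms: list[str] | None = None,
    n_retained: int | None = None,
    max_iter: int = 1000,
    tol: float = 1e-6,
    intercept: bool = False,
) -> ComponentModel:
    """PCA -> varimax -> voxelwise GLM in one call.

    ``n_retained`` overrides the eigenvalue-above-average retention rule
    (used by null pipelines that must match the real data's component
    count).
    """
    model = fit_pca(li_matrix, terms=terms, n_retained=n_retained)
    model = rotate_model(model, max_iter=max_iter, tol=tol)
    betas, intercept_map, z = spatial_maps_glm(
        li_matrix, model.loadings_rotated, intercept=intercept
    )
    model.betas, model.intercept, model.z_maps = betas, intercept_map, z
    if terms is not None:
        model.labels = label_components(model.loadings_rotated, terms)
    return model


# --------------------------------------------------------------------------
# Maximal-statistic permutation significance
# --------------------------------------------------------------------------


@dataclass
class SignificanceMask:
    """Per-component significance masks (split by lateralisation sign)."""

    pos: np.ndarray = field(repr=False, default=None)  # components x voxels bool
    neg: np.ndarray = field(repr=False, default=None)
    maxima: np.ndarray = field(repr=False, default=None)  # permutation null of map maxima
    minima: np.ndarray = field(repr=False, default=None)
    alpha: float = 0.05
    cluster_min: int = 20

    @property
    def any_mask(self) -> np.ndarray:
        """Voxels significant for at least one component, either sign."""
        return (self.pos | self.neg).any(axis=0)

    def component_mask(self, k: int) -> np.ndarray:
        return self.pos[k] | self.neg[k]


def _connectivity_structure(connectivity: int) -> np.ndarray:
    order = {6: 1, 18: 2, 26: 3}.get(connectivity)
    if order is None:
        raise ValueError("connectivity must be 6, 18 or 26")
    return ndimage.generate_binary_structure(3, order)


def _cluster_filter(
    mask_vec: np.ndarray, grid: GridSpec, cluster_min: int, structure: np.ndarray
) -> np.ndarray:
    """Drop connected components smaller than cluster_min voxels."""
    if cluster_min <= 1 or not mask_vec.any():
        return mask_vec
    field3d = grid.vector_to_half(mask_vec.astype(float)) > 0.5
    labels, n = ndimage.label(field3d, structure=structure)
    if n == 0:
        return np.zeros_like(mask_vec)
    sizes = np.bincount(labels.ravel())
    keep = np.zeros(n + 1, dtype=bool)
    keep[1:] = sizes[1:] >= cluster_min
    return keep[labels][grid.half_mask]


def permutation_significance(
    li_matrix: np.ndarray,
    model: ComponentModel,
    grid: GridSpec,
    n_perm: int = 5000,
    alpha: float = 0.05,
    cluster_min: int = 20,
    connectivity: int = 26,
    seed: int | np.random.Generator = 0,
    statistic: str = "beta",
    intercept: bool = False,
) -> SignificanceMask:
    """Rotation-aware maximal-statistic permutation FWE test.

    Each permutation reorders the rows of the unrotated loading matrix,
    re-applies varimax, refits the voxelwise GLM against the *unpermuted*
    LI matrix, and records the single largest and smallest spatial-map
    value.  Real map values are compared against those extremes (strictly,
    two-tailed at ``alpha``), then clusters below ``cluster_min`` voxels
    are removed per component and sign.
    """
    if not 0 < alpha < 0.5:
        raise ValueError("alpha must be in (0, 0.5)")
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if n_perm * alpha / 2.0 < 1.0:
        raise ValueError(f"n_perm={n_perm} too small to resolve alpha={alpha} two-tailed")
    if model.betas is None:
        raise ValueError("model has no spatial maps; run fit_component_model first")
    Y = np.asarray(li_matrix, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    structure = _connectivity_structure(connectivity)

    real = model.betas if statistic == "beta" else model.z_maps
    if real is None:
        raise ValueError(f"statistic {statistic!r} not available on the model")

    L0 = model.loadings_unrotated
    n_terms, k = L0.shape
    maxima = np.empty(n_perm)
    minima = np.empty(n_perm)
    if not intercept:
        # lean vectorised path: row permutation leaves L0'L0 unchanged, and
        # the varimax output is the permuted loadings times an orthogonal R
        G0_inv = np.linalg.inv(L0.T @ L0)
        dof = n_terms - k
        yy = np.einsum("tv,tv->v", Y, Y)  # per-voxel sum of squares
        perms = np.stack([rng.permutation(n_terms) for _ in range(n_perm)])
        chunk = max(1, int(4e7 // (k * Y.shape[1])))  # cap working memory
        for lo in range(0, n_perm, chunk):
            idx = slice(lo, min(lo + chunk, n_perm))
            rotated, R = varimax_batch(L0[perms[idx]])
            n_c = rotated.shape[0]
            XtX_inv = np.swapaxes(R, 1, 2) @ G0_inv @ R
            # one large GEMM instead of a strided batch of small ones
            Xt = np.ascontiguousarray(np.swapaxes(rotated, 1, 2)).reshape(n_c * k, n_terms)
            XtY = (Xt @ Y).reshape(n_c, k, -1)
            coef = XtX_inv @ XtY
            if statistic == "z":
                # residual SS = ||y||^2 - (X'y)'beta, no residual matrix needed
                sigma2 = (yy[None, :] - np.einsum("nkv,nkv->nv", XtY, coef)) / dof
                sigma2 = np.maximum(sigma2, 0.0)
                diag = np.diagonal(XtX_inv, axis1=1, axis2=2)
                with np.errstate(divide="ignore", invalid="ignore"):
                    stat = coef / np.sqrt(diag[:, :, None] * sigma2[:, None, :])
            else:
                stat = coef
            maxima[idx] = stat.max(axis=(1, 2))
            minima[idx] = stat.min(axis=(1, 2))
    else:
        for i in range(n_perm):
            perm = rng.permutation(n_terms)
            rotated, _, _ = varimax(L0[perm])
            betas, _, z = spatial_maps_glm(
                Y, rotated, with_z=(statistic == "z"), intercept=True
            )
            stat = betas if statistic == "beta" else z
            maxima[i] = stat.max()
            minima[i] = stat.min()

    # strict two-tailed comparison against the permutation extremes
    n_hi = np.sum(real[:, :, None] > maxima[None, None, :], axis=2)
    n_lo = np.sum(real[:, :, None] < minima[None, None, :], axis=2)
    thresh = (1.0 - alpha / 2.0) * n_perm
    pos = n_hi >= thresh
    neg = n_lo >= thresh

    for kcomp in range(pos.shape[0]):
        pos[kcomp] = _cluster_filter(pos[kcomp], grid, cluster_min, structure)
        neg[kcomp] = _cluster_filter(neg[kcomp], grid, cluster_min, structure)

    return SignificanceMask(
        pos=pos, neg=neg, maxima=maxima, minima=minima, alpha=alpha, cluster_min=cluster_min
    )
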