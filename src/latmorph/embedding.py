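"""Spectral embedding of lateralisation maps (the "morphospace").

Maps are first denoised by reconstructing them from the retained varimax
components and their spatial maps.  Pairwise similarity is the voxelwise
dot product of denoised maps with negative values zeroed; the maps are then
embedded by eigendecomposition of the symmetric normalised graph Laplacian
``L = I - D^{-1/2} W D^{-1/2}``.  Dimensions are ordered by ascending
eigenvalue and the first (zero-eigenvalue, constant) dimension is dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, sparse
from scipy.sparse import csgraph

from .components import ComponentModel

logger = logging.getLogger(__name__)


@dataclass
class EmbeddingSpace:
    """Coordinates of maps in the spectral morphospace."""

    coords: np.ndarray = field(repr=False, default=None)  # maps x n_dims
    eigenvalues: np.ndarray = field(repr=False, default=None)  # ascending, incl. dropped 0
    similarity: np.ndarray = field(repr=False, default=None)
    degree_rescaled: bool = True

    @property
    def n_dims(self) -> int:
        return self.coords.shape[1]


def denoise_maps(li_matrix: np.ndarray, model: ComponentModel) -> np.ndarray:
    """Reconstruct LI maps from retained components and their spatial maps.

    ``denoised = rotated_loadings @ betas + intercept``; the intercept is
    the per-voxel constant of the voxelwise GLM, re-added so the
    reconstruction lives on the scale of the original maps.
    """
    if model.betas is None or model.loadings_rotated is None:
        raise ValueError("model must carry rotated loadings and spatial maps")
    Y = np.asarray(li_matrix, dtype=float)
    if Y.shape != (model.loadings_rotated.shape[0], model.betas.shape[1]):
        raise ValueError(
            f"li_matrix shape {Y.shape} does not match model "
            f"({model.loadings_rotated.shape[0]} terms x {model.betas.shape[1]} voxels)"
        )
    return model.loadings_rotated @ model.betas + model.intercept[None, :]


def similarity_matrix(denoised: np.ndarray) -> np.ndarray:
    """Nonnegative dot-product similarity between denoised maps.

    Entry (i, j) is ``max(0, sum_v x_i(v) x_j(v))`` for i != j; negative
    dot products are zeroed (anti-correlated maps are simply unconnected in
    the graph) and the diagonal is set to zero.
    """
    X = np.asarray(denoised, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("need at least 3 maps")
    S = X @ X.T
    np.maximum(S, 0.0, out=S)
    np.fill_diagonal(S, 0.0)
    S = (S + S.T) / 2.0  # exact symmetry against rounding
    if not S.any():
        raise ValueError("similarity matrix is all zero: no graph to embed")
    return S


def spectral_embed(
    similarity: np.ndarray, n_dims: int, degree_rescaled: bool = True
) -> EmbeddingSpace:
    """Embed maps via the symmetric normalised graph Laplacian.

    Eigenpairs are sorted by ascending eigenvalue; the first eigenvector
    (eigenvalue 0) is dropped and the next ``n_dims`` form the coordinates,
    rescaled by ``D^{-1/2}`` unless ``degree_rescaled`` is False.  Each
    coordinate's sign is fixed so its largest-magnitude entry is positive.

    Raises
    ------
    ValueError
        If the similarity graph is disconnected (with the component count)
        or ``n_dims`` is too large.
    """
    W = np.asarray(similarity, dtype=float)
    n = W.shape[0]
    if n_dims >= n:
        raise ValueError(f"n_dims={n_dims} must be < number of maps ({n})")
    n_comp, _ = csgraph.connected_components(sparse.csr_matrix(W > 0), directed=False)
    if n_comp > 1:
        raise ValueError(f"similarity graph is disconnected ({n_comp} components)")
    d = W.sum(axis=1)
    d_isqrt = 1.0 / np.sqrt(d)
    L = np.eye(n) - d_isqrt[:, None] * W * d_isqrt[None, :]
    L = (L + L.T) / 2.0
    evals, evecs = linalg.eigh(L)
    # detect near-degenerate eigenvalues among the used dimensions
    used = evals[1 : n_dims + 1]
    if np.any(np.diff(used) < 1e-10 * max(1.0, float(np.abs(used).max()))):
        logger.info("repeated Laplacian eigenvalues: within-eigenspace rotation is arbitrary")
    vecs = evecs[:, 1 : n_dims + 1]
    if degree_rescaled:
        vecs = d_isqrt[:, None] * vecs
    idx = np.argmax(np.abs(vecs), axis=0)
    signs = np.sign(vecs[idx, np.arange(vecs.shape[1])])
    signs[signs == 0] = 1.0
    coords = vecs * signs
    return EmbeddingSpace(
        coords=coords, eigenvalues=evals, similarity=W, degree_rescaled=degree_rescaled
    )


def embed_li_matrix(
    li_matrix: np.ndarray,
    model: ComponentModel,
    n_dims: int,
    degree_rescaled: bool = True,
) -> tuple[np.ndarray, EmbeddingSpace]:
    """Denoise, build similarity, and embed in one call."""
    den = denoise_maps(li_matrix, model)
    S = similarity_matrix(den)
    return den, spectral_embed(S, n_dims, degree_rescaled=degree_rescaled)
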