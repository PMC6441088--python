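"""Synthetic symmetric-brain datasets with planted ground truth.

The generator emulates the inputs of the lateralisation analysis at desk
scale: a stack of per-term volumes on a mirror-symmetric grid whose
laterality structure is a noisy convex mixture of a small number of planted
archetype patterns (yielding a triangular morphospace), matched null
datasets whose hemispheres are exchangeable, and per-subject callosal
connectivity whose connection probability decreases linearly with planted
hemispheric dominance and whose axonal water fraction is lowered by a
planted offset for lateralised voxels.

Every stage draws from its own child stream of a single master seed (see
:mod:`latmorph._seeds`), so identical ``(config, seed)`` pairs give
byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ._seeds import stage_rng
from .grid import GridSpec

logger = logging.getLogger(__name__)

# Study-condition defaults for the planted dominance-connectivity relation.
# The connection-probability model is p = P_BASE + conn_slope * |dominance|
# + voxel jitter, clipped to [1/n_subjects, 1].  With dominance magnitudes
# spanning [0, pi/4], DEFAULT_CONN_SLOPE drives strongly lateralised voxels
# into the lower clip; that saturation, together with the jitter, is what
# places the binned dominance-probability correlation at the planted target
# of -0.8 (a purely linear unclipped relation bins to r ~ -1).  See
# docs/methods.md for the calibration.
DEFAULT_P_BASE = 0.90
DEFAULT_CONN_SLOPE = -3.0
DEFAULT_P_JITTER_SD = 0.25
DEFAULT_AWF_MEAN = 0.60
DEFAULT_AWF_SD = 0.08

_BACKGROUND_OFFSET = 3.0  # keeps activations positive
_SMOOTH_SIGMA_VOX = 1.5  # spatial scale of planted patterns


@dataclass
class TermMapSet:
    """Stack of per-term volumes on a symmetric grid."""

    volumes: np.ndarray = field(repr=False, default=None)  # terms x grid shape
    terms: list[str] = None
    grid: GridSpec = None

    @property
    def n_terms(self) -> int:
        return self.volumes.shape[0]


@dataclass
class PlantedTruth:
    """Ground truth planted by the generator, for recovery tests."""

    archetype_patterns: np.ndarray = field(repr=False, default=None)  # K x half-voxels
    archetype_coords: np.ndarray = None  # K x 2 latent positions
    term_weights: np.ndarray = field(repr=False, default=None)  # T x K convex
    dominance_field: np.ndarray = field(repr=False, default=None)  # half-voxels, radians
    conn_slope: float | None = None
    awf_offset: float | None = None


@dataclass
class SubjectConnectivity:
    """Per-subject callosal connectivity (indicator + axonal water fraction)."""

    n_subjects: int
    indicator: np.ndarray = field(repr=False, default=None)  # subjects x voxels, binary
    awf: np.ndarray = field(repr=False, default=None)  # subjects x callosal voxels


def _smooth_field(rng: np.random.Generator, shape, mask, sigma=_SMOOTH_SIGMA_VOX):
    """Smoothed white noise standardised to zero mean, unit sd over the mask."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="constant")
    vals = f[mask]
    f = (f - vals.mean()) / vals.std()
    return np.where(mask, f, 0.0)


def _latent_coords(k: int) -> np.ndarray:
    if k == 3:  # equilateral triangle
        ang = np.pi / 2 + np.arange(3) * 2 * np.pi / 3
    else:  # square
        ang = np.pi / 4 + np.arange(4) * np.pi / 2
    return np.column_stack([np.cos(ang), np.sin(ang)])


def _backgrounds(grid: GridSpec, n_terms: int, rng: np.random.Generator) -> np.ndarray:
    """Per-term symmetric background fields (half-grid), positive, rank-1 across terms.

    A shared smooth bilateral pattern with term-varying amplitude gives the
    original (un-differenced) maps significant bilateral structure, which
    the non-lateralised-region definition needs.
    """
    shared = _smooth_field(rng, grid.half_shape, grid.half_mask)
    amps = rng.uniform(0.5, 1.5, size=n_terms)
    return _BACKGROUND_OFFSET + amps[:, None, None, None] * shared[None]


def _assemble_volumes(grid: GridSpec, backgrounds: np.ndarray, li_half: np.ndarray) -> np.ndarray:
    """Full volumes whose right-minus-mirrored-left equals ``li_half`` exactly."""
    mask = grid.mask
    vols = np.empty((len(backgrounds),) + grid.shape)
    for t in range(len(backgrounds)):
        vols[t] = grid.assemble(backgrounds[t] - li_half[t] / 2.0,
                                backgrounds[t] + li_half[t] / 2.0)
    return np.where(mask[None], vols, 0.0)


def generate_term_maps(
    grid: GridSpec,
    n_terms: int,
    n_archetypes: int = 3,
    noise_sd: float = 0.1,
    seed: int = 0,
    effect_scale: float = 1.0,
    dirichlet_alpha: float = 0.35,
) -> tuple[TermMapSet, PlantedTruth]:
    """Term maps whose LI structure is a noisy convex mixture of archetypes.

    The first ``n_archetypes`` terms are pure archetypes; the remaining
    term weights are Dirichlet(``dirichlet_alpha``) draws, spreading the
    maps across the simplex with its corners occupied.  With
    ``noise_sd=0`` the LI map of every term (computed without smoothing)
    equals its planted mixture exactly.
    """
    if n_archetypes not in (3, 4):
        raise ValueError("n_archetypes must be 3 or 4")
    if n_terms < 3 * n_archetypes:
        raise ValueError("n_terms must be at least 3 * n_archetypes")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")

    half_mask = grid.half_mask
    n_vox = grid.n_half_voxels

    rng_a = stage_rng(seed, "archetypes")
    raw = np.stack(
        [grid.half_to_vector(_smooth_field(rng_a, grid.half_shape, half_mask))
         for _ in range(n_archetypes)]
    )
    # archetypes are maximally distinct specialised profiles: make them
    # exactly uncorrelated over voxels (random smooth fields can come out
    # strongly correlated, which squeezes the planted simplex)
    Q, _ = np.linalg.qr(raw.T)
    signs = np.sign(Q[np.argmax(np.abs(Q), axis=0), np.arange(n_archetypes)])
    signs[signs == 0] = 1.0
    patterns = (Q * signs).T
    patterns /= patterns.std(axis=1, keepdims=True)

    rng_w = stage_rng(seed, "weights")
    weights = np.zeros((n_terms, n_archetypes))
    weights[:n_archetypes] = np.eye(n_archetypes)
    weights[n_archetypes:] = rng_w.dirichlet(
        np.full(n_archetypes, dirichlet_alpha), size=n_terms - n_archetypes
    )

    li_vec = effect_scale * (weights @ patterns)
    if noise_sd > 0:
        li_vec = li_vec + stage_rng(seed, "noise").normal(0.0, noise_sd, size=li_vec.shape)
    li_half = np.stack([grid.vector_to_half(v) for v in li_vec])

    backgrounds = _backgrounds(grid, n_terms, stage_rng(seed, "background"))
    volumes = _assemble_volumes(grid, backgrounds, li_half)

    # planted dominance: mean activation of the two hemispheres across terms
    right = np.clip(backgrounds.mean(axis=0) + li_half.mean(axis=0) / 2.0, 0.0, None)
    left = np.clip(backgrounds.mean(axis=0) - li_half.mean(axis=0) / 2.0, 0.0, None)
    with np.errstate(invalid="ignore"):
        dom = np.arctan2(right, left) - np.pi / 4.0
    dominance = grid.half_to_vector(np.where(half_mask, dom, np.nan))

    terms = [f"term_{i:03d}" for i in range(n_terms)]
    truth = PlantedTruth(
        archetype_patterns=patterns,
        archetype_coords=_latent_coords(n_archetypes),
        term_weights=weights,
        dominance_field=dominance,
    )
    return TermMapSet(volumes=volumes, terms=terms, grid=grid), truth


def generate_null_maps(
    grid: GridSpec, n_terms: int, noise_sd: float = 0.1, seed: int = 0
) -> TermMapSet:
    """Term maps with exchangeable hemispheres (no planted asymmetry).

    Each volume is a symmetric background plus independent voxelwise
    Gaussian noise over the full grid, so left and right hemisphere values
    are identically distributed and the expected LI is zero everywhere.
    """
    if n_terms < 3:
        raise ValueError("n_terms must be at least 3")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    backgrounds = _backgrounds(grid, n_terms, stage_rng(seed, "background"))
    vols = _assemble_volumes(grid, backgrounds, np.zeros((n_terms,) + grid.half_shape))
    if noise_sd > 0:
        vols = vols + stage_rng(seed, "null_maps").normal(0.0, noise_sd, size=vols.shape)
    vols = np.where(grid.mask[None], vols, 0.0)
    return TermMapSet(volumes=vols, terms=[f"null_{i:03d}" for i in range(n_terms)], grid=grid)


def generate_connectivity(
    grid: GridSpec | None,
    dominance_field: np.ndarray,
    conn_slope: float = DEFAULT_CONN_SLOPE,
    awf_offset: float = -0.05,
    n_subjects: int = 163,
    seed: int = 0,
    p_base: float = DEFAULT_P_BASE,
    p_jitter_sd: float = DEFAULT_P_JITTER_SD,
    awf_mean: float = DEFAULT_AWF_MEAN,
    awf_sd: float = DEFAULT_AWF_SD,
) -> SubjectConnectivity:
    """Per-subject connectivity with a planted dominance-probability relation.

    ``dominance_field`` is a vector of dominance values in radians with NaN
    for non-lateralised voxels (which get the base probability and the
    unshifted AWF mean).  Per subject and voxel the connection indicator is
    Bernoulli with probability ``p_base + conn_slope*|dominance| + jitter``
    clipped to ``[1/n_subjects, 1]``; AWF is Gaussian with mean lowered by
    ``awf_offset`` (a negative value lowers it) for lateralised voxels.
    Callosal voxels are indexed identically to cortical voxels (one
    projection target per cortical voxel).
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    dom = np.asarray(dominance_field, dtype=float).ravel()
    lateralised = ~np.isnan(dom)
    mag = np.where(lateralised, np.abs(dom), 0.0)

    rng = stage_rng(seed, "connectivity")
    p_pre = p_base + conn_slope * mag
    if p_jitter_sd > 0:
        p_pre = p_pre + rng.normal(0.0, p_jitter_sd, size=p_pre.shape)
    if np.any(p_pre < 0.0) or np.any(p_pre > 1.0):
        logger.warning(
            "connection probabilities outside [0, 1] before clipping "
            "(%d of %d voxels)", int(np.sum((p_pre < 0) | (p_pre > 1))), p_pre.size
        )
    p = np.clip(p_pre, 1.0 / n_subjects, 1.0)

    indicator = (rng.random((n_subjects, p.size)) < p[None, :]).astype(np.uint8)
    awf = rng.normal(awf_mean + awf_offset * lateralised, awf_sd, size=(n_subjects, p.size))
    awf = np.clip(awf, 0.0, 1.0)
    return SubjectConnectivity(n_subjects=n_subjects, indicator=indicator, awf=awf)


def demo_dominance_field(
    n_lateralised: int, n_nonlateralised: int = 0, seed: int = 0
) -> np.ndarray:
    """Dominance vector with uniform |dominance| on lateralised voxels.

    Lateralised voxels get magnitudes uniform on [0, pi/4] with random
    sign; non-lateralised voxels are NaN.  Used by the connectivity
    recovery analyses, which need a stand-alone dominance field without a
    full term-map pipeline.
    """
    rng = stage_rng(seed, "misc")
    mag = rng.uniform(0.0, np.pi / 4.0, size=n_lateralised)
    sign = rng.choice([-1.0, 1.0], size=n_lateralised)
    return np.concatenate([mag * sign, np.full(n_nonlateralised, np.nan)])
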