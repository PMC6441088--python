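"""Laterality-index (LI) maps.

A functional volume on a symmetric grid is split into hemisphere halves,
each half is smoothed with a Gaussian kernel renormalised inside the brain
mask, the left half is flipped onto the right, and the difference
``smooth(right) - flip(smooth(left))`` is the LI map.  Positive values mean
stronger right-hemisphere activation.

Smoothing the halves *after* the split avoids leakage of signal across the
interhemispheric plane; for a symmetric kernel, smoothing and flipping
commute, so the order of flip and smooth for the left half is immaterial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import GridSpec

#: FWHM of a Gaussian = 2*sqrt(2*ln 2) standard deviations.
FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

_TRUNCATE_SD = 4.0  # kernel truncation radius in standard deviations


@dataclass(frozen=True)
class LIMap:
    """Half-grid laterality-index field for one term (positive = right)."""

    values: np.ndarray = field(repr=False)  # half-grid field, 0 outside mask
    term: str
    fwhm_mm: float


def fwhm_to_sigma_voxels(fwhm_mm: float, voxel_size_mm: float) -> float:
    """Per-axis Gaussian standard deviation in voxels for a given FWHM in mm."""
    return fwhm_mm / FWHM_PER_SIGMA / voxel_size_mm


def split_hemispheres(volume: np.ndarray, grid: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    """Split a full volume into (left, right) halves in homologous indexing.

    The left half is returned flipped into half-grid order, so equal indices
    address homologous voxel pairs.  ``grid.assemble(left, right)``
    reconstructs the input exactly.
    """
    volume = np.asarray(volume)
    if volume.shape != grid.shape:
        raise ValueError(
            f"volume shape {volume.shape} does not match grid shape {grid.shape}"
        )
    return grid.left_half(volume), grid.right_half(volume)


def smooth_gaussian(
    half: np.ndarray,
    fwhm_mm: float,
    voxel_size_mm: float,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Mask-renormalised Gaussian smoothing of a half-grid field.

    The kernel is truncated at 4 standard deviations and renormalised over
    the mask (ratio of smoothed masked field to smoothed mask), so constant
    fields are preserved exactly and no mass bleeds outside the brain.
    Output is zero outside the mask.
    """
    if fwhm_mm < 0:
        raise ValueError(f"fwhm_mm must be >= 0, got {fwhm_mm}")
    half = np.asarray(half, dtype=float)
    if mask is None:
        mask = np.ones(half.shape, dtype=bool)
    if fwhm_mm == 0:
        return np.where(mask, half, 0.0)
    sigma = fwhm_to_sigma_voxels(fwhm_mm, voxel_size_mm)
    m = mask.astype(float)
    num = ndimage.gaussian_filter(half * m, sigma=sigma, truncate=_TRUNCATE_SD, mode="constant")
    den = ndimage.gaussian_filter(m, sigma=sigma, truncate=_TRUNCATE_SD, mode="constant")
    out = np.zeros_like(half)
    np.divide(num, den, out=out, where=den > 0)
    return np.where(mask, out, 0.0)


def compute_li(volume: np.ndarray, grid: GridSpec, fwhm_mm: float, term: str = "") -> LIMap:
    """LI map of a volume: split, smooth each half, subtract flipped left from right."""
    left, right = split_hemispheres(volume, grid)
    hm = grid.half_mask
    sl = smooth_gaussian(left, fwhm_mm, grid.voxel_size_mm, mask=hm)
    sr = smooth_gaussian(right, fwhm_mm, grid.voxel_size_mm, mask=hm)
    values = np.where(hm, sr - sl, 0.0)
    return LIMap(values=values, term=term, fwhm_mm=fwhm_mm)


def li_matrix(volumes: np.ndarray, grid: GridSpec, fwhm_mm: float) -> np.ndarray:
    """Stack LI maps of several volumes into a terms x half-voxels matrix."""
    volumes = np.asarray(volumes)
    return np.stack(
        [grid.half_to_vector(compute_li(v, grid, fwhm_mm).values) for v in volumes]
    )


def hemisphere_matrices(
    volumes: np.ndarray, grid: GridSpec, fwhm_mm: float
) -> tuple[np.ndarray, np.ndarray]:
    """Smoothed (left, right) hemisphere matrices, terms x half-voxels.

    Left is in homologous (flipped) indexing; ``right - left`` equals the
    LI matrix.
    """
    hm = grid.half_mask
    lefts, rights = [], []
    for v in np.asarray(volumes):
        left, right = split_hemispheres(v, grid)
        lefts.append(grid.half_to_vector(smooth_gaussian(left, fwhm_mm, grid.voxel_size_mm, hm)))
        rights.append(grid.half_to_vector(smooth_gaussian(right, fwhm_mm, grid.voxel_size_mm, hm)))
    return np.stack(lefts), np.stack(rights)
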