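"""Left-right symmetric voxel grids.

The analyses operate on volumes registered to a mirror-symmetric template:
every voxel in one hemisphere has a homologous (homotopic) partner obtained
by flipping the grid across the interhemispheric plane.  The grid here is an
idealisation of that template: the mirror plane sits between two voxel
layers (even extent along the mirror axis, no shared midline voxel) and the
in-brain mask is exactly mirror-symmetric.

Half-grid convention
--------------------
The "right" hemisphere is the upper half of the mirror axis, the "left" the
lower half.  Half-grid fields are indexed so that index ``j`` along the
(former) mirror axis counts *away from the midline*; homologous voxels of
the two hemispheres therefore share the same half-grid index.  Positive
laterality-index values mean right-hemisphere dominance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class GridSpec:
    """A symmetric 3-D grid with an in-brain mask.

    Parameters
    ----------
    shape : tuple of int
        Voxels per axis; even along ``mirror_axis``.
    mirror_axis : int
        Axis across which the hemispheres are mirrored.
    mask : ndarray of bool
        In-brain voxels; exactly mirror-symmetric.
    voxel_size_mm : float
        Isotropic voxel edge length in millimetres.
    """

    shape: tuple[int, int, int]
    mirror_axis: int
    mask: np.ndarray = field(repr=False)
    voxel_size_mm: float = 2.0

    def __post_init__(self) -> None:
        if len(self.shape) != 3:
            raise ValueError("shape must be a triple")
        if not 0 <= self.mirror_axis < 3:
            raise ValueError("mirror_axis must be 0, 1 or 2")
        if self.shape[self.mirror_axis] % 2 != 0:
            raise ValueError(
                f"extent along mirror axis {self.mirror_axis} must be even "
                f"(no shared midline voxel); got {self.shape[self.mirror_axis]}"
            )
        if tuple(self.mask.shape) != tuple(self.shape):
            raise ValueError("mask shape does not match grid shape")
        if not np.array_equal(self.mask, np.flip(self.mask, axis=self.mirror_axis)):
            raise ValueError("mask is not mirror-symmetric across the mirror axis")

    # ---- derived geometry -------------------------------------------------

    @property
    def half_extent(self) -> int:
        return self.shape[self.mirror_axis] // 2

    @property
    def half_shape(self) -> tuple[int, int, int]:
        s = list(self.shape)
        s[self.mirror_axis] = self.half_extent
        return tuple(s)

    @property
    def half_mask(self) -> np.ndarray:
        """Mask restricted to one hemisphere, in half-grid (away-from-midline) order."""
        return self.right_half(self.mask.astype(float)) > 0.5

    @property
    def n_half_voxels(self) -> int:
        return int(self.half_mask.sum())

    def _half_slices(self):
        h = self.half_extent
        left = [slice(None)] * 3
        right = [slice(None)] * 3
        left[self.mirror_axis] = slice(0, h)
        right[self.mirror_axis] = slice(h, 2 * h)
        return tuple(left), tuple(right)

    # ---- hemisphere extraction / assembly ---------------------------------

    def right_half(self, volume: np.ndarray) -> np.ndarray:
        """Right-hemisphere half in half-grid order (index 0 adjacent to midline)."""
        _, right = self._half_slices()
        return np.ascontiguousarray(volume[right])

    def left_half(self, volume: np.ndarray) -> np.ndarray:
        """Left-hemisphere half, *flipped* into half-grid order so homologous
        voxels share indices with :meth:`right_half`."""
        left, _ = self._half_slices()
        return np.ascontiguousarray(np.flip(volume[left], axis=self.mirror_axis))

    def assemble(self, left_half: np.ndarray, right_half: np.ndarray) -> np.ndarray:
        """Inverse of (:meth:`left_half`, :meth:`right_half`)."""
        if left_half.shape != self.half_shape or right_half.shape != self.half_shape:
            raise ValueError("half volumes do not match grid half shape")
        out = np.empty(self.shape, dtype=np.result_type(left_half, right_half))
        left, right = self._half_slices()
        out[left] = np.flip(left_half, axis=self.mirror_axis)
        out[right] = right_half
        return out

    def mirror(self, volume: np.ndarray) -> np.ndarray:
        """Swap hemispheres (flip across the mirror axis)."""
        if volume.shape != self.shape:
            raise ValueError("volume shape does not match grid")
        return np.flip(volume, axis=self.mirror_axis)

    # ---- half-grid <-> flat vector over the half mask ----------------------

    def half_to_vector(self, half_field: np.ndarray) -> np.ndarray:
        """Flatten a half-grid field to the vector of in-mask voxels."""
        if half_field.shape != self.half_shape:
            raise ValueError("field shape does not match half grid")
        return np.asarray(half_field)[self.half_mask]

    def vector_to_half(self, vec: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Embed a half-mask vector back into a half-grid field."""
        vec = np.asarray(vec)
        if vec.shape[-1] != self.n_half_voxels:
            raise ValueError("vector length does not match half-mask size")
        out = np.full(vec.shape[:-1] + self.half_shape, fill, dtype=float)
        out[..., self.half_mask] = vec
        return out

    def midline_distance_mm(self) -> np.ndarray:
        """Distance of each half-mask voxel centre to the interhemispheric plane."""
        idx = np.indices(self.half_shape)[self.mirror_axis]
        dist = (idx + 0.5) * self.voxel_size_mm
        return dist[self.half_mask]

    def affine(self) -> np.ndarray:
        """NIfTI affine: isotropic voxels, origin at the grid centre."""
        a = np.eye(4)
        a[:3, :3] *= self.voxel_size_mm
        a[:3, 3] = -np.asarray(self.shape) / 2.0 * self.voxel_size_mm
        return a


def make_symmetric_grid(
    shape: tuple[int, int, int],
    mask_kind: str = "box",
    mirror_axis: int = 0,
    voxel_size_mm: float = 2.0,
) -> GridSpec:
    """Construct a mirror-symmetric grid with a full-box or ellipsoid mask.

    Raises
    ------
    ValueError
        If any extent is < 4, the mirror-axis extent is odd, or
        ``mask_kind`` is unknown.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s < 4 for s in shape):
        raise ValueError(f"shape components must be >= 4, got {shape}")
    if shape[mirror_axis] % 2 != 0:
        raise ValueError(
            f"extent along mirror axis {mirror_axis} must be even, got {shape[mirror_axis]}"
        )
    if mask_kind == "box":
        mask = np.ones(shape, dtype=bool)
    elif mask_kind == "ellipsoid":
        centre = (np.asarray(shape) - 1) / 2.0
        semi = np.asarray(shape) / 2.0
        idx = np.indices(shape)
        r2 = sum(((idx[a] - centre[a]) / semi[a]) ** 2 for a in range(3))
        mask = r2 <= 1.0
        # enforce exact symmetry against floating-point asymmetries
        mask &= np.flip(mask, axis=mirror_axis)
    else:
        raise ValueError(f"unknown mask_kind {mask_kind!r}; use 'box' or 'ellipsoid'")
    return GridSpec(shape=shape, mirror_axis=mirror_axis, mask=mask, voxel_size_mm=voxel_size_mm)
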