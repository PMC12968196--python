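"""Voxel-grid geometry and NIfTI I/O.

All geometry in this package is computed in world millimetres (RAS+), never
in voxel units, so anisotropic grids come for free.  Conventions used
everywhere downstream:

* voxel indices are 0-based;
* a voxel's world position is its **center** (``affine @ (i, j, k, 1)``);
* a voxel belongs to a region iff its center satisfies the predicate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "Volume",
    "VoxelDims",
    "read_volume",
    "write_volume",
    "voxel_dimensions",
    "voxel_to_world",
    "world_to_voxel",
    "point_in_mask",
    "distance_to_mask",
]


@dataclass
class VoxelDims:
    """Edge lengths of one voxel in mm along the three index axes."""

    dx: float
    dy: float
    dz: float

    def __post_init__(self) -> None:
        if min(self.dx, self.dy, self.dz) <= 0:
            raise ValueError("voxel dimensions must be strictly positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.dx, self.dy, self.dz], dtype=float)

    @property
    def volume_mm3(self) -> float:
        return float(self.dx * self.dy * self.dz)


@dataclass
class Volume:
    """A 3-D array plus the 4x4 affine mapping voxel indices to world mm.

    ``data`` may be scalar intensity, a binary label in {0, 1}, or an
    integer segment code.  All volumes in one study are assumed to share
    grid shape and affine (the co-registration contract); operations that
    combine volumes check this.
    """

    data: np.ndarray
    affine: np.ndarray
    frame: str = field(default="world-RAS")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3-D volume, got {self.data.ndim}-D")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_dims(self) -> VoxelDims:
        return voxel_dimensions(self.affine)

    def is_binary(self) -> bool:
        return bool(np.isin(self.data, (0, 1)).all())

    def same_grid(self, other: "Volume", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def require_same_grid(self, other: "Volume") -> None:
        if not self.same_grid(other):
            raise ValueError("volumes are not on the same grid (shape/affine mismatch)")

    def with_data(self, data: np.ndarray) -> "Volume":
        return Volume(data=data, affine=self.affine.copy(), frame=self.frame)


def read_volume(path) -> Volume:
    """Load a NIfTI-1 volume, reoriented to RAS+.

    Integer-coded label images are preserved without rescaling (the raw
    on-disk array is used when no scaling is declared).
    """
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise ValueError(f"expected 3-D volume, got shape {img.shape}")
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    return Volume(data=np.asarray(data), affine=np.asarray(img.affine))


def write_volume(v: Volume, path) -> None:
    """Write a volume as NIfTI-1; integer data keeps an integer dtype."""
    data = v.data
    if np.issubdtype(data.dtype, np.bool_):
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, v.affine)
    img.header.set_data_dtype(data.dtype)
    nib.save(img, str(path))


def voxel_dimensions(affine: np.ndarray) -> VoxelDims:
    """Voxel edge lengths = Euclidean norms of the affine's spatial columns."""
    affine = np.asarray(affine, dtype=float)
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("affine is singular")
    norms = np.linalg.norm(affine[:3, :3], axis=0)
    return VoxelDims(*norms)


def voxel_to_world(v: Volume, index) -> np.ndarray:
    """World-mm position of a voxel center (or an array of N x 3 indices)."""
    idx = np.atleast_2d(np.asarray(index, dtype=float))
    pts = idx @ v.affine[:3, :3].T + v.affine[:3, 3]
    return pts[0] if np.ndim(index) == 1 else pts


def world_to_voxel(v: Volume, point) -> np.ndarray:
    """Continuous voxel index of a world-mm point; may lie outside the grid."""
    inv = np.linalg.inv(v.affine)
    pts = np.atleast_2d(np.asarray(point, dtype=float))
    idx = pts @ inv[:3, :3].T + inv[:3, 3]
    return idx[0] if np.ndim(point) == 1 else idx


def point_in_mask(mask: Volume, point) -> np.ndarray:
    """Voxel-center membership test: True where the containing voxel is set.

    ``point`` is one mm point or an (N, 3) array; the containing voxel is
    the nearest voxel center (round-half-up of the continuous index).
    """
    idx = np.atleast_2d(world_to_voxel(mask, point))
    ijk = np.round(idx).astype(int)
    inside = np.all((ijk >= 0) & (ijk < np.array(mask.shape)), axis=1)
    hit = np.zeros(len(ijk), dtype=bool)
    if inside.any():
        sel = ijk[inside]
        hit[inside] = mask.data[sel[:, 0], sel[:, 1], sel[:, 2]] > 0
    return hit[0] if np.ndim(point) == 1 else hit


def distance_to_mask(grid: Volume, voxel_dims: VoxelDims | None = None) -> Volume:
    """Euclidean distance (mm) from every voxel center to the nearest
    voxel center where ``grid`` is 1; zero inside the mask.

    Anisotropy-aware: distances use the physical voxel edge lengths.  An
    empty mask yields all-infinite distances with a warning.
    """
    if not grid.is_binary():
        raise ValueError("distance_to_mask expects a binary mask")
    if voxel_dims is None:
        voxel_dims = grid.voxel_dims
    mask = grid.data.astype(bool)
    if not mask.any():
        warnings.warn("distance_to_mask: empty mask, distances are infinite")
        return grid.with_data(np.full(grid.shape, np.inf))
    dist = ndimage.distance_transform_edt(~mask, sampling=voxel_dims.as_array())
    return grid.with_data(np.asarray(dist, dtype=float))
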