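"""Single-tensor DTI fitting, FA, deterministic streamline tracking, and
connection-presence decisions between cortical/subcortical ROIs and putamen
segments.

Tracking is fixed-step bidirectional Euler integration along the principal
eigenvector field with trilinear interpolation of the six unique tensor
components.  Stopping criteria follow routine clinical deterministic
tractography: a fractional-anisotropy floor, a per-step turning-angle cap,
leaving the brain mask, and a step budget; tracks shorter than a minimum
length are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume import Volume, point_in_mask, voxel_to_world, world_to_voxel

__all__ = [
    "TensorField",
    "TrackingCriteria",
    "Streamline",
    "fit_tensor",
    "fractional_anisotropy",
    "track_streamline",
    "track_from_segment",
    "connection_present",
    "connectivity_counts",
]

# Order of the six unique tensor components everywhere in this module.
_COMP = ("xx", "yy", "zz", "xy", "xz", "yz")
LAMBDA_MIN = 1e-7  # mm^2/s eigenvalue clamp inside the validity mask


def _to_matrices(comp6: np.ndarray) -> np.ndarray:
    """(..., 6) component stack -> (..., 3, 3) symmetric matrices."""
    comp6 = np.asarray(comp6, dtype=float)
    m = np.empty(comp6.shape[:-1] + (3, 3), dtype=float)
    m[..., 0, 0] = comp6[..., 0]
    m[..., 1, 1] = comp6[..., 1]
    m[..., 2, 2] = comp6[..., 2]
    m[..., 0, 1] = m[..., 1, 0] = comp6[..., 3]
    m[..., 0, 2] = m[..., 2, 0] = comp6[..., 4]
    m[..., 1, 2] = m[..., 2, 1] = comp6[..., 5]
    return m


def _to_comp6(matrices: np.ndarray) -> np.ndarray:
    m = np.asarray(matrices, dtype=float)
    return np.stack(
        [m[..., 0, 0], m[..., 1, 1], m[..., 2, 2], m[..., 0, 1], m[..., 0, 2], m[..., 1, 2]],
        axis=-1,
    )


@dataclass
class TensorField:
    """Per-voxel symmetric diffusion tensor stored as 6 unique components.

    ``components`` has shape (X, Y, Z, 6) in the order xx, yy, zz, xy, xz,
    yz (mm^2/s); ``valid`` marks voxels with a usable fit (brain and
    positive signal).  Eigenvalues inside the validity mask are clamped to
    ``LAMBDA_MIN`` on construction via :func:`fit_tensor`.
    """

    components: np.ndarray
    affine: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.components.ndim != 4 or self.components.shape[-1] != 6:
            raise ValueError("components must have shape (X, Y, Z, 6)")
        if self.valid.shape != self.components.shape[:3]:
            raise ValueError("validity mask shape mismatch")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.components.shape[:3]

    def tensor_at_voxel(self, ijk) -> np.ndarray:
        i, j, k = ijk
        return _to_matrices(self.components[i, j, k])

    def interpolate(self, points_mm: np.ndarray) -> np.ndarray:
        """Trilinearly interpolated 3x3 tensors at world-mm points."""
        grid_vol = Volume(self.valid.astype(np.uint8), self.affine)
        idx = np.atleast_2d(world_to_voxel(grid_vol, points_mm)).T  # (3, N)
        comp = np.stack(
            [
                ndimage.map_coordinates(self.components[..., c], idx, order=1, mode="nearest")
                for c in range(6)
            ],
            axis=-1,
        )
        mats = _to_matrices(comp)
        return mats[0] if np.ndim(points_mm) == 1 else mats

    @classmethod
    def from_matrices(cls, matrices: np.ndarray, affine: np.ndarray, valid: np.ndarray) -> "TensorField":
        return cls(components=_to_comp6(matrices), affine=affine, valid=valid)


@dataclass
class TrackingCriteria:
    """Deterministic-tracking stop criteria.

    Defaults are the routine clinical settings: FA floor 0.2, minimum
    retained length 20 mm, maximum per-step turning angle 50 degrees.  The
    1 mm step is half the smallest voxel edge at the default 2 mm
    isotropic resolution.
    """

    fa_min: float = 0.2
    length_min: float = 20.0
    angle_max: float = 50.0
    step_mm: float = 1.0
    max_steps: int = 500
    seeds_per_voxel: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.fa_min < 1:
            raise ValueError("fa_min must lie in (0, 1)")
        if not 0 < self.angle_max < 90:
            raise ValueError("angle_max must lie in (0, 90) degrees")
        if self.step_mm <= 0:
            raise ValueError("step_mm must be positive")


@dataclass
class Streamline:
    """Ordered mm points of one track, with provenance metadata."""

    points: np.ndarray
    seed_segment: int = 0
    visited_rois: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)

    @property
    def length(self) -> float:
        if len(self.points) < 2:
            return 0.0
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


def fit_tensor(dwi: np.ndarray, gradients: np.ndarray, bvals: np.ndarray,
               brain: Volume | None = None, affine: np.ndarray | None = None) -> TensorField:
    """Log-linear least-squares single-tensor fit per voxel.

    Solves ``ln S_i = ln S0 - b_i g_i^T D g_i`` for (ln S0, 6 tensor
    components) by one pseudo-inverse of the shared design matrix.  At
    least one b~0 volume (or >1 distinct b-value) is required, otherwise
    the intercept is collinear with the tensor trace.  Voxels with any
    non-positive signal are marked invalid rather than NaN; negative
    eigenvalues are clamped to ``LAMBDA_MIN``.
    """
    dwi = np.asarray(dwi, dtype=float)
    gradients = np.asarray(gradients, dtype=float)
    bvals = np.asarray(bvals, dtype=float)
    if dwi.ndim != 4:
        raise ValueError("dwi must be 4-D (X, Y, Z, n_volumes)")
    n_vol = dwi.shape[-1]
    if gradients.shape != (n_vol, 3) or bvals.shape != (n_vol,):
        raise ValueError("gradient table does not match the number of volumes")
    weighted = bvals > 0
    if weighted.sum() < 6:
        raise ValueError("at least 6 diffusion-weighted directions required")
    g = gradients
    design = np.column_stack(
        [
            np.ones(n_vol),
            -bvals * g[:, 0] ** 2,
            -bvals * g[:, 1] ** 2,
            -bvals * g[:, 2] ** 2,
            -bvals * 2 * g[:, 0] * g[:, 1],
            -bvals * 2 * g[:, 0] * g[:, 2],
            -bvals * 2 * g[:, 1] * g[:, 2],
        ]
    )
    if np.linalg.matrix_rank(design) < 7:
        raise ValueError("gradient directions are collinear / design matrix rank-deficient")
    if affine is None:
        if brain is None:
            raise ValueError("provide an affine or a brain-mask Volume")
        affine = brain.affine
    shape = dwi.shape[:3]
    valid = np.all(dwi > 0, axis=-1)
    if brain is not None:
        valid &= brain.data.astype(bool)
    comp = np.zeros(shape + (6,), dtype=float)
    if valid.any():
        logs = np.log(dwi[valid])                      # (N, n_vol)
        coef = logs @ np.linalg.pinv(design).T          # (N, 7)
        d6 = coef[:, 1:]
        mats = _to_matrices(d6)
        w, v = np.linalg.eigh(mats)
        w = np.maximum(w, LAMBDA_MIN)
        mats = np.einsum("nij,nj,nkj->nik", v, w, v)
        comp[valid] = _to_comp6(mats)
    return TensorField(components=comp, affine=affine, valid=valid)


def fractional_anisotropy(t: np.ndarray) -> float | np.ndarray:
    """FA of one or many symmetric tensors.

    ``FA = sqrt(3/2) * ||lambda - mean(lambda)|| / ||lambda||`` over the
    eigenvalue vector; 0 for the zero (or isotropic) tensor, 1 in the
    rank-1 limit.
    """
    t = np.asarray(t, dtype=float)
    if t.shape[-1] == 6 and (t.ndim == 1 or t.shape[-2:] != (3, 3)):
        t = _to_matrices(t)
    w = np.linalg.eigvalsh(t)
    norm = np.linalg.norm(w, axis=-1)
    dev = w - w.mean(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * np.linalg.norm(dev, axis=-1) / norm
    fa = np.where(norm > 0, fa, 0.0)
    return float(fa) if fa.ndim == 0 else fa


def _principal_direction(tensor: np.ndarray) -> tuple[np.ndarray, float]:
    w, v = np.linalg.eigh(tensor)
    return v[:, -1], fractional_anisotropy(tensor)


def _track_one_side(field: TensorField, brain: Volume, seed: np.ndarray,
                    direction: np.ndarray, criteria: TrackingCriteria) -> list[np.ndarray]:
    cos_max = np.cos(np.radians(criteria.angle_max))
    pts: list[np.ndarray] = []
    pos = np.asarray(seed, dtype=float)
    d = np.asarray(direction, dtype=float)
    for _ in range(criteria.max_steps):
        nxt = pos + criteria.step_mm * d
        if not point_in_mask(brain, nxt):
            break
        tensor = field.interpolate(nxt)
        if fractional_anisotropy(tensor) < criteria.fa_min:
            break
        v, _ = _principal_direction(tensor)
        if v @ d < 0:  # eigenvectors are sign-ambiguous; align with travel
            v = -v
        if v @ d < cos_max:
            break
        pts.append(nxt)
        pos, d = nxt, v
    return pts


def track_streamline(field: TensorField, seed, criteria: TrackingCriteria,
                     brain: Volume, seed_segment: int = 0) -> Streamline | None:
    """Bidirectional Euler tracking from one seed point (world mm).

    Both half-tracks start along +/- the principal eigenvector at the
    seed and are concatenated; ``None`` is returned when the seed fails
    the FA floor or the joined track is shorter than ``length_min``.
    """
    seed = np.asarray(seed, dtype=float)
    if not point_in_mask(brain, seed):
        raise ValueError("seed lies outside the brain mask")
    tensor = field.interpolate(seed)
    if fractional_anisotropy(tensor) < criteria.fa_min:
        return None
    v0, _ = _principal_direction(tensor)
    fwd = _track_one_side(field, brain, seed, v0, criteria)
    bwd = _track_one_side(field, brain, seed, -v0, criteria)
    pts = bwd[::-1] + [seed] + fwd
    sl = Streamline(points=np.array(pts), seed_segment=seed_segment)
    if sl.length < criteria.length_min:
        return None
    return sl


def track_from_segment(field: TensorField, segment: Volume, criteria: TrackingCriteria,
                       brain: Volume, segment_code: int = 0) -> list[Streamline]:
    """Seed one streamline per segment voxel center; keep retained tracks."""
    idx = np.argwhere(segment.data > 0)
    seeds = voxel_to_world(segment, idx)
    out = []
    for seed in np.atleast_2d(seeds):
        sl = track_streamline(field, seed, criteria, brain, seed_segment=segment_code)
        if sl is not None:
            out.append(sl)
    return out


def connection_present(streamlines, roi: Volume, segment: Volume) -> bool:
    """True iff >= 1 retained streamline has a point in the ROI *and* a
    point in the putamen segment (traversal semantics)."""
    roi.require_same_grid(segment)
    for sl in streamlines:
        in_roi = point_in_mask(roi, sl.points)
        if not in_roi.any():
            continue
        if point_in_mask(segment, sl.points).any():
            return True
    return False


def connectivity_counts(subject_matrices: list[pd.DataFrame]) -> pd.DataFrame:
    """Sum per-hemisphere boolean connection matrices into presence counts.

    Each input is a (region x segment) boolean DataFrame for one
    hemisphere; the output entry is the number of hemispheres with a
    present connection, bounded by the number of matrices (2 per subject
    in a bilateral cohort).
    """
    if not subject_matrices:
        raise ValueError("no connection matrices supplied")
    first = subject_matrices[0]
    total = pd.DataFrame(0, index=first.index, columns=first.columns, dtype=int)
    for m in subject_matrices:
        if not (m.index.equals(first.index) and m.columns.equals(first.columns)):
            raise ValueError("inconsistent region/segment sets across hemispheres")
        total += m.astype(int)
    return total
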