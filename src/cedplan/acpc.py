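"""AC-PC stereotactic frame and four-quadrant putamen parcellation.

The putamen is split into superior-anterior, superior-posterior,
inferior-posterior and inferior-anterior segments by two planes anchored at
the anterior commissure (AC): the axial plane containing the AC-PC line,
and the coronal plane perpendicular to it.  This mirrors routine
stereotactic practice, where AC and PC are reliably identifiable landmarks,
at the cost of unequally sized segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .volume import Volume, voxel_to_world

__all__ = [
    "ACPCFrame",
    "PutamenParcellation",
    "SEGMENT_CODES",
    "SEGMENT_NAMES",
    "build_acpc_frame",
    "parcellate_putamen",
]

# Label codes for the four quadrants.
SEGMENT_CODES = {
    "superior-anterior": 1,
    "superior-posterior": 2,
    "inferior-posterior": 3,
    "inferior-anterior": 4,
}
SEGMENT_NAMES = {v: k for k, v in SEGMENT_CODES.items()}


@dataclass
class ACPCFrame:
    """Anatomical axes derived from AC, PC and a superior reference point.

    ``y_ap`` points anterior (PC toward AC), ``z_si`` superior (the third
    landmark orthogonalized against the AC-PC line), ``x_lr = y_ap x z_si``.
    The axes are orthonormal and right-handed in RAS+.
    """

    ac: np.ndarray
    pc: np.ndarray
    ih: np.ndarray
    y_ap: np.ndarray = field(init=False)
    z_si: np.ndarray = field(init=False)
    x_lr: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.ac = np.asarray(self.ac, dtype=float)
        self.pc = np.asarray(self.pc, dtype=float)
        self.ih = np.asarray(self.ih, dtype=float)
        ap = self.ac - self.pc
        n_ap = np.linalg.norm(ap)
        if n_ap < 1e-9:
            raise ValueError("AC and PC coincide")
        y = ap / n_ap
        si = self.ih - self.ac
        si = si - (si @ y) * y  # Gram-Schmidt against the AC-PC axis
        n_si = np.linalg.norm(si)
        if n_si < 1e-9:
            raise ValueError("superior reference point is collinear with the AC-PC line")
        z = si / n_si
        self.y_ap = y
        self.z_si = z
        self.x_lr = np.cross(y, z)


def build_acpc_frame(ac, pc, ih) -> ACPCFrame:
    """Construct the AC-PC frame from three landmark points in mm."""
    return ACPCFrame(ac=np.asarray(ac), pc=np.asarray(pc), ih=np.asarray(ih))


@dataclass
class PutamenParcellation:
    """Quadrant label volume (codes 1-4) with per-segment volumetry."""

    labels: Volume
    hemisphere: str
    counts: dict[str, int]
    volumes_mm3: dict[str, float]

    def segment_mask(self, segment: str | int) -> Volume:
        code = SEGMENT_CODES[segment] if isinstance(segment, str) else segment
        return self.labels.with_data((self.labels.data == code).astype(np.uint8))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "segment": list(self.counts),
                "voxels": list(self.counts.values()),
                "volume_mm3": list(self.volumes_mm3.values()),
            }
        )


def classify_points(points: np.ndarray, frame: ACPCFrame) -> np.ndarray:
    """Quadrant code of each mm point relative to the AC anchor.

    Superior iff (p - ac) . z_si >= 0, anterior iff (p - ac) . y_ap >= 0
    (boundary points go to superior / anterior — a deterministic tie-break
    on a measure-zero set).
    """
    rel = np.atleast_2d(points) - frame.ac
    superior = rel @ frame.z_si >= 0
    anterior = rel @ frame.y_ap >= 0
    codes = np.where(
        superior,
        np.where(anterior, SEGMENT_CODES["superior-anterior"], SEGMENT_CODES["superior-posterior"]),
        np.where(anterior, SEGMENT_CODES["inferior-anterior"], SEGMENT_CODES["inferior-posterior"]),
    )
    return codes


def parcellate_putamen(
    putamen: Volume, frame: ACPCFrame, hemisphere: str = "unknown"
) -> PutamenParcellation:
    """Split a binary putamen mask into the four AC-anchored quadrants.

    The four labels partition the mask exactly: every putamen voxel gets
    exactly one code, non-putamen voxels get 0.
    """
    if not putamen.is_binary():
        raise ValueError("putamen mask must be binary")
    mask = putamen.data.astype(bool)
    if not mask.any():
        raise ValueError("putamen mask is empty")
    idx = np.argwhere(mask)
    centers = voxel_to_world(putamen, idx)
    codes = classify_points(centers, frame)
    labels = np.zeros(putamen.shape, dtype=np.int16)
    labels[mask] = codes
    vox_mm3 = putamen.voxel_dims.volume_mm3
    counts = {name: int((codes == code).sum()) for name, code in SEGMENT_CODES.items()}
    volumes = {name: c * vox_mm3 for name, c in counts.items()}
    return PutamenParcellation(
        labels=putamen.with_data(labels),
        hemisphere=hemisphere,
        counts=counts,
        volumes_mm3=volumes,
    )
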