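"""Straight stereotactic trajectories: sampling, valid in-segment centers,
and safety classification against a margin around critical structures.

A trajectory is the entry->target line of a planned catheter.  It is
discretized into 100 equidistant sample points (both endpoints included);
the sample points whose voxel falls inside the target putamen segment are
the *valid centers* — the only admissible infusion-sphere centers.  Safety
is a hard margin test: the trajectory is safe iff every sample point keeps
at least ``margin_mm`` (default 2 mm) of interpolated Euclidean distance
from every critical-structure mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import Volume, point_in_mask, world_to_voxel

__all__ = [
    "Trajectory",
    "SafetyConfig",
    "SafetyResult",
    "sample_trajectory",
    "valid_centers",
    "classify_safety",
]

N_SAMPLE_POINTS = 100


@dataclass
class SafetyConfig:
    margin_mm: float = 2.0

    def __post_init__(self) -> None:
        if self.margin_mm < 0:
            raise ValueError("margin must be non-negative")


@dataclass
class SafetyResult:
    safe: bool
    min_distance_mm: float
    min_distances: dict[str, float]
    offending_structure: str | None


@dataclass
class Trajectory:
    """Entry->target line with its samples and in-segment valid centers."""

    entry: np.ndarray
    target: np.ndarray
    approach: str = "frontal"
    hemisphere: str = "right"
    n_points: int = N_SAMPLE_POINTS
    sample_points: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.entry = np.asarray(self.entry, dtype=float)
        self.target = np.asarray(self.target, dtype=float)
        self.sample_points = sample_trajectory(self.entry, self.target, self.n_points)

    @property
    def spacing_mm(self) -> float:
        return float(np.linalg.norm(self.target - self.entry) / (self.n_points - 1))

    def valid_centers(self, segment: Volume) -> np.ndarray:
        return valid_centers(self, segment)

    def in_segment_length(self, segment: Volume) -> float:
        """Path length (mm) spent inside the segment: spacing summed over
        consecutive in-segment sample pairs."""
        inside = point_in_mask(segment, self.sample_points)
        pairs = int(np.sum(inside[:-1] & inside[1:]))
        return pairs * self.spacing_mm


def sample_trajectory(entry, target, n_points: int = N_SAMPLE_POINTS) -> np.ndarray:
    """n equidistant points from entry to target inclusive (spacing
    ||target - entry|| / (n - 1))."""
    entry = np.asarray(entry, dtype=float)
    target = np.asarray(target, dtype=float)
    if np.allclose(entry, target):
        raise ValueError("entry and target coincide")
    t = np.linspace(0.0, 1.0, n_points)[:, None]
    return entry + t * (target - entry)


def valid_centers(traj: Trajectory, segment: Volume) -> np.ndarray:
    """Sample points whose containing voxel lies in the segment mask, in
    path order.  May be empty (trajectory misses the segment — unusable
    for infusion, which is distinct from unsafe)."""
    inside = point_in_mask(segment, traj.sample_points)
    return traj.sample_points[inside]


def _interp_distance(dmap: Volume, points: np.ndarray) -> np.ndarray:
    idx = np.atleast_2d(world_to_voxel(dmap, points)).T
    return ndimage.map_coordinates(dmap.data, idx, order=1, mode="nearest")


def classify_safety(traj: Trajectory, cfg: SafetyConfig,
                    distance_maps: dict[str, Volume]) -> SafetyResult:
    """Hard margin test against per-structure distance maps.

    Distances at sub-voxel sample points are trilinearly interpolated from
    the voxel-wise maps.  With no critical structures configured the
    trajectory is trivially safe.
    """
    mins: dict[str, float] = {}
    for name, dmap in distance_maps.items():
        d = _interp_distance(dmap, traj.sample_points)
        mins[name] = float(np.min(d))
    if not mins:
        return SafetyResult(True, np.inf, {}, None)
    worst = min(mins, key=mins.get)
    safe = mins[worst] >= cfg.margin_mm
    return SafetyResult(safe, mins[worst], mins, None if safe else worst)
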