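"""Sphere-based infusion simulation optimized by a genetic algorithm.

Drug infusion from a catheter point is modelled as an instantaneous
isotropic sphere; a plan is an ordered list of (center, radius) spheres
whose centers must come from the trajectory's valid in-segment centers.
Spheres that would cross the allowed region's boundary are penalized by a
deterministic radius shrink (phenotypic repair) before scoring.  Fitness is
the fraction of target-segment voxels covered by the union of spheres, and
a small elitist GA searches over sphere count, radii and center placement.

No convection-diffusion physics, anisotropy or backflow is modelled: the
spheres are a transparent geometric planning surrogate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume import Volume, point_in_mask, world_to_voxel

__all__ = [
    "Sphere",
    "InjectionPlan",
    "GAConfig",
    "InjectionResult",
    "sphere_mask",
    "optimize_radius",
    "coverage",
    "coverage_mask",
    "mutate",
    "crossover",
    "evaluate_plan",
    "optimize_injection",
]


@dataclass(frozen=True)
class Sphere:
    center: tuple[float, float, float]
    radius: float

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError("radius must be non-negative")


@dataclass
class InjectionPlan:
    spheres: list[Sphere]
    fitness: float | None = None


@dataclass
class GAConfig:
    """GA hyperparameters.  Only the generation count is dictated by the
    study design; the rest are package defaults, all exposed."""

    generations: int = 20
    population_size: int = 50
    crossover_prob: float = 0.7
    mutation_prob: float = 0.3
    tournament_size: int = 3
    n_spheres_max: int = 4
    radius_step_mm: float = 0.5
    radius_max_mm: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        for p in (self.crossover_prob, self.mutation_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class InjectionResult:
    feasible: bool
    plan: InjectionPlan | None
    coverage: float
    sphere_volumes_mm3: list[float]
    coverage_mask: Volume | None
    history: list[float]   # best fitness per generation (non-decreasing)


# --------------------------------------------------------------------------
# geometry

def _sphere_voxels(center, radius: float, grid: Volume):
    """(ijk array, mm-distance array) of voxels in a conservative box
    around the sphere; membership is distance <= radius at voxel centers."""
    center = np.asarray(center, dtype=float)
    c_idx = world_to_voxel(grid, center)
    dims = grid.voxel_dims.as_array()
    pad = np.ceil(radius / dims).astype(int) + 1
    lo = np.maximum(np.round(c_idx).astype(int) - pad, 0)
    hi = np.minimum(np.round(c_idx).astype(int) + pad, np.array(grid.shape) - 1)
    if np.any(lo > hi):
        return np.empty((0, 3), dtype=int), np.empty(0)
    ranges = [np.arange(lo[a], hi[a] + 1) for a in range(3)]
    ii, jj, kk = np.meshgrid(*ranges, indexing="ij")
    ijk = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=-1)
    pts = ijk @ grid.affine[:3, :3].T + grid.affine[:3, 3]
    dist = np.linalg.norm(pts - center, axis=1)
    return ijk, dist


def sphere_mask(center, radius: float, grid: Volume) -> Volume:
    """Binary mask of voxels whose centers lie within ``radius`` mm of
    ``center``; radius 0 gives exactly the containing voxel."""
    mask = np.zeros(grid.shape, dtype=np.uint8)
    if radius == 0:
        idx = np.round(world_to_voxel(grid, center)).astype(int)
        if np.all(idx >= 0) and np.all(idx < np.array(grid.shape)):
            mask[tuple(idx)] = 1
        return grid.with_data(mask)
    ijk, dist = _sphere_voxels(center, radius, grid)
    sel = ijk[dist <= radius]
    mask[sel[:, 0], sel[:, 1], sel[:, 2]] = 1
    return grid.with_data(mask)


def optimize_radius(center, requested_radius: float, allowed_roi: Volume,
                    step: float = 0.5) -> float:
    """Largest radius on the ladder requested - k*step (k >= 0, floored at
    0) whose voxel mask lies entirely inside ``allowed_roi``.

    This shrink is the penalty mechanism for spheres that would cross the
    anatomical boundary.  The center itself must be inside the ROI.
    """
    if not point_in_mask(allowed_roi, center):
        raise ValueError("sphere center lies outside the allowed ROI")
    if requested_radius <= 0:
        return 0.0
    ijk, dist = _sphere_voxels(center, requested_radius, allowed_roi)
    inside_roi = allowed_roi.data[ijk[:, 0], ijk[:, 1], ijk[:, 2]] > 0
    r = requested_radius
    while r > 0:
        violation = (dist <= r) & ~inside_roi
        if not violation.any():
            return float(r)
        r -= step
    return 0.0


def _union_mask(spheres: list[Sphere], grid: Volume) -> np.ndarray:
    union = np.zeros(grid.shape, dtype=bool)
    for s in spheres:
        if s.radius == 0:
            idx = np.round(world_to_voxel(grid, s.center)).astype(int)
            if np.all(idx >= 0) and np.all(idx < np.array(grid.shape)):
                union[tuple(idx)] = True
            continue
        ijk, dist = _sphere_voxels(s.center, s.radius, grid)
        sel = ijk[dist <= s.radius]
        union[sel[:, 0], sel[:, 1], sel[:, 2]] = True
    return union


def coverage(plan: InjectionPlan, target_segment: Volume) -> float:
    """|union of sphere masks ∩ segment| / |segment| by voxel count
    (overlap counted once)."""
    seg = target_segment.data > 0
    n_seg = int(seg.sum())
    if n_seg == 0:
        raise ValueError("empty target segment")
    union = _union_mask(plan.spheres, target_segment)
    return float((union & seg).sum() / n_seg)


def coverage_mask(plan: InjectionPlan, grid: Volume) -> Volume:
    return grid.with_data(_union_mask(plan.spheres, grid).astype(np.uint8))


# --------------------------------------------------------------------------
# GA operators

def mutate(plan: InjectionPlan, valid_centers: np.ndarray,
           rng: np.random.Generator) -> InjectionPlan:
    """Replace exactly one sphere's center with a uniformly drawn valid
    center; radii and sphere count are untouched."""
    centers = np.atleast_2d(valid_centers)
    if len(centers) == 0:
        raise ValueError("no valid centers to mutate toward")
    spheres = list(plan.spheres)
    i = int(rng.integers(len(spheres)))
    new_center = centers[int(rng.integers(len(centers)))]
    spheres[i] = Sphere(tuple(new_center), spheres[i].radius)
    return InjectionPlan(spheres=spheres)


def crossover(a: InjectionPlan, b: InjectionPlan,
              rng: np.random.Generator) -> tuple[InjectionPlan, InjectionPlan]:
    """One-point tail swap at a shared cut c in [0, min(len a, len b)].

    The combined sphere multiset is conserved across the pair; offspring
    lengths are the parents' lengths swapped, so counts stay within the
    configured bounds.  Identical parents yield identical offspring.
    """
    if not a.spheres or not b.spheres:
        raise ValueError("crossover requires nonempty plans")
    c = int(rng.integers(0, min(len(a.spheres), len(b.spheres)) + 1))
    child1 = InjectionPlan(spheres=a.spheres[:c] + b.spheres[c:])
    child2 = InjectionPlan(spheres=b.spheres[:c] + a.spheres[c:])
    return child1, child2


def evaluate_plan(plan: InjectionPlan, target_segment: Volume, allowed_roi: Volume,
                  radius_step: float) -> tuple[float, InjectionPlan]:
    """Fitness of a plan: shrink each sphere to fit the allowed ROI, then
    score union coverage of the target segment.  Returns (fitness, the
    repaired plan with effective radii)."""
    repaired = [
        Sphere(s.center, optimize_radius(s.center, s.radius, allowed_roi, radius_step))
        for s in plan.spheres
    ]
    rp = InjectionPlan(spheres=repaired)
    fit = coverage(rp, target_segment)
    rp.fitness = fit
    return fit, rp


class _CachedEvaluator:
    """Memoized plan evaluation for one GA run.

    Centers come from a small discrete set and radii live on a ladder, so
    effective radii and per-sphere covered-voxel sets are cached; coverage
    is the size of the union of cached voxel-index sets.  Semantically
    identical to :func:`evaluate_plan`."""

    def __init__(self, target_segment: Volume, allowed_roi: Volume, radius_step: float):
        self.segment = target_segment
        self.allowed = allowed_roi
        self.step = radius_step
        seg = target_segment.data > 0
        self.n_seg = int(seg.sum())
        if self.n_seg == 0:
            raise ValueError("empty target segment")
        self._seg_flat = np.flatnonzero(seg.ravel())
        self._seg_set = frozenset(self._seg_flat.tolist())
        self._radius_cache: dict[tuple, float] = {}
        self._cover_cache: dict[tuple, frozenset] = {}

    def _eff_radius(self, s: Sphere) -> float:
        key = (s.center, s.radius)
        if key not in self._radius_cache:
            self._radius_cache[key] = optimize_radius(s.center, s.radius, self.allowed, self.step)
        return self._radius_cache[key]

    def _covered(self, center, radius: float) -> frozenset:
        key = (center, radius)
        if key not in self._cover_cache:
            m = sphere_mask(center, radius, self.segment).data.astype(bool).ravel()
            self._cover_cache[key] = frozenset(np.flatnonzero(m).tolist()) & self._seg_set
        return self._cover_cache[key]

    def __call__(self, plan: InjectionPlan) -> tuple[float, InjectionPlan]:
        repaired = [Sphere(s.center, self._eff_radius(s)) for s in plan.spheres]
        covered: set = set()
        for s in repaired:
            covered |= self._covered(s.center, s.radius)
        rp = InjectionPlan(spheres=repaired)
        rp.fitness = len(covered) / self.n_seg
        return rp.fitness, rp


def _random_plan(valid_centers: np.ndarray, cfg: GAConfig,
                 rng: np.random.Generator) -> InjectionPlan:
    n_levels = max(1, int(round(cfg.radius_max_mm / cfg.radius_step_mm)))
    n = int(rng.integers(1, cfg.n_spheres_max + 1))
    spheres = []
    for _ in range(n):
        c = valid_centers[int(rng.integers(len(valid_centers)))]
        r = cfg.radius_step_mm * int(rng.integers(1, n_levels + 1))
        spheres.append(Sphere(tuple(c), float(r)))
    return InjectionPlan(spheres=spheres)


def optimize_injection(valid_centers: np.ndarray, target_segment: Volume,
                       allowed_roi: Volume | None = None,
                       cfg: GAConfig | None = None) -> InjectionResult:
    """Elitist generational GA over injection plans.

    ``allowed_roi`` defaults to the target segment itself (conservative
    containment); pass the brain mask for the permissive mode.  An empty
    valid-center list yields a distinct infeasible outcome rather than an
    error.  The run is fully reproducible from ``cfg.seed``.
    """
    cfg = cfg or GAConfig()
    centers = np.atleast_2d(np.asarray(valid_centers, dtype=float))
    if centers.size == 0:
        return InjectionResult(False, None, 0.0, [], None, [])
    allowed = allowed_roi if allowed_roi is not None else target_segment
    target_segment.require_same_grid(allowed)
    rng = np.random.default_rng(cfg.seed)
    evaluate = _CachedEvaluator(target_segment, allowed, cfg.radius_step_mm)

    pop = [_random_plan(centers, cfg, rng) for _ in range(cfg.population_size)]
    scored = [evaluate(p) for p in pop]
    best_fit, best_plan = max(scored, key=lambda t: t[0])
    history = [best_fit]

    def tournament() -> InjectionPlan:
        picks = rng.integers(len(scored), size=cfg.tournament_size)
        winner = max(picks, key=lambda i: scored[i][0])
        return pop[winner]

    for _ in range(cfg.generations):
        offspring: list[InjectionPlan] = []
        while len(offspring) < cfg.population_size - 1:
            p1, p2 = tournament(), tournament()
            c1 = InjectionPlan(spheres=list(p1.spheres))
            c2 = InjectionPlan(spheres=list(p2.spheres))
            if rng.random() < cfg.crossover_prob:
                c1, c2 = crossover(c1, c2, rng)
            for child in (c1, c2):
                if rng.random() < cfg.mutation_prob:
                    child = mutate(child, centers, rng)
                offspring.append(child)
        offspring = offspring[: cfg.population_size - 1]
        pop = offspring
        scored = [evaluate(p) for p in pop]
        gen_fit, gen_plan = max(scored, key=lambda t: t[0])
        if gen_fit > best_fit:
            best_fit, best_plan = gen_fit, gen_plan
        # elitism: the incumbent survives into the pool considered next round
        pop.append(InjectionPlan(spheres=list(best_plan.spheres)))
        scored.append((best_fit, best_plan))
        history.append(best_fit)

    vox_mm3 = target_segment.voxel_dims.volume_mm3
    volumes = [
        float(sphere_mask(s.center, s.radius, target_segment).data.sum() * vox_mm3)
        for s in best_plan.spheres
    ]
    cov_mask = coverage_mask(best_plan, target_segment)
    return InjectionResult(True, best_plan, best_fit, volumes, cov_mask, history)
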