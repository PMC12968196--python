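from itertools import combinations_with_replacement

import numpy as np
import pytest
from scipy.stats import chisquare

from cedplan import (GAConfig, InjectionPlan, Sphere, coverage, crossover,
                     distance_to_mask, mutate, optimize_injection,
                     optimize_radius, sphere_mask)
from cedplan.volume import point_in_mask, voxel_to_world

from conftest import make_volume


def ball_roi(shape=(14, 14, 14), center=(7, 7, 7), r=5.0, voxel=1.0):
    idx = np.indices(shape).reshape(3, -1).T * voxel
    inside = np.linalg.norm(idx - np.asarray(center), axis=1) <= r
    data = np.zeros(shape, dtype=np.uint8)
    data.ravel()[inside] = 1
    return make_volume(data, voxel=voxel)


class TestSphereMask:
    def test_radius_zero_single_voxel(self):
        grid = make_volume(np.zeros((9, 9, 9), np.uint8))
        m = sphere_mask((4.2, 3.9, 4.0), 0.0, grid)
        assert m.data.sum() == 1 and m.data[4, 4, 4] == 1

    def test_matches_brute_force_count(self):
        grid = make_volume(np.zeros((15, 15, 15), np.uint8))
        m = sphere_mask((7.0, 7.0, 7.0), 5.0, grid)
        idx = np.indices((15, 15, 15)).reshape(3, -1).T.astype(float)
        brute = int(np.sum(np.linalg.norm(idx - 7.0, axis=1) <= 5.0))
        assert int(m.data.sum()) == brute

    def test_reflection_symmetry(self):
        grid = make_volume(np.zeros((11, 11, 11), np.uint8))
        m = sphere_mask((5.0, 5.0, 5.0), 3.7, grid).data
        np.testing.assert_array_equal(m, m[::-1])
        np.testing.assert_array_equal(m, m[:, ::-1])


class TestOptimizeRadius:
    def test_deep_center_keeps_request(self):
        roi = ball_roi(r=6.0)
        assert optimize_radius((7, 7, 7), 2.0, roi, step=0.5) == 2.0

    def test_shrink_bounded_by_distance_to_complement(self):
        """The EDT of the ROI complement bounds the feasible radius."""
        roi = ball_roi(r=5.0)
        center = (7.0, 7.0, 10.0)  # ~2 mm from the boundary
        r = optimize_radius(center, 10.0, roi, step=0.5)
        comp = roi.with_data(1 - roi.data)
        d_free = distance_to_mask(comp).data[7, 7, 10]
        assert r < d_free + 0.5
        audit = sphere_mask(center, r, roi)
        assert not (audit.data.astype(bool) & ~roi.data.astype(bool)).any()

    def test_single_voxel_roi_shrinks_to_center_voxel(self):
        roi = make_volume(np.zeros((7, 7, 7), np.uint8))
        roi.data[3, 3, 3] = 1
        r = optimize_radius((3, 3, 3), 5.0, roi, step=0.5)
        assert r < 1.0  # below the nearest-neighbor distance
        assert sphere_mask((3, 3, 3), r, roi).data.sum() == 1

    def test_center_outside_roi_rejected(self):
        roi = ball_roi()
        with pytest.raises(ValueError, match="outside"):
            optimize_radius((0, 0, 0), 1.0, roi)


class TestCoverage:
    def test_enclosing_sphere_full_coverage(self):
        seg = ball_roi(r=3.0)
        plan = InjectionPlan([Sphere((7, 7, 7), 10.0)])
        assert coverage(plan, seg) == 1.0

    def test_union_idempotence(self):
        seg = ball_roi(r=4.0)
        one = InjectionPlan([Sphere((7, 7, 7), 2.5)])
        two = InjectionPlan([Sphere((7, 7, 7), 2.5)] * 2)
        assert coverage(two, seg) == coverage(one, seg)

    def test_hand_built_case_matches_exhaustive_count(self):
        seg = make_volume(np.zeros((12, 12, 12), np.uint8))
        seg.data[2:10, 2:10, 2:10] = 1  # 8^3 cube
        plan = InjectionPlan([Sphere((5.0, 5.0, 5.0), 2.0)])
        idx = np.indices((12, 12, 12)).reshape(3, -1).T.astype(float)
        in_sphere = np.linalg.norm(idx - 5.0, axis=1) <= 2.0
        in_seg = seg.data.ravel() > 0
        assert coverage(plan, seg) == pytest.approx(
            np.sum(in_sphere & in_seg) / in_seg.sum())

    def test_adding_a_sphere_never_decreases_coverage(self, rng):
        seg = ball_roi(r=5.0)
        spheres = [Sphere(tuple(rng.uniform(4, 10, 3)), rng.uniform(0.5, 3))
                   for _ in range(5)]
        covs = [coverage(InjectionPlan(spheres[:k]), seg) for k in range(1, 6)]
        assert all(b >= a for a, b in zip(covs, covs[1:]))

    def test_empty_segment_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            coverage(InjectionPlan([Sphere((0, 0, 0), 1.0)]),
                     make_volume(np.zeros((4, 4, 4), np.uint8)))


class TestOperators:
    def test_mutation_single_center_noop(self, rng):
        plan = InjectionPlan([Sphere((1.0, 1.0, 1.0), 2.0)])
        out = mutate(plan, np.array([[1.0, 1.0, 1.0]]), rng)
        assert out.spheres == plan.spheres

    def test_mutation_changes_at_most_one_center(self, rng):
        centers = np.arange(12, dtype=float).reshape(4, 3)
        plan = InjectionPlan([Sphere(tuple(c), 2.0) for c in centers[:3]])
        out = mutate(plan, centers, rng)
        assert len(out.spheres) == 3
        assert [s.radius for s in out.spheres] == [2.0] * 3
        n_diff = sum(a.center != b.center for a, b in zip(plan.spheres, out.spheres))
        assert n_diff <= 1

    def test_mutation_draws_centers_uniformly(self, rng):
        centers = np.arange(12, dtype=float).reshape(4, 3)
        plan = InjectionPlan([Sphere((99.0, 99.0, 99.0), 1.0)])
        hits = {tuple(c): 0 for c in centers}
        for _ in range(10_000):
            out = mutate(plan, centers, rng)
            hits[out.spheres[0].center] += 1
        stat, p = chisquare(list(hits.values()))
        assert p > 1e-4  # consistent with uniform draw

    def test_crossover_cut_zero_swaps_parents(self):
        a = InjectionPlan([Sphere((float(i), 0, 0), 1.0) for i in range(3)])
        b = InjectionPlan([Sphere((float(i), 9, 9), 1.0) for i in range(3)])

        class CutZero:
            def integers(self, *args, **kw):
                return 0
        c1, c2 = crossover(a, b, CutZero())
        assert c1.spheres == b.spheres and c2.spheres == a.spheres

    def test_crossover_conserves_sphere_multiset(self, rng):
        a = InjectionPlan([Sphere((float(i), 0, 0), 1.0) for i in range(4)])
        b = InjectionPlan([Sphere((float(i), 9, 9), 2.0) for i in range(2)])
        for _ in range(20):
            c1, c2 = crossover(a, b, rng)
            combined = sorted(c1.spheres + c2.spheres, key=str)
            assert combined == sorted(a.spheres + b.spheres, key=str)
            assert {len(c1.spheres), len(c2.spheres)} == {2, 4}

    def test_identical_parents_identical_offspring(self, rng):
        a = InjectionPlan([Sphere((float(i), 1, 1), 1.5) for i in range(3)])
        b = InjectionPlan(list(a.spheres))
        c1, c2 = crossover(a, b, rng)
        assert c1.spheres == a.spheres and c2.spheres == a.spheres


# --------------------------------------------------------------------------
# independent exhaustive oracle for tiny instances

def oracle_effective_radius(center, radius, roi, step):
    data = roi.data.astype(bool)
    idx = np.indices(roi.shape).reshape(3, -1).T
    pts = voxel_to_world(roi, idx)
    dist = np.linalg.norm(pts - np.asarray(center), axis=1)
    r = radius
    while r > 0:
        covered = dist <= r
        if not np.any(covered & ~data.ravel()):
            return r
        r -= step
    return 0.0


def oracle_best_coverage(centers, seg, radius_levels, max_spheres, step):
    seg_flat = seg.data.ravel() > 0
    idx = np.indices(seg.shape).reshape(3, -1).T
    pts = voxel_to_world(seg, idx)
    genes = [(tuple(c), r) for c in centers for r in radius_levels]
    best = 0.0
    for n in range(1, max_spheres + 1):
        for combo in combinations_with_replacement(genes, n):
            covered = np.zeros(seg_flat.shape, dtype=bool)
            for c, r in combo:
                r_eff = oracle_effective_radius(c, r, seg, step)
                if r_eff == 0.0:
                    # a fully shrunk sphere still covers its containing voxel
                    covered[np.ravel_multi_index(
                        np.round(np.asarray(c)).astype(int), seg.shape)] = True
                else:
                    covered |= np.linalg.norm(pts - np.asarray(c), axis=1) <= r_eff
            best = max(best, np.sum(covered & seg_flat) / seg_flat.sum())
    return best


def tiny_instance(seed):
    rng = np.random.default_rng(seed)
    seg = ball_roi(shape=(14, 14, 14), center=tuple(rng.uniform(6, 8, 3)),
                   r=rng.uniform(3.5, 5.0))
    c0 = np.array([7.0, 7.0, 7.0]) + rng.uniform(-1, 1, 3)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    centers = np.array([c0 + (k - 2.5) * 1.5 * direction for k in range(6)])
    centers = centers[point_in_mask(seg, centers)]
    return seg, centers


class TestGeneticAlgorithm:
    CFG = GAConfig(generations=20, population_size=30, n_spheres_max=2,
                   radius_step_mm=1.0, radius_max_mm=3.0, seed=0)

    def test_single_center_single_sphere_is_brute_force_optimum(self):
        seg = ball_roi()
        centers = np.array([[7.0, 7.0, 7.0]])
        cfg = GAConfig(n_spheres_max=1, radius_step_mm=1.0, radius_max_mm=3.0, seed=1)
        res = optimize_injection(centers, seg, cfg=cfg)
        best = oracle_best_coverage(centers, seg, [1.0, 2.0, 3.0], 1, 1.0)
        assert res.coverage == pytest.approx(best)

    def test_never_beats_and_usually_matches_exhaustive(self):
        matches, total = 0, 10
        for seed in range(total):
            seg, centers = tiny_instance(seed)
            if len(centers) == 0:
                continue
            from dataclasses import replace
            res = optimize_injection(centers, seg, cfg=replace(self.CFG, seed=seed))
            best = oracle_best_coverage(centers, seg, [1.0, 2.0, 3.0], 2, 1.0)
            assert res.coverage <= best + 1e-12
            matches += res.coverage == pytest.approx(best)
        assert matches >= 0.9 * total

    def test_history_is_non_decreasing(self):
        seg, centers = tiny_instance(3)
        res = optimize_injection(centers, seg, cfg=self.CFG)
        assert all(b >= a for a, b in zip(res.history, res.history[1:]))
        assert res.history[-1] == res.coverage

    def test_seeded_run_is_bitwise_reproducible(self):
        seg, centers = tiny_instance(5)
        r1 = optimize_injection(centers, seg, cfg=self.CFG)
        r2 = optimize_injection(centers, seg, cfg=self.CFG)
        assert r1.plan.spheres == r2.plan.spheres
        assert r1.coverage == r2.coverage

    def test_returned_plan_respects_containment(self):
        seg, centers = tiny_instance(7)
        res = optimize_injection(centers, seg, cfg=self.CFG)
        roi = seg.data.astype(bool)
        for s in res.plan.spheres:
            audit = sphere_mask(s.center, s.radius, seg)
            assert not (audit.data.astype(bool) & ~roi).any()

    def test_no_valid_centers_is_distinct_infeasible_outcome(self):
        seg = ball_roi()
        res = optimize_injection(np.empty((0, 3)), seg)
        assert not res.feasible and res.plan is None and res.coverage == 0.0
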