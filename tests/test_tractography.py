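import numpy as np
import pandas as pd
import pytest

from cedplan import (TensorField, TrackingCriteria, connection_present,
                     connectivity_counts, fit_tensor, fractional_anisotropy,
                     load_gradient_table, track_streamline)
from cedplan.phantom import axially_symmetric_tensor
from cedplan.tractography import Streamline

from conftest import make_volume


class TestFractionalAnisotropy:
    def test_isotropic_is_zero(self):
        assert fractional_anisotropy(0.7e-3 * np.eye(3)) == 0.0
        assert fractional_anisotropy(np.zeros((3, 3))) == 0.0

    def test_rank_one_limit_is_one(self):
        assert fractional_anisotropy(np.diag([1.0, 0, 0])) == pytest.approx(1.0)

    def test_direct_formula_evaluation(self):
        lam = np.array([1.7, 0.3, 0.3]) * 1e-3
        expected = np.sqrt(1.5) * np.linalg.norm(lam - lam.mean()) / np.linalg.norm(lam)
        assert fractional_anisotropy(np.diag(lam)) == pytest.approx(expected, rel=1e-12)
        # rotation does not change FA
        q, _ = np.linalg.qr(np.random.default_rng(0).normal(size=(3, 3)))
        rotated = q @ np.diag(lam) @ q.T
        assert fractional_anisotropy(rotated) == pytest.approx(expected, rel=1e-9)


class TestFitTensor:
    def test_matches_independent_pinv_oracle(self, rng):
        """Refit equals a from-scratch least-squares on the log design."""
        bvecs, bvals = load_gradient_table()
        n = 12
        sig = rng.uniform(10, 100, size=(n, 1, 1, len(bvals)))
        fitted = fit_tensor(sig, bvecs, bvals, affine=np.eye(4))
        # independent oracle: per-voxel numpy.linalg.lstsq on the same model
        g = bvecs
        design = np.column_stack([
            np.ones(len(bvals)),
            -bvals * g[:, 0] ** 2, -bvals * g[:, 1] ** 2, -bvals * g[:, 2] ** 2,
            -bvals * 2 * g[:, 0] * g[:, 1], -bvals * 2 * g[:, 0] * g[:, 2],
            -bvals * 2 * g[:, 1] * g[:, 2]])
        for i in range(n):
            coef, *_ = np.linalg.lstsq(design, np.log(sig[i, 0, 0]), rcond=None)
            d = np.array([[coef[1], coef[4], coef[5]],
                          [coef[4], coef[2], coef[6]],
                          [coef[5], coef[6], coef[3]]])
            w, v = np.linalg.eigh(d)
            d = v @ np.diag(np.maximum(w, 1e-7)) @ v.T
            np.testing.assert_allclose(
                fitted.tensor_at_voxel((i, 0, 0)), d, atol=1e-10)

    def test_isotropic_signal_fits_isotropic_tensor(self):
        bvecs, bvals = load_gradient_table()
        sig = np.full((1, 1, 1, len(bvals)), 80.0)
        sig[..., bvals > 0] = 40.0
        f = fit_tensor(sig, bvecs, bvals, affine=np.eye(4))
        assert fractional_anisotropy(f.tensor_at_voxel((0, 0, 0))) < 1e-6

    def test_zero_signal_marked_invalid(self):
        bvecs, bvals = load_gradient_table()
        sig = np.zeros((2, 1, 1, len(bvals)))
        sig[0] = 50.0
        f = fit_tensor(sig, bvecs, bvals, affine=np.eye(4))
        assert f.valid[0, 0, 0] and not f.valid[1, 0, 0]
        assert np.isfinite(f.components).all()


def tube_field(shape=(40, 11, 11), voxel=2.0, elbow_at=None):
    """Straight (or elbowed) anisotropic tube along x on an isotropic-FA
    background; the tube fills the whole grid cross-section."""
    axis_x = axially_symmetric_tensor(0.8, 0.7e-3, np.array([1.0, 0, 0]))
    axis_z = axially_symmetric_tensor(0.8, 0.7e-3, np.array([0.0, 0, 1.0]))
    mats = np.tile(axis_x, shape + (1, 1))
    if elbow_at is not None:
        mats[elbow_at:] = axis_z
    aff = np.diag([voxel, voxel, voxel, 1.0])
    field = TensorField.from_matrices(mats, aff, np.ones(shape, bool))
    brain = make_volume(np.ones(shape, np.uint8), voxel=voxel)
    return field, brain


class TestTracking:
    def test_straight_tube_is_tracked_full_length(self):
        field, brain = tube_field()
        crit = TrackingCriteria()
        sl = track_streamline(field, np.array([40.0, 10.0, 10.0]), crit, brain)
        assert sl is not None
        assert sl.length >= 40.0
        # essentially straight: lateral deviation stays tiny
        assert np.ptp(sl.points[:, 1]) < 1.0 and np.ptp(sl.points[:, 2]) < 1.0
        # consecutive spacing never exceeds the step
        steps = np.linalg.norm(np.diff(sl.points, axis=0), axis=1)
        assert steps.max() <= crit.step_mm + 1e-9

    def test_length_equals_sum_of_segments(self):
        field, brain = tube_field()
        sl = track_streamline(field, np.array([40.0, 10.0, 10.0]),
                              TrackingCriteria(), brain)
        assert sl.length == pytest.approx(
            np.linalg.norm(np.diff(sl.points, axis=0), axis=1).sum(), abs=1e-9)

    def test_isotropic_seed_returns_none(self):
        shape = (20, 9, 9)
        iso = axially_symmetric_tensor(0.05, 0.7e-3, np.array([1.0, 0, 0]))
        field = TensorField.from_matrices(np.tile(iso, shape + (1, 1)),
                                          np.diag([2.0, 2, 2, 1]), np.ones(shape, bool))
        brain = make_volume(np.ones(shape, np.uint8), voxel=2.0)
        assert track_streamline(field, np.array([20.0, 8.0, 8.0]),
                                TrackingCriteria(), brain) is None

    def test_ninety_degree_elbow_stops_tracking(self):
        field, brain = tube_field(elbow_at=25)  # elbow at x = 50 mm
        sl = track_streamline(field, np.array([20.0, 10.0, 10.0]),
                              TrackingCriteria(), brain)
        assert sl is not None
        # the track must not turn the corner: it ends near the elbow plane
        assert sl.points[:, 0].max() <= 52.0
        assert np.ptp(sl.points[:, 2]) < 4.0

    def test_seed_outside_brain_rejected(self):
        field, brain = tube_field()
        with pytest.raises(ValueError, match="outside"):
            track_streamline(field, np.array([-50.0, 0, 0]), TrackingCriteria(), brain)

    def test_tracking_is_deterministic(self):
        field, brain = tube_field()
        a = track_streamline(field, np.array([40.0, 10.0, 10.0]), TrackingCriteria(), brain)
        b = track_streamline(field, np.array([40.0, 10.0, 10.0]), TrackingCriteria(), brain)
        np.testing.assert_array_equal(a.points, b.points)


class TestConnections:
    def test_empty_streamline_set(self):
        roi = make_volume(np.ones((4, 4, 4), np.uint8))
        assert connection_present([], roi, roi) is False

    def test_requires_both_masks(self):
        roi = make_volume(np.zeros((10, 4, 4), np.uint8))
        seg = make_volume(np.zeros((10, 4, 4), np.uint8))
        roi.data[0] = 1
        seg.data[9] = 1
        through = Streamline(points=np.column_stack(
            [np.linspace(0, 9, 20), np.ones(20), np.ones(20)]))
        touching_roi_only = Streamline(points=np.column_stack(
            [np.linspace(0, 4, 10), np.ones(10), np.ones(10)]))
        assert connection_present([through], roi, seg) is True
        assert connection_present([touching_roi_only], roi, seg) is False

    def test_count_matrix_bounds(self):
        regions, segments = ["SMA", "amygdala"], ["sa", "sp", "ip", "ia"]
        full = pd.DataFrame(True, index=regions, columns=segments)
        empty = pd.DataFrame(False, index=regions, columns=segments)
        all_present = connectivity_counts([full] * 40)
        assert (all_present.to_numpy() == 40).all()
        assert (connectivity_counts([empty] * 40).to_numpy() == 0).all()
        half = connectivity_counts([full] * 20 + [empty] * 20)
        assert (half.to_numpy() == 20).all()

    def test_inconsistent_regions_rejected(self):
        a = pd.DataFrame(True, index=["SMA"], columns=["sa"])
        b = pd.DataFrame(True, index=["insula"], columns=["sa"])
        with pytest.raises(ValueError, match="inconsistent"):
            connectivity_counts([a, b])
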