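"""Artifact models and geometric robustness transforms."""

import dataclasses

import numpy as np
import pytest

from vesseltrace.core import Centerline, ImageVolume
from vesseltrace.metrics import surface_dice_1d
from vesseltrace.perturbations import (
    ArtifactSpec,
    DeformationSpec,
    add_gaussian_noise,
    calibration_shift,
    grid_distortion,
    motion_blur,
    motion_kernel,
    rigid_deform,
    training_augment,
)
from vesseltrace.preprocess import WindowSpec, apply_window


@pytest.fixture(scope="module")
def big_noise_vol(  ):
    rng = np.random.default_rng(0)
    return ImageVolume(rng.normal(50, 20, size=(64, 64, 64)).astype(np.float32))


class TestGaussianNoise:
    def test_mean_and_variance_match_spec(self, big_noise_vol):
        out = add_gaussian_noise(big_noise_vol, ArtifactSpec(seed=4))
        delta = out.values.astype(np.float64) - big_noise_vol.values
        assert abs(delta.mean()) < 0.1
        assert delta.var() == pytest.approx(15.0, abs=1.0)

    def test_zero_variance_is_identity(self, big_noise_vol):
        out = add_gaussian_noise(
            big_noise_vol, ArtifactSpec(noise_variance_hu2=0.0, seed=1)
        )
        np.testing.assert_array_equal(out.values, big_noise_vol.values)

    def test_seeded_reproducibility(self, big_noise_vol):
        a = add_gaussian_noise(big_noise_vol, ArtifactSpec(seed=7))
        b = add_gaussian_noise(big_noise_vol, ArtifactSpec(seed=7))
        np.testing.assert_array_equal(a.values, b.values)


class TestCalibrationShift:
    def test_spatially_constant(self, big_noise_vol):
        out = calibration_shift(big_noise_vol, ArtifactSpec(seed=3))
        delta = out.values - big_noise_vol.values
        assert delta.max() - delta.min() < 1e-4

    def test_shift_within_range_over_many_draws(self, big_noise_vol):
        small = ImageVolume(np.zeros((4, 4, 4), dtype=np.float32))
        shifts = [
            float(calibration_shift(small, ArtifactSpec(seed=s)).values[0, 0, 0])
            for s in range(1000)
        ]
        assert min(shifts) >= -10.0 and max(shifts) <= 10.0
        assert max(shifts) > 8.0 and min(shifts) < -8.0  # range actually used

    def test_windowed_shift_algebra(self, big_noise_vol):
        out = calibration_shift(big_noise_vol, ArtifactSpec(seed=3))
        c = float((out.values - big_noise_vol.values).mean())
        w = WindowSpec()
        before = apply_window(big_noise_vol, w).values
        after = apply_window(out, w).values
        interior = (before > 0.01) & (before < 0.99) & (after > 0.01) & (after < 0.99)
        np.testing.assert_allclose(
            (after - before)[interior], c / w.width_hu, atol=1e-5
        )


class TestMotionBlur:
    def test_sum_preserved_with_constant_border(self):
        vol = ImageVolume(np.zeros((20, 20, 20), dtype=np.float32))
        vol.values[8:12, 8:12, 8:12] = 100.0
        out = motion_blur(
            vol, ArtifactSpec(motion_amp_voxels=(3, 3), motion_direction=(1, 1, 0),
                              seed=0)
        )
        assert out.values.sum() == pytest.approx(vol.values.sum(), rel=1e-6)

    def test_zero_amplitude_is_identity(self, big_noise_vol):
        out = motion_blur(
            big_noise_vol, ArtifactSpec(motion_amp_voxels=(0, 0), seed=0)
        )
        np.testing.assert_array_equal(out.values, big_noise_vol.values)

    def test_impulse_response_spreads_to_kernel_support(self):
        vol = ImageVolume(np.zeros((15, 15, 15), dtype=np.float32))
        vol.values[7, 7, 7] = 1.0
        spec = ArtifactSpec(motion_amp_voxels=(2, 2), motion_direction=(1, 0, 0),
                            seed=0)
        out = motion_blur(vol, spec)
        kern = motion_kernel(2, (1, 0, 0))
        support = np.count_nonzero(kern > 1e-12)
        assert np.count_nonzero(out.values > 1e-12) == support
        # spread is along the motion axis only
        nz = np.nonzero(out.values)
        assert set(nz[1]) == {7} and set(nz[2]) == {7}
        assert len(set(nz[0])) == support


class TestRigidDeform:
    def test_identity_transform(self, default_case):
        vol, mask, cl = default_case
        spec = DeformationSpec(scale_range=(1.0, 1.0), rotation_range_deg=0.0, seed=0)
        v2, m2, c2 = rigid_deform(vol, mask, cl, spec)
        np.testing.assert_allclose(v2.values, vol.values, atol=1e-3)
        np.testing.assert_array_equal(m2.values, mask.values)
        np.testing.assert_allclose(c2.points, cl.points, atol=1e-9)

    def test_rotation_round_trip_on_centerline(self, default_case):
        vol, mask, cl = default_case
        fwd = DeformationSpec(scale_range=(1.0, 1.0), rotation_range_deg=8.0, seed=5)
        v2, m2, c2 = rigid_deform(vol, mask, cl, fwd)
        # invert by constructing the exact inverse map on the points
        rng = np.random.default_rng(5)
        s = rng.uniform(*fwd.scale_range)
        angles = np.deg2rad(rng.uniform(-8.0, 8.0, size=3))
        mats = []
        for ax, ang in enumerate(angles):
            c_, s_ = np.cos(ang), np.sin(ang)
            r = np.eye(3)
            i, j = [(1, 2), (0, 2), (0, 1)][ax]
            r[i, i] = c_
            r[j, j] = c_
            r[i, j] = -s_
            r[j, i] = s_
            mats.append(r)
        m = s * (mats[0] @ mats[1] @ mats[2])
        center = vol.origin_mm + vol.extent_mm / 2.0
        back = (c2.points - center) @ np.linalg.inv(m).T + center
        np.testing.assert_allclose(back, cl.points, atol=1e-6)

    def test_gt_containment_preserved(self, default_case):
        from scipy import ndimage

        vol, mask, cl = default_case
        spec = DeformationSpec(seed=11)
        v2, m2, c2 = rigid_deform(vol, mask, cl, spec)
        dilated = ndimage.binary_dilation(m2.values[0], iterations=1)
        vox = (c2.points / vol.spacing_mm - 0.5).round().astype(int)
        assert dilated[tuple(vox.T)].all()

    def test_out_of_grid_rejected(self, default_case):
        vol, mask, cl = default_case
        spec = DeformationSpec(scale_range=(1.8, 1.8), rotation_range_deg=0.0, seed=0)
        with pytest.raises(ValueError, match="out of the grid"):
            rigid_deform(vol, mask, cl, spec)


class TestGridDistortion:
    def test_zero_displacement_is_identity(self, default_case):
        vol, mask, cl = default_case
        spec = DeformationSpec(grid_max_disp_mm=0.0, seed=0)
        v2, m2, c2 = grid_distortion(vol, mask, cl, spec)
        np.testing.assert_allclose(v2.values, vol.values, atol=1e-3)
        np.testing.assert_allclose(c2.points, cl.points, atol=1e-9)

    def test_centerline_moves_by_field_lookup(self, default_case):
        import vesseltrace.perturbations as pert

        vol, mask, cl = default_case
        spec = DeformationSpec(grid_max_disp_mm=3.0, seed=21)
        rng = np.random.default_rng(21)
        field = pert._forward_field(vol, spec, rng)
        expected = cl.points + pert._field_at(field, cl.points, vol)
        _, _, c2 = grid_distortion(vol, mask, cl, spec)
        np.testing.assert_allclose(c2.points, expected, atol=1e-9)

    def test_jacobian_positive_over_100_seeds(self, default_case):
        import vesseltrace.perturbations as pert

        vol, _, _ = default_case
        spec = DeformationSpec()
        ok = 0
        for s in range(100):
            field = pert._forward_field(vol, spec, np.random.default_rng(s))
            ok += pert._jacobian_positive(field, vol.spacing_mm)
        assert ok == 100


class TestTrainingAugment:
    def test_double_flip_is_identity(self, default_case):
        from vesseltrace.perturbations import _flip

        vol, mask, cl = default_case
        v1, m1, c1 = _flip(vol, mask, cl, axis=0)
        v2, m2, c2 = _flip(v1, m1, c1, axis=0)
        np.testing.assert_array_equal(v2.values, vol.values)
        np.testing.assert_allclose(c2.points, cl.points, atol=1e-12)

    def test_seeded_reproducibility(self, default_case):
        a = training_augment(default_case, seed=13)
        b = training_augment(default_case, seed=13)
        np.testing.assert_array_equal(a[0].values, b[0].values)
        np.testing.assert_array_equal(a[2].points, b[2].points)

    @pytest.mark.parametrize("seed", range(0, 100, 5))
    def test_centerline_stays_inside_mask(self, default_case, seed):
        from scipy import ndimage

        vol, mask, cl = default_case
        v2, m2, c2 = training_augment((vol, mask, cl), seed=seed)
        dilated = ndimage.binary_dilation(m2.values[0], iterations=1)
        vox = np.clip(
            (c2.points / v2.spacing_mm - 0.5).round().astype(int),
            0,
            np.asarray(v2.shape) - 1,
        )
        assert dilated[tuple(vox.T)].all()

    def test_intensity_perturbations_leave_gt_metrics_perfect(self, default_case):
        vol, mask, cl = default_case
        for fn in (add_gaussian_noise, calibration_shift, motion_blur):
            fn(vol, ArtifactSpec(seed=2))  # ground truth untouched by design
        assert surface_dice_1d(cl, cl, 1.0) == 100.0
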