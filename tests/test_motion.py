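"""Motion estimation, binning, k-space correction, bin SENSE, registration,
and the motion-compensated encoding operator."""

import numpy as np
import pytest
from scipy.ndimage import shift as nd_shift

from triomap.motion import (
    DeformationField,
    assign_bins,
    build_warp_matrix,
    cg_sense,
    compose_encoding_operator,
    correct_translation_kspace,
    estimate_translation_ncc,
    reconstruct_bin_images,
    register_ffd,
)
from triomap.phantom import (
    MotionTrace,
    ifft3c,
    make_coil_sensitivities,
    make_vial_phantom,
    simulate_acquisition,
)
from triomap.sampling import bin_sampling_masks, generate_caspr_pattern
from triomap.signal_model import AcquisitionSpec


def _test_image():
    img = np.zeros((32, 32))
    img[8:20, 10:24] = np.hanning(12)[:, None] * np.hanning(14)[None, :]
    return img


class TestTranslationNCC:
    def test_identical_images_give_zero(self):
        img = _test_image()
        assert estimate_translation_ncc(img, img, (10, 10), (1, 1)) == (0.0, 0.0)

    def test_known_integer_shift_recovered(self):
        img = _test_image()
        moved = nd_shift(img, (3, -2), order=1)
        rl, fh = estimate_translation_ncc(moved, img, (10, 10), (1, 1))
        assert abs(rl - 3) < 0.25 and abs(fh + 2) < 0.25

    def test_subpixel_shift_recovered(self):
        img = _test_image()
        moved = nd_shift(img, (1.4, -2.6), order=3)
        rl, fh = estimate_translation_ncc(moved, img, (10, 10), (1, 1))
        assert abs(rl - 1.4) < 0.25 and abs(fh + 2.6) < 0.25

    def test_antisymmetry(self):
        img = _test_image()
        moved = nd_shift(img, (2, -1), order=1)
        f = estimate_translation_ncc(moved, img, (10, 10), (1, 1))
        b = estimate_translation_ncc(img, moved, (10, 10), (1, 1))
        assert abs(f[0] + b[0]) < 0.25 and abs(f[1] + b[1]) < 0.25

    def test_flat_image_rejected(self):
        with pytest.raises(ValueError):
            estimate_translation_ncc(np.zeros((8, 8)), np.ones((8, 8)))


class TestBinning:
    def test_constant_trace_single_bin(self):
        bins, centers, ref = assign_bins(np.full(10, 3.3), n_bins=4)
        assert len(np.unique(bins)) == 1

    def test_eight_distinct_values_two_per_bin(self):
        bins, _, _ = assign_bins(np.array([1, 5, 2, 8, 3, 7, 4, 6.0]), n_bins=4)
        assert np.all(np.bincount(bins, minlength=4) == 2)

    def test_reference_is_minimal_median_displacement(self):
        fh = np.array([0.1, 0.2, 4.0, 4.1, 8.0, 8.1, 12.0, 12.1])
        bins, centers, ref = assign_bins(fh, n_bins=4)
        # recompute medians by hand
        med = [np.median(fh[bins == b]) for b in range(4)]
        assert ref == int(np.argmin(np.abs(med)))
        np.testing.assert_allclose(centers, med)


@pytest.fixture(scope="module")
def moving_acquisition():
    shape = (32, 32, 8)
    pmap = make_vial_phantom(9, shape=shape)
    acq = AcquisitionSpec()
    pattern = generate_caspr_pattern((32, 8), accel=2)
    sens = make_coil_sensitivities(4, shape, seed=11)
    n_hb = pattern.n_heartbeats
    rng = np.random.default_rng(2)
    motion = MotionTrace(fh=rng.uniform(-6, 6, n_hb), rl=rng.uniform(-2, 2, n_hb), seed=2)
    ksp, inavs = simulate_acquisition(pmap, acq, pattern, sens, motion=motion,
                                      noise_sigma=0.0)
    return pmap, acq, pattern, sens, motion, ksp, inavs


class TestKspaceCorrection:
    def test_zero_residual_leaves_data_unchanged(self, moving_acquisition):
        *_, ksp, _ = moving_acquisition
        n_hb = ksp.hb_index.max() + 1
        bins = np.zeros(n_hb, dtype=int)
        out = correct_translation_kspace(
            ksp, np.zeros(n_hb), np.zeros(n_hb), bins,
            centers_rl=np.zeros(1), centers_fh=np.zeros(1))
        assert np.array_equal(out.data, ksp.data)

    def test_correction_magnitude_preserving(self, moving_acquisition):
        *_, motion, ksp, _ = moving_acquisition
        n_hb = len(motion.fh)
        bins = np.zeros(n_hb, dtype=int)
        out = correct_translation_kspace(ksp, motion.rl, motion.fh, bins,
                                         centers_rl=np.zeros(1), centers_fh=np.zeros(1))
        np.testing.assert_allclose(np.abs(out.data), np.abs(ksp.data), atol=1e-12)

    def test_correction_realigns_shot_images(self, moving_acquisition):
        pmap, acq, pattern, sens, motion, ksp, _ = moving_acquisition
        n_hb = pattern.n_heartbeats
        bins = np.zeros(n_hb, dtype=int)
        # correct everything to position zero, then the full dataset is static
        out = correct_translation_kspace(ksp, motion.rl, motion.fh, bins,
                                         centers_rl=np.zeros(1), centers_fh=np.zeros(1))
        img = np.abs(np.sum(np.conj(sens) * ifft3c(out.data[1, 1]), axis=0))
        static, _ = simulate_acquisition(pmap, acq, pattern, sens, noise_sigma=0.0)
        ref = np.abs(np.sum(np.conj(sens) * ifft3c(static.data[1, 1]), axis=0))
        proj_img, proj_ref = img.sum(axis=(0, 2)), ref.sum(axis=(0, 2))
        com = lambda p: np.sum(np.arange(len(p)) * p) / p.sum()  # noqa: E731
        assert abs(com(proj_img) - com(proj_ref)) < 0.25


class TestBinSense:
    def test_full_sampling_single_bin_equals_direct(self, moving_acquisition):
        pmap, acq, *_ = moving_acquisition
        shape = pmap.shape
        pattern = generate_caspr_pattern((32, 8), accel=1)
        sens = make_coil_sensitivities(4, shape, seed=11)
        ksp, _ = simulate_acquisition(pmap, acq, pattern, sens, noise_sigma=0.0)
        masks = np.ones((1, 32, 8))
        out = reconstruct_bin_images(ksp.data[3, 1], masks, sens, n_iters=10)
        direct = np.sum(np.conj(sens) * ifft3c(ksp.data[3, 1]), axis=0)
        err = np.linalg.norm(out[0] - direct) / np.linalg.norm(direct)
        assert err < 1e-5

    def test_cg_residual_non_increasing(self, moving_acquisition):
        pmap, acq, pattern, sens, motion, ksp, _ = moving_acquisition
        _, residuals = cg_sense(ksp.data[3, 1], ksp.masks[3].astype(float), sens,
                                n_iters=10)
        assert np.all(np.diff(residuals) <= 1e-12)

    def test_empty_bin_raises_with_bin_name(self, moving_acquisition):
        pmap, acq, pattern, sens, motion, ksp, _ = moving_acquisition
        masks = np.stack([ksp.masks[3], np.zeros_like(ksp.masks[3])])
        with pytest.raises(ValueError, match="bin 1"):
            reconstruct_bin_images(ksp.data[3, 1], masks, sens)

    def test_bin_images_show_known_displacement(self):
        # two bins at distinct positions: reconstructed bin images must have
        # centroids separated by the true FH displacement
        shape = (32, 32, 8)
        pmap = make_vial_phantom(1, params=None, shape=shape)
        acq = AcquisitionSpec()
        pattern = generate_caspr_pattern((32, 8), accel=1)
        sens = make_coil_sensitivities(4, shape, seed=11)
        n_hb = pattern.n_heartbeats
        fh = np.where(np.arange(n_hb) % 2 == 0, 0.0, 6.0)  # 3 voxels
        motion = MotionTrace(fh=fh, rl=np.zeros(n_hb), seed=0)
        ksp, _ = simulate_acquisition(pmap, acq, pattern, sens, motion=motion,
                                      noise_sigma=0.0)
        bins = (np.arange(n_hb) % 2).astype(int)
        masks = bin_sampling_masks(pattern, bins, n_bins=2)
        out = reconstruct_bin_images(ksp.data[3, 1], masks[3], sens, n_iters=15)
        # displacement between the two bin images, estimated in-plane
        proj0 = np.abs(out[0]).sum(axis=2)
        proj1 = np.abs(out[1]).sum(axis=2)
        rl, fh = estimate_translation_ncc(proj1, proj0, max_shift_mm=(10, 10),
                                          pixel_size_mm=(1, 1))
        assert abs(fh - 3.0) < 0.5 and abs(rl) < 0.5


class TestRegistration:
    def test_identity_registration_near_zero(self):
        pmap = make_vial_phantom(5, shape=(32, 32, 8))
        img = pmap.m0 * (0.5 + 0.5 * pmap.t1 / 1500)
        fld = register_ffd(img, img, voxel_size=(2, 2, 2))
        assert np.abs(fld.displacement).max() / 2.0 < 0.1  # voxels

    def test_known_shift_recovered(self):
        pmap = make_vial_phantom(9, shape=(64, 64, 16))
        ref = pmap.m0 * (0.5 + 0.5 * pmap.t1 / 1500)
        mov = nd_shift(ref, (0, 2, 0), order=1)  # +2 voxels FH
        fld = register_ffd(mov, ref, voxel_size=(2, 2, 2))
        inside = pmap.m0 > 0
        med = np.median(fld.displacement[1][inside]) / 2.0
        assert abs(med - 2.0) < 0.5

    def test_recovered_field_halves_mse(self):
        # smooth synthetic deformation (thin-plate-like bump)
        pmap = make_vial_phantom(9, shape=(64, 64, 16))
        ref = pmap.m0 * (0.5 + 0.5 * pmap.t1 / 1500)
        x = np.linspace(-1, 1, 64)
        bump = 1.5 * np.exp(-(x[:, None] ** 2 + x[None, :] ** 2) / 0.4)
        coords = np.meshgrid(np.arange(64), np.arange(64), np.arange(16), indexing="ij")
        mov_coords = [coords[0], coords[1] - bump[:, :, None], coords[2]]
        from scipy.ndimage import map_coordinates

        mov = map_coordinates(ref, mov_coords, order=1)
        fld = register_ffd(mov, ref, voxel_size=(2, 2, 2), grid_spacing_mm=24)
        W = build_warp_matrix(fld, (2, 2, 2))
        warped = (W @ mov.ravel()).reshape(mov.shape)
        mse0 = np.mean((mov - ref) ** 2)
        mse1 = np.mean((warped - ref) ** 2)
        assert mse1 <= 0.5 * mse0


@pytest.fixture(scope="module")
def operator():
    rng = np.random.default_rng(5)
    shape = (16, 16, 8)
    sens = make_coil_sensitivities(3, shape, seed=6)
    disp = rng.normal(0, 1.2, size=(3,) + shape)
    fields = [None, DeformationField(disp, 0)]
    masks = (rng.random((4, 2, 16, 8)) < 0.4).astype(float)
    return compose_encoding_operator(masks, sens, fields, voxel_size=(2, 2, 2))


class TestEncodingOperator:

    def test_adjoint_dot_product(self, operator):
        rng = np.random.default_rng(6)
        shape = (4,) + operator.shape
        for _ in range(20):
            x = rng.normal(size=shape) + 1j * rng.normal(size=shape)
            y = rng.normal(size=(4, 3) + operator.shape) + \
                1j * rng.normal(size=(4, 3) + operator.shape)
            lhs = np.vdot(y, operator.forward(x))
            rhs = np.vdot(operator.adjoint(y), x)
            assert abs(lhs - rhs) / abs(lhs) < 1e-6

    def test_linearity(self, operator):
        rng = np.random.default_rng(7)
        shape = (4,) + operator.shape
        x1 = rng.normal(size=shape) + 1j * rng.normal(size=shape)
        x2 = rng.normal(size=shape) + 1j * rng.normal(size=shape)
        lhs = operator.forward(2.0 * x1 + 3j * x2)
        rhs = 2.0 * operator.forward(x1) + 3j * operator.forward(x2)
        np.testing.assert_allclose(lhs, rhs, atol=1e-9 * np.abs(rhs).max())

    def test_single_bin_identity_field_is_fourier_sense(self):
        from triomap.phantom import fft3c

        rng = np.random.default_rng(8)
        shape = (16, 16, 8)
        sens = make_coil_sensitivities(3, shape, seed=6)
        masks = np.ones((1, 1, 16, 8))
        E = compose_encoding_operator(masks, sens, [None])
        x = rng.normal(size=(1,) + shape) + 1j * rng.normal(size=(1,) + shape)
        np.testing.assert_allclose(E.forward(x)[0], fft3c(sens * x[0][None]), atol=1e-12)

    def test_masked_energy_bounded_by_unmasked(self, operator):
        rng = np.random.default_rng(9)
        shape = (4,) + operator.shape
        x = rng.normal(size=shape) + 1j * rng.normal(size=shape)
        from triomap.phantom import fft3c

        full = 0.0
        for b in range(operator.n_bins):
            for c in range(4):
                xb = operator._warp(x[c], b)
                full += np.sum(np.abs(fft3c(operator.sens * xb[None])) ** 2)
        assert np.sum(np.abs(operator.forward(x)) ** 2) <= full + 1e-9

    def test_warp_matrix_preserves_constants(self):
        rng = np.random.default_rng(10)
        disp = rng.normal(0, 2.0, size=(3, 8, 8, 4))
        W = build_warp_matrix(DeformationField(disp, 0), (2, 2, 2))
        ones = np.ones(8 * 8 * 4)
        np.testing.assert_allclose(W @ ones, ones, atol=1e-12)
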