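"""HD-PROST building blocks: patch selection, HOSVD denoising, the regularized
data-consistency solve, and the full ADMM loop on small fixtures."""

import numpy as np
import pytest

from triomap.motion import compose_encoding_operator
from triomap.phantom import (
    contrast_weights,
    dixon_echo_factor,
    make_coil_sensitivities,
    make_vial_phantom,
    simulate_acquisition,
)
from triomap.recon import (
    HDProstConfig,
    aggregate_patches,
    data_consistency_step,
    extract_patches,
    hd_prost_reconstruct,
    hosvd_denoise,
    patch_select,
    select_all_patches,
)
from triomap.sampling import bin_sampling_masks, generate_caspr_pattern
from triomap.signal_model import AcquisitionSpec


class TestPatchSelect:
    def test_constant_image_all_distances_zero(self):
        cfg = HDProstConfig(patch_size=3, n_similar=5, search_window=6, patch_offset=2)
        X = np.ones((2, 12, 12, 8), dtype=complex)
        T, corners = patch_select(X, (4, 4, 2), cfg)
        assert T.shape == (27, 5, 2)
        assert np.allclose(T, 1.0)

    def test_reference_patch_always_selected(self):
        rng = np.random.default_rng(0)
        cfg = HDProstConfig(patch_size=3, n_similar=4, search_window=6, patch_offset=2)
        X = rng.normal(size=(1, 12, 12, 8)) + 0j
        v = (4, 6, 2)
        _, corners = patch_select(X, v, cfg)
        cshape = (10, 10, 6)
        ref_flat = (v[0] * cshape[1] + v[1]) * cshape[2] + v[2]
        assert ref_flat in corners

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        cfg = HDProstConfig(patch_size=3, n_similar=6, search_window=8, patch_offset=4)
        X = rng.normal(size=(2, 16, 16, 16)) + 1j * rng.normal(size=(2, 16, 16, 16))
        sim = np.mean(np.abs(X), axis=0)
        p, half = cfg.patch_size, cfg.search_window // 2
        for v in [(0, 0, 0), (4, 8, 4), (12, 12, 12)]:
            _, corners = patch_select(X, v, cfg, sim=sim)
            # brute force: distances of every candidate corner in the window
            cands, dists = [], []
            ref = sim[v[0]:v[0] + p, v[1]:v[1] + p, v[2]:v[2] + p]
            for cx in range(max(v[0] - half, 0), min(v[0] + half, 16 - p) + 1):
                for cy in range(max(v[1] - half, 0), min(v[1] + half, 16 - p) + 1):
                    for cz in range(max(v[2] - half, 0), min(v[2] + half, 16 - p) + 1):
                        d = np.sum((sim[cx:cx + p, cy:cy + p, cz:cz + p] - ref) ** 2)
                        cands.append((cx, cy, cz))
                        dists.append(d)
            order = np.argsort(np.asarray(dists), kind="stable")[:cfg.n_similar]
            want = {cands[i] for i in order}
            cshape = (14, 14, 14)
            got = {tuple(np.unravel_index(c, cshape)) for c in corners}
            assert got == want


class TestHosvd:
    def test_rank_one_tensor_unchanged(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=10) + 1j * rng.normal(size=10)
        b = rng.normal(size=6) + 1j * rng.normal(size=6)
        c = rng.normal(size=4) + 1j * rng.normal(size=4)
        T = np.einsum("i,j,k->ijk", a, b, c)
        out = hosvd_denoise(T, 0.1)
        assert np.linalg.norm(out - T) / np.linalg.norm(T) < 1e-9

    def test_lam_zero_is_identity(self):
        rng = np.random.default_rng(3)
        T = rng.normal(size=(8, 5, 3)) + 1j * rng.normal(size=(8, 5, 3))
        np.testing.assert_array_equal(hosvd_denoise(T, 0.0), T)

    @pytest.mark.parametrize("rule,factor", [("rank", 0.7), ("core", 1.0)])
    def test_noisy_low_rank_tensor_denoised(self, rule, factor):
        # the default rank-truncation rule must cut the error by >= 30%;
        # the alternative core-threshold rule must at least not hurt
        rng = np.random.default_rng(4)
        U = rng.normal(size=(27, 2))
        V = rng.normal(size=(12, 2))
        W = rng.normal(size=(6, 2))
        clean = np.einsum("ir,jr,kr->ijk", U, V, W).astype(complex)
        noisy = clean + 0.05 * np.linalg.norm(clean) / np.sqrt(clean.size) * (
            rng.normal(size=clean.shape) + 1j * rng.normal(size=clean.shape))
        out = hosvd_denoise(noisy, 0.2, rule=rule)
        err_in = np.linalg.norm(noisy - clean)
        err_out = np.linalg.norm(out - clean)
        assert err_out <= factor * err_in

    def test_non_tensor_rejected(self):
        with pytest.raises(ValueError):
            hosvd_denoise(np.zeros((3, 3)), 0.1)


class TestAggregation:
    def test_partition_of_unity(self):
        rng = np.random.default_rng(5)
        cfg = HDProstConfig(patch_size=3, n_similar=4, search_window=6, patch_offset=2)
        X = rng.normal(size=(2, 12, 12, 8)) + 1j * rng.normal(size=(2, 12, 12, 8))
        sel = select_all_patches(X, cfg)
        back = aggregate_patches(extract_patches(X, sel), sel, X.shape[1:])
        covered = sel.counts > 0
        np.testing.assert_allclose(back[:, covered], X[:, covered], atol=1e-9)
        assert covered.all()  # stride grid tiles the whole volume


@pytest.fixture(scope="module")
def toy_problem():
    """8x8x1 fully explicit problem: dense matrix vs operator."""
    rng = np.random.default_rng(6)
    shape = (8, 8, 1)
    sens = make_coil_sensitivities(2, shape, seed=7)
    masks = (rng.random((1, 2, 8, 1)) < 0.6).astype(float)
    masks[0, :, 4, 0] = 1.0
    E = compose_encoding_operator(masks, sens, [None, None])
    n = 64

    def dense_of(op):
        cols = []
        for j in range(n):
            e = np.zeros((1,) + shape, dtype=complex)
            e.ravel()[j] = 1.0
            cols.append(op.forward(e).ravel())
        return np.stack(cols, axis=1)

    return E, dense_of(E), shape


class TestDataConsistency:
    def test_cg_matches_dense_least_squares(self, toy_problem):
        E, A, shape = toy_problem
        rng = np.random.default_rng(8)
        x_true = rng.normal(size=(1,) + shape) + 1j * rng.normal(size=(1,) + shape)
        K = E.forward(x_true)
        cfg = HDProstConfig(sense_iters=200, cg_tol=1e-14)
        x_cg = data_consistency_step(E, K, cfg, mu=0.0)
        x_dense, *_ = np.linalg.lstsq(A, K.ravel(), rcond=None)
        np.testing.assert_allclose(x_cg.ravel(), x_dense, atol=1e-6)

    def test_full_sampling_mu_zero_is_coil_combined_inverse(self):
        rng = np.random.default_rng(9)
        shape = (16, 16, 4)
        sens = make_coil_sensitivities(3, shape, seed=10)
        masks = np.ones((2, 1, 16, 4))
        E = compose_encoding_operator(masks, sens, [None])
        x = rng.normal(size=(2,) + shape) + 1j * rng.normal(size=(2,) + shape)
        K = E.forward(x)
        cfg = HDProstConfig(sense_iters=10)
        out = data_consistency_step(E, K, cfg, mu=0.0)
        np.testing.assert_allclose(out, x, atol=1e-5 * np.abs(x).max())

    def test_quadratic_objective_non_increasing(self, toy_problem):
        # CG on the normal equations minimizes ||E x - K||^2 over growing
        # Krylov subspaces, so the data residual is non-increasing
        E, A, shape = toy_problem
        rng = np.random.default_rng(10)
        K = rng.normal(size=(1, 2) + shape) + 1j * rng.normal(size=(1, 2) + shape)
        rhs = E.adjoint(K)
        x = np.zeros_like(rhs)
        r = rhs - E.normal(x)
        p = r.copy()
        rs = np.vdot(r, r).real
        obj = [np.linalg.norm(E.forward(x) - K)]
        for _ in range(20):
            ap = E.normal(p)
            alpha = rs / np.vdot(p, ap).real
            x = x + alpha * p
            r = r - alpha * ap
            rs_new = np.vdot(r, r).real
            p = r + (rs_new / rs) * p
            rs = rs_new
            obj.append(np.linalg.norm(E.forward(x) - K))
        assert np.all(np.diff(obj) <= 1e-9 * obj[0])


@pytest.fixture(scope="module")
def hdprost_fixture():
    shape = (32, 32, 8)
    pmap = make_vial_phantom(9, shape=shape)
    acq = AcquisitionSpec()
    sens = make_coil_sensitivities(4, shape, seed=5)
    w = contrast_weights(pmap, acq)
    truth = np.stack([w[c] * dixon_echo_factor(pmap.fat_fraction, te) * pmap.m0
                      for c in range(5) for te in (acq.te1, acq.te2)])
    return pmap, acq, sens, truth


class TestHdProst:
    def _run(self, pmap, acq, sens, accel):
        pattern = generate_caspr_pattern((32, 8), accel=accel)
        ksp, _ = simulate_acquisition(pmap, acq, pattern, sens, noise_sigma=0.0)
        K = ksp.data.reshape((10, sens.shape[0]) + pmap.shape)
        masks = bin_sampling_masks(pattern, np.zeros(pattern.n_heartbeats, int), 1)
        E = compose_encoding_operator(np.repeat(masks, 2, axis=0), sens, [None])
        cfg = HDProstConfig(search_window=10)
        X, hist = hd_prost_reconstruct(K, E, cfg)
        return X, hist, E, K

    def test_fully_sampled_recovers_truth(self, hdprost_fixture):
        pmap, acq, sens, truth = hdprost_fixture
        X, _, _, _ = self._run(pmap, acq, sens, accel=1)
        err = np.linalg.norm(X - truth) / np.linalg.norm(truth)
        assert err < 1e-3

    def test_undersampled_beats_zero_filled(self, hdprost_fixture):
        pmap, acq, sens, truth = hdprost_fixture
        X, hist, E, K = self._run(pmap, acq, sens, accel=4)
        zf = E.adjoint(K)
        nrmse = lambda a: np.linalg.norm(a - truth) / np.linalg.norm(truth)  # noqa: E731
        assert nrmse(X) <= 0.6 * nrmse(zf)
        assert hist[-1] <= hist[0]

    def test_deterministic_and_phase_equivariant(self, hdprost_fixture):
        pmap, acq, sens, truth = hdprost_fixture
        pattern = generate_caspr_pattern((32, 8), accel=4)
        ksp, _ = simulate_acquisition(pmap, acq, pattern, sens, noise_sigma=0.0)
        K = ksp.data.reshape((10, sens.shape[0]) + pmap.shape)
        masks = bin_sampling_masks(pattern, np.zeros(pattern.n_heartbeats, int), 1)
        E = compose_encoding_operator(np.repeat(masks, 2, axis=0), sens, [None])
        cfg = HDProstConfig(search_window=10, outer_iters=2)
        X1, _ = hd_prost_reconstruct(K, E, cfg)
        X2, _ = hd_prost_reconstruct(K.copy(), E, cfg)
        assert np.array_equal(X1, X2)
        phase = np.exp(1j * 0.7)
        X3, _ = hd_prost_reconstruct(K * phase, E, cfg)
        np.testing.assert_allclose(X3, X1 * phase, atol=1e-8 * np.abs(X1).max())
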