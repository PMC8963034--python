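import numpy as np
import pytest

from emgfuse import bilinear as bl
from emgfuse.features import FeatureMatrix
from emgfuse.synthetic import plant_bilinear_dataset


def principal_angle_deg(A, B):
    qa, _ = np.linalg.qr(A)
    qb, _ = np.linalg.qr(B)
    s = np.linalg.svd(qa.T @ qb, compute_uv=False)
    return float(np.degrees(np.arccos(np.clip(s.min(), -1.0, 1.0))))


def _planted(noise=0.0, seed=1, S=5, T=200, K=8):
    Z, X, W, Y = plant_bilinear_dataset(S, T, I=2, J=3, n_channels=K,
                                        noise_sd=noise, seed=seed)
    stacked = Y.reshape(S * T, K)
    subj = np.repeat(np.arange(S), T)
    return Z, X, W, Y, stacked, subj


class TestStack:
    def _fm(self, rng, sid, n=10, d=4):
        return FeatureMatrix(rng.normal(size=(n, d)), np.ones(n, int),
                             np.full(n, sid), np.ones(n, int), np.ones(n, int),
                             [f"f{i}" for i in range(d)])

    def test_block_order_preserved(self, rng):
        a, b = self._fm(rng, 1), self._fm(rng, 2)
        stacked, idx = bl.stack_training_features([a, b])
        assert stacked.shape == (20, 4)
        np.testing.assert_array_equal(stacked[:10], a.values)
        np.testing.assert_array_equal(stacked[10:], b.values)
        np.testing.assert_array_equal(idx, [1] * 10 + [2] * 10)

    def test_single_subject_identity(self, rng):
        a = self._fm(rng, 1)
        stacked, _ = bl.stack_training_features([a])
        np.testing.assert_array_equal(stacked, a.values)

    def test_unstack_roundtrip(self, rng):
        a, b = self._fm(rng, 1), self._fm(rng, 2)
        stacked, idx = bl.stack_training_features([a, b])
        np.testing.assert_array_equal(stacked[idx == 1], a.values)
        np.testing.assert_array_equal(stacked[idx == 2], b.values)

    def test_dim_mismatch(self, rng):
        with pytest.raises(ValueError):
            bl.stack_training_features([self._fm(rng, 1, d=4), self._fm(rng, 2, d=5)])


class TestFit:
    def test_noise_free_recovery(self):
        Z, X, W, Y, stacked, subj = _planted()
        m = bl.fit_bilinear(stacked, subj)
        assert m.fit_residual <= 1e-8
        assert principal_angle_deg(X, m.contents) < 1.0
        assert principal_angle_deg(Z, m.styles) < 1.0

    def test_residual_monotone(self):
        _, _, _, _, stacked, subj = _planted(noise=0.3, seed=4)
        m = bl.fit_bilinear(stacked, subj)
        hist = m.residual_history
        assert all(b <= a + 1e-12 for a, b in zip(hist, hist[1:]))

    def test_noisy_recovery_close(self):
        Z, X, W, Y, stacked, subj = _planted(noise=0.1, seed=2)
        m = bl.fit_bilinear(stacked, subj)
        noise_floor = 0.1**2 * Y.size / np.sum(Y**2)
        assert m.fit_residual < 2.0 * noise_floor
        assert principal_angle_deg(X, m.contents) < 5.0

    def test_rank_one_matches_svd(self, rng):
        # I = J = 1 on a single channel reduces to the best rank-1 fit
        Z, X, W, Y = plant_bilinear_dataset(6, 40, I=1, J=1, n_channels=1,
                                            noise_sd=0.05, seed=3)
        stacked = Y.reshape(-1, 1)
        subj = np.repeat(np.arange(6), 40)
        m = bl.fit_bilinear(stacked, subj, I=1, J=1)
        recon = m.reconstruct()[:, :, 0]
        u, s, vt = np.linalg.svd(Y[:, :, 0])
        svd_rank1 = s[0] * np.outer(u[:, 0], vt[0])
        np.testing.assert_allclose(recon, svd_rank1, atol=1e-6)

    def test_too_few_subjects(self):
        _, _, _, _, stacked, subj = _planted(S=2, T=30)
        with pytest.raises(ValueError):
            bl.fit_bilinear(stacked[subj == 0], subj[subj == 0])

    def test_degenerate_rank(self):
        stacked = np.zeros((40, 6))
        subj = np.repeat([0, 1], 20)
        with pytest.raises(bl.DegenerateFitError):
            bl.fit_bilinear(stacked, subj)


class TestContent:
    def test_row_count(self):
        _, X, _, _, stacked, subj = _planted(T=150)
        m = bl.fit_bilinear(stacked, subj)
        assert bl.extract_content(m).shape == (150, 3)

    def test_content_correlates_with_planted(self):
        _, X, _, _, stacked, subj = _planted()
        m = bl.fit_bilinear(stacked, subj)
        C = bl.extract_content(m)
        # canonical correlation via LS fit: planted x predicts recovered content
        coef, *_ = np.linalg.lstsq(X - X.mean(0), C - C.mean(0), rcond=None)
        pred = (X - X.mean(0)) @ coef
        resid = C - C.mean(0) - pred
        r2 = 1 - np.sum(resid**2) / np.sum((C - C.mean(0)) ** 2)
        assert r2 > 0.999

    def test_unfitted_raises(self):
        m = bl.BilinearModel(np.zeros((1, 2, 3)), np.zeros((2, 2)), None)
        with pytest.raises(ValueError):
            bl.extract_content(m)


class TestStyleAdaptation:
    def test_recover_training_subject_style(self):
        Z, X, W, Y, stacked, subj = _planted()
        m = bl.fit_bilinear(stacked, subj)
        m2 = bl.adapt_style(m, Y[0, :40].reshape(40, -1), m.contents[:40])
        rel = np.linalg.norm(m2.new_style - m.styles[0]) / np.linalg.norm(m.styles[0])
        assert rel < 0.05

    def test_homogeneity(self):
        _, _, _, Y, stacked, subj = _planted()
        m = bl.fit_bilinear(stacked, subj)
        cal = Y[1, :30].reshape(30, -1)
        z1 = bl.adapt_style(m, cal, m.contents[:30]).new_style
        z3 = bl.adapt_style(m, 3.0 * cal, m.contents[:30]).new_style
        np.testing.assert_allclose(z3, 3.0 * z1, rtol=1e-8)

    def test_local_optimality(self, rng):
        _, _, _, Y, stacked, subj = _planted(noise=0.05, seed=5)
        m = bl.fit_bilinear(stacked, subj)
        cal = Y[2, :30].reshape(30, -1)
        m2 = bl.adapt_style(m, cal, m.contents[:30])

        def resid(z):
            rec = np.einsum("i,kij,tj->tk", z, m.weights, m.contents[:30])
            return np.sum((rec - cal) ** 2)

        base = resid(m2.new_style)
        for _ in range(100):
            assert base <= resid(m2.new_style + rng.normal(0, 0.05, size=2)) + 1e-12

    def test_empty_cal(self):
        _, _, _, _, stacked, subj = _planted(T=30)
        m = bl.fit_bilinear(stacked, subj)
        with pytest.raises(ValueError):
            bl.adapt_style(m, np.empty((0, 8)), np.empty((0, 3)))


class TestProjection:
    def test_noise_free_reconstruction(self):
        _, _, _, Y, stacked, subj = _planted()
        m = bl.fit_bilinear(stacked, subj)
        m2 = bl.adapt_style(m, Y[0, :40].reshape(40, -1), m.contents[:40])
        C = bl.project_content(m2, Y[0].reshape(200, -1))
        rec = np.einsum("i,kij,tj->tk", m2.new_style, m.weights, C)
        rel = np.linalg.norm(rec - Y[0]) / np.linalg.norm(Y[0])
        assert rel <= 1e-4
        assert C.shape == (200, 3)

    def test_known_content_up_to_gauge(self):
        _, X, _, Y, stacked, subj = _planted()
        m = bl.fit_bilinear(stacked, subj)
        m2 = bl.adapt_style(m, Y[0, :40].reshape(40, -1), m.contents[:40])
        C = bl.project_content(m2, Y[0].reshape(200, -1))
        assert principal_angle_deg(X, C) < 1.0

    def test_requires_adapted_style(self):
        _, _, _, _, stacked, subj = _planted(T=30)
        m = bl.fit_bilinear(stacked, subj)
        with pytest.raises(ValueError):
            bl.project_content(m, np.zeros((5, 8)))


class TestContentIMUFusion:
    def test_single_subject_average_is_identity(self, rng):
        C = rng.normal(size=(10, 3))
        imu = rng.normal(size=(10, 12))
        out = bl.fuse_content_imu(C, imu, mode="train", subject_index=np.ones(10))
        np.testing.assert_array_equal(out[:, 3:], imu)

    def test_identical_imu_across_subjects(self, rng):
        C = rng.normal(size=(10, 3))
        imu_one = rng.normal(size=(10, 12))
        imu = np.vstack([imu_one, imu_one])
        idx = np.repeat([1, 2], 10)
        out = bl.fuse_content_imu(C, imu, mode="train", subject_index=idx)
        np.testing.assert_allclose(out[:, 3:], imu_one)

    def test_fused_width(self, rng):
        C = rng.normal(size=(10, 3))
        out = bl.fuse_content_imu(C, rng.normal(size=(10, 12)), mode="test")
        assert out.shape == (10, 15)

    def test_misalignment_raises(self, rng):
        with pytest.raises(ValueError):
            bl.fuse_content_imu(rng.normal(size=(10, 3)),
                                rng.normal(size=(9, 12)), mode="test")
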