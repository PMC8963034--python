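import numpy as np
import pytest

from emgfuse import pipeline as pl
from emgfuse import preprocess as pre
from emgfuse import onset as onset_mod
from emgfuse.synthetic import (
    CohortConfig,
    ConfigurationError,
    generate_cohort,
    generate_subject,
    load_cohort,
    make_profile,
    plant_bilinear_dataset,
    save_cohort,
)


class TestConfig:
    def test_default_protocol_counts(self):
        cfg = CohortConfig()
        assert cfg.n_gestures == 7
        assert cfg.n_positions == 4
        assert cfg.n_repetitions == 10
        assert cfg.n_emg_samples == round((3 + 5 + 3) * 200)
        assert cfg.n_imu_samples == round((3 + 5 + 3) * 50)

    @pytest.mark.parametrize("bad", [
        dict(n_subjects=0), dict(n_gestures=0), dict(hold_s=-1.0),
        dict(emg_rate=190.0),   # not divisible by 50
        dict(rotation_max=8),
    ])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            CohortConfig(**bad)


class TestGenerateSubject:
    def test_default_counts_280(self):
        # protocol counts, short hold to keep this fast
        cfg = CohortConfig(hold_s=0.5, rest_s=0.25, seed=0)
        prof = make_profile(1, cfg, np.random.SeedSequence(1))
        recs = generate_subject(prof, cfg)
        assert len(recs) == 7 * 4 * 10 == 280

    def test_determinism(self, tiny_cfg):
        prof = make_profile(1, tiny_cfg, np.random.SeedSequence(9))
        a = generate_subject(prof, tiny_cfg)
        b = generate_subject(prof, tiny_cfg)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.emg, rb.emg)
            np.testing.assert_array_equal(ra.accel, rb.accel)
            np.testing.assert_array_equal(ra.gyro, rb.gyro)

    def test_shapes_and_truth_bounds(self, tiny_cohort, tiny_cfg):
        for rec in tiny_cohort[0][1]:
            assert rec.emg.shape == (8, tiny_cfg.n_emg_samples)
            assert rec.accel.shape == (3, tiny_cfg.n_imu_samples)
            assert 0 <= rec.true_onset < rec.true_offset <= rec.emg.shape[1]

    def test_detector_hits_planted_onset_at_high_snr(self):
        cfg = CohortConfig(
            n_subjects=1, n_positions=2, n_repetitions=3,
            hold_s=1.5, rest_s=0.75, seed=11, snr=20.0,
        )
        prof = make_profile(1, cfg, np.random.SeedSequence([11, 104729, 1]))
        recs = generate_subject(prof, cfg)
        hits = 0
        for rec in recs:
            emg_f = pre.filter_emg(rec.emg)
            seg = onset_mod.detect_active_region(onset_mod.energy_profile(emg_f).psi_rms)
            if abs(seg.onset_idx - rec.true_onset) <= 0.15 * 200:
                hits += 1
        assert hits / len(recs) >= 0.95

    def test_auto_detection_rate(self, tiny_cohort):
        """Single-hold trials should overwhelmingly auto-detect (>= 70%)."""
        n_auto = n = 0
        for _, recs in tiny_cohort:
            for rec in recs:
                emg_f = pre.filter_emg(rec.emg)
                seg = onset_mod.detect_active_region(onset_mod.energy_profile(emg_f).psi_rms)
                n += 1
                n_auto += seg.status == "auto"
        assert n_auto / n >= 0.70


class TestCohort:
    def test_subject_count_and_layout(self, tiny_cohort, tiny_cfg):
        assert len(tiny_cohort) == tiny_cfg.n_subjects
        for prof, recs in tiny_cohort:
            assert len(recs) == tiny_cfg.n_gestures * tiny_cfg.n_positions * tiny_cfg.n_repetitions

    def test_single_subject_cohort(self):
        cfg = CohortConfig(n_subjects=1, n_positions=1, n_repetitions=1,
                           hold_s=0.5, rest_s=0.25, seed=2)
        assert len(generate_cohort(cfg)) == 1

    def test_disk_roundtrip(self, tmp_path, tiny_cohort):
        save_cohort(tiny_cohort[:1], tmp_path)
        loaded = load_cohort(tmp_path)
        assert len(loaded) == 1
        prof, recs = loaded[0]
        orig_prof, orig_recs = tiny_cohort[0]
        assert prof.channel_rotation == orig_prof.channel_rotation
        np.testing.assert_array_equal(prof.channel_gains, orig_prof.channel_gains)
        assert len(recs) == len(orig_recs)
        by_key = {(r.gesture_id, r.position_id, r.repetition): r for r in recs}
        for orig in orig_recs:
            r = by_key[(orig.gesture_id, orig.position_id, orig.repetition)]
            np.testing.assert_array_equal(r.emg, orig.emg)
            np.testing.assert_array_equal(r.accel, orig.accel)
            assert r.true_onset == orig.true_onset

    def test_gravity_angles_across_positions(self, tiny_cohort):
        # raw accelerometer rest-period means encode arm position
        prof, recs = tiny_cohort[0]
        means = {}
        for rec in recs:
            rest = rec.accel[:, : rec.true_onset * 50 // 200 - 5]
            means.setdefault(rec.position_id, []).append(rest.mean(axis=1))
        dirs = {p: np.mean(v, axis=0) for p, v in means.items()}
        dirs = {p: v / np.linalg.norm(v) for p, v in dirs.items()}
        ps = sorted(dirs)
        for i, a in enumerate(ps):
            for b in ps[i + 1:]:
                ang = np.degrees(np.arccos(np.clip(dirs[a] @ dirs[b], -1, 1)))
                assert ang > 20.0


class TestSeparabilityKnob:
    def _centroid_accuracy(self, class_sep, seed=3):
        cfg = CohortConfig(
            n_subjects=1, n_positions=1, n_repetitions=6,
            hold_s=1.0, rest_s=0.5, seed=seed, snr=10.0,
            class_sep=class_sep, rotation_max=0, gain_jitter=0.0,
        )
        prof = make_profile(1, cfg, np.random.SeedSequence([seed, 104729, 1]))
        fm = pl.subject_feature_matrix(generate_subject(prof, cfg), segmentation="true")
        train = fm.repetitions <= 3
        mu = fm.values[train].mean(0)
        sd = fm.values[train].std(0)
        sd[sd == 0] = 1
        Xtr = (fm.values[train] - mu) / sd
        Xte = (fm.values[~train] - mu) / sd
        cents = {g: Xtr[fm.labels[train] == g].mean(0) for g in np.unique(fm.labels)}
        gs = sorted(cents)
        d = np.stack([np.linalg.norm(Xte - cents[g], axis=1) for g in gs], axis=1)
        pred = np.array(gs)[np.argmin(d, axis=1)]
        return float(np.mean(pred == fm.labels[~train]))

    def test_separable_templates_beat_90(self):
        assert self._centroid_accuracy(1.0) > 0.90

    def test_identical_templates_near_chance(self):
        acc = self._centroid_accuracy(0.0)
        # binomial 95% envelope around 1/7 for 441 test windows is ~ +-0.05
        assert abs(acc - 1 / 7) < 0.08


class TestPlantedBilinear:
    def test_shapes(self):
        Z, X, W, Y = plant_bilinear_dataset(4, 30, I=2, J=3, n_channels=5, seed=0)
        assert Z.shape == (4, 2) and X.shape == (30, 3)
        assert W.shape == (5, 2, 3) and Y.shape == (4, 30, 5)

    def test_rank_one_case(self):
        Z, X, W, Y = plant_bilinear_dataset(3, 10, I=1, J=1, n_channels=4, seed=1)
        # each channel slice is an outer product scaled by the scalar W_k
        for k in range(4):
            assert np.linalg.matrix_rank(Y[:, :, k]) == 1
            np.testing.assert_allclose(Y[:, :, k], W[k, 0, 0] * np.outer(Z[:, 0], X[:, 0]))

    def test_gauge_invariance(self, rng):
        Z, X, W, Y = plant_bilinear_dataset(4, 20, I=2, J=3, n_channels=6, seed=2)
        A = rng.normal(size=(2, 2))
        B = rng.normal(size=(3, 3))
        Z2 = Z @ A.T
        X2 = X @ B.T
        W2 = np.einsum("ai,kij,bj->kab", np.linalg.inv(A).T, W, np.linalg.inv(B).T)
        Y2 = np.einsum("si,kij,tj->stk", Z2, W2, X2)
        np.testing.assert_allclose(Y, Y2, atol=1e-10)

    def test_noise_and_validation(self):
        with pytest.raises(ValueError):
            plant_bilinear_dataset(2, 5, I=0, J=1)
        with pytest.raises(ValueError):
            plant_bilinear_dataset(2, 5, noise_sd=-1.0)
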