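"""BLS quality gate: closed-form solves, incremental widening, integrity flags."""

import copy

import numpy as np
import pytest

from iopscreen.phantom import ArtifactSpec, inject_artifact
from iopscreen.qc import (
    BLSQualityMonitor,
    build_quality_dataset,
    classify_quality,
    edge_integrity_check,
    fit_output_weights,
    normalized_cross_correlation,
    quality_targets,
)


class TestFeatureMapping:
    def test_zero_weights_give_half_activation(self):
        bls = BLSQualityMonitor(n_feature_nodes=4, n_enhancement_nodes=2)
        X = np.random.default_rng(0).random((3, 5))
        bls.fit(X, np.zeros(3))
        bls.W_feat_[:] = 0.0
        bls.b_feat_[:] = 0.0
        bls.W_enh_[:] = 0.0
        bls.b_enh_[:] = 0.0
        Z = bls.map_features(X)
        assert np.allclose(Z, 0.5)
        assert Z.shape == (3, 6)  # m + p columns

    def test_hand_computed_sigmoid_chain(self):
        bls = BLSQualityMonitor(n_feature_nodes=2, n_enhancement_nodes=1)
        X = np.array([[1.0, 2.0]])
        bls.fit(X, np.zeros(1))
        bls.W_feat_ = np.array([[1.0, 0.0], [0.0, -1.0]])
        bls.b_feat_ = np.array([0.5, 0.0])
        bls.W_enh_ = np.array([[2.0], [1.0]])
        bls.b_enh_ = np.array([-0.5])
        sig = lambda v: 1 / (1 + np.exp(-v))
        h = sig(np.array([1.0 * 1 + 0.5, -2.0]))
        z = sig(h @ np.array([[2.0], [1.0]]) + (-0.5))
        out = bls.map_features(X)
        assert np.allclose(out, np.concatenate([h, z.ravel()])[None])
        assert np.all((out > 0) & (out < 1))

    def test_dimension_mismatch_rejected(self):
        bls = BLSQualityMonitor(n_feature_nodes=3, n_enhancement_nodes=1)
        bls.fit(np.random.default_rng(0).random((4, 6)), np.zeros(4))
        with pytest.raises(ValueError):
            bls.map_features(np.zeros((2, 9)))


class TestRidgeSolve:
    def test_square_full_rank_interpolates_at_zero_penalty(self, rng):
        Z = rng.normal(size=(6, 6)) + np.eye(6)
        y = rng.normal(size=6)
        w = fit_output_weights(Z, y, 0.0)
        assert np.allclose(Z @ w, y, atol=1e-8)

    def test_large_penalty_shrinks_weights(self, rng):
        Z = rng.normal(size=(40, 10))
        y = rng.normal(size=40)
        w0 = fit_output_weights(Z, y, 0.0)
        w_big = fit_output_weights(Z, y, 1e9)
        assert np.linalg.norm(w_big) < 1e-6 * np.linalg.norm(w0)

    def test_matches_independent_normal_equation_solve(self, rng):
        for _ in range(10):
            n, d = rng.integers(20, 100), rng.integers(5, 100)
            Z = rng.normal(size=(n, d))
            y = rng.normal(size=n)
            lam = float(rng.uniform(0.01, 1.0))
            w = fit_output_weights(Z, y, lam)
            oracle = np.linalg.solve(Z.T @ Z + lam * np.eye(d), Z.T @ y)
            assert np.abs(w - oracle).max() < 1e-8


class TestIncrementalWidening:
    @pytest.fixture()
    def fitted(self, rng):
        X = rng.random((200, 40))
        y = rng.random(200)
        return BLSQualityMonitor(
            n_feature_nodes=30, n_enhancement_nodes=10, random_state=1
        ).fit(X, y)

    def test_zero_delta_is_identity(self, fitted):
        w = fitted.output_weights_.copy()
        fitted.add_enhancement_nodes(0)
        assert np.array_equal(fitted.output_weights_, w)

    def test_widening_never_raises_training_mse(self, fitted):
        before = fitted.training_mse()
        fitted.add_enhancement_nodes(50)
        assert fitted.training_mse() <= before + 1e-12
        assert fitted.n_enhancement_nodes == 60

    def test_incremental_equals_full_retrain(self, fitted):
        full = copy.deepcopy(fitted)
        seed = fitted._enh_seed
        fitted.add_enhancement_nodes(25)
        # oracle: rebuild the widened design and solve from scratch
        rng2 = np.random.default_rng(seed)
        m = full.n_feature_nodes
        W = rng2.normal(0, 1 / np.sqrt(m), size=(m, 25))
        b = rng2.uniform(-1, 1, size=25)
        B = 1 / (1 + np.exp(-(full._H_train @ W + b)))
        A2 = np.concatenate([full._design, B], axis=1)
        w_full = fit_output_weights(A2, full._y_train, full.ridge_lambda)
        assert np.abs(w_full - fitted.output_weights_).max() < 1e-6


class TestGate:
    def test_threshold_boundary_inclusive(self):
        assert classify_quality(0.71, 0.7)
        assert classify_quality(0.70, 0.7)
        assert not classify_quality(0.69, 0.7)

    def test_gate_monotone_in_threshold(self, small_cohort):
        imgs, targ, _ = build_quality_dataset(small_cohort[:40], seed=1)
        bls = BLSQualityMonitor(
            n_feature_nodes=50, n_enhancement_nodes=20, random_state=0
        ).fit(imgs, targ)
        scores = bls.score_samples(imgs)
        accept_lo = scores >= 0.5
        accept_hi = scores >= 0.8
        # raising T never converts a rejected sample into an accepted one
        assert not np.any(accept_hi & ~accept_lo)

    def test_scores_deterministic_and_clean_beats_corrupted(self, small_cohort):
        imgs, targ, clean = build_quality_dataset(small_cohort[:60], seed=2)
        bls = BLSQualityMonitor(
            n_feature_nodes=100, n_enhancement_nodes=50, random_state=0
        ).fit(imgs, targ)
        heavy = inject_artifact(
            small_cohort[61].image, ArtifactSpec("texture_noise", 0.9), seed=3
        )
        assert bls.quality_score(small_cohort[61].image) > bls.quality_score(heavy)
        s1 = bls.score_samples(imgs[:5])
        s2 = bls.score_samples(imgs[:5])
        assert np.array_equal(s1, s2)

    def test_unfitted_model_rejected(self):
        with pytest.raises(RuntimeError):
            BLSQualityMonitor().score_samples(np.zeros((1, 32, 32)))


class TestTargets:
    def test_ncc_bounds_and_identity(self, small_cohort):
        img = small_cohort[0].image
        assert normalized_cross_correlation(img, img) == pytest.approx(1.0)
        t = quality_targets([img], [img])
        assert t[0] == pytest.approx(1.0)

    def test_targets_decrease_with_magnitude(self, small_cohort):
        img = small_cohort[0].image
        mags = np.array([0.0, 0.4, 0.8])
        corr = [inject_artifact(img, ArtifactSpec("texture_noise", m), seed=1)
                if m else img for m in mags]
        t = quality_targets(corr, [img] * 3, mags)
        assert t[0] > t[1] > t[2]


class TestIntegrity:
    def test_clean_phantom_raises_no_flags(self, small_cohort):
        assert edge_integrity_check(small_cohort[0].image) == []

    def test_discontinuity_flagged_on_paired_corruption(self, small_cohort):
        bad = inject_artifact(
            small_cohort[0].image, ArtifactSpec("edge_discontinuity", 0.5), seed=1
        )
        assert "edge_discontinuity" in edge_integrity_check(bad)

    def test_saturation_flagged(self, small_cohort):
        bad = inject_artifact(
            small_cohort[0].image, ArtifactSpec("bright_region", 0.7), seed=1
        )
        assert "saturated_region" in edge_integrity_check(bad)

    def test_blank_image_flags_missing_contour(self):
        assert edge_integrity_check(np.zeros((64, 64))) == ["missing_contour"]
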