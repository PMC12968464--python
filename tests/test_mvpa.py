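"""Searchlight MVPA: labelling, geometry, whitening, crossnobis estimator."""

import numpy as np
import pandas as pd
import pytest

from densnav import mvpa


class TestLabelEvents:
    def test_density_median_split(self, session):
        lab = mvpa.label_events(session.events, "density")
        stacks = session.events[session.events.event_type == "adjust_stack"]
        assert len(lab) == len(stacks)
        merged = lab.merge(
            stacks[["onset", "density_level"]], on="onset", how="left"
        )
        low = merged[merged.label == "low"]["density_level"]
        high = merged[merged.label == "high"]["density_level"]
        assert low.max() <= 12 and high.min() >= 13  # 26 levels: 0-12 vs 13-25

    def test_label_can_switch_within_trial(self, session):
        lab = mvpa.label_events(session.events, "density")
        switches = sum(
            g["label"].nunique() > 1 for _, g in lab.groupby("trial_index")
        )
        assert switches > 0

    def test_direction_uses_press_state(self, session):
        lab = mvpa.label_events(session.events, "direction")
        assert set(lab.condition) <= {"MA", "NA"}
        assert set(lab.label) <= {"up", "down"}

    def test_target_scheme_one_label_per_memory_trial(self, session):
        lab = mvpa.label_events(session.events, "target")
        assert set(lab.condition) <= {"MA", "MP"}
        assert lab.groupby("trial_index").size().eq(1).all()

    def test_scheme_condition_mismatch_raises(self, session):
        na_only = session.events[session.events.condition == "NA"]
        with pytest.raises(ValueError):
            mvpa.label_events(na_only, "target")
        with pytest.raises(ValueError):
            mvpa.label_events(session.events, "bogus")


class TestSearchlightGeometry:
    def test_interior_sphere_has_seven_members(self):
        mask = np.ones((7, 7, 7), dtype=bool)
        spheres = mvpa.searchlight_neighborhoods(mask, 4.0, 3.0)
        center = np.flatnonzero(
            (spheres.centers == [3, 3, 3]).all(axis=1)
        )[0]
        members = spheres.members(center)
        assert len(members) == 7  # center + 6 face neighbors at 3 mm
        assert spheres.center_flat[center] in members

    def test_radius_zero_single_member(self):
        mask = np.ones((3, 3, 3), dtype=bool)
        spheres = mvpa.searchlight_neighborhoods(mask, 0.0, 3.0)
        assert np.all(spheres.sizes == 1)

    def test_corner_clipped_to_mask(self):
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[:2, :2, :2] = True
        spheres = mvpa.searchlight_neighborhoods(mask, 4.0, 3.0)
        corner = np.flatnonzero((spheres.centers == [0, 0, 0]).all(axis=1))[0]
        assert spheres.sizes[corner] == 4  # center + 3 in-mask face neighbors


class TestWhitening:
    def test_white_noise_whitening_is_near_identity(self):
        rng = np.random.default_rng(0)
        R = rng.normal(size=(5000, 5))
        sigma, lam = mvpa.shrunk_covariance(R)
        np.testing.assert_allclose(sigma, np.eye(5), atol=0.08)
        W = mvpa.whitening_matrix(sigma)
        np.testing.assert_allclose(W, np.eye(5), atol=0.08)

    def test_full_shrinkage_is_diagonal_scaling(self):
        rng = np.random.default_rng(1)
        R = rng.normal(size=(100, 4)) @ np.diag([1.0, 2.0, 0.5, 3.0])
        sigma, _ = mvpa.shrunk_covariance(R, shrinkage=1.0)
        off = sigma[~np.eye(4, dtype=bool)]
        assert np.all(off == 0)
        np.testing.assert_allclose(np.diag(sigma), R.var(axis=0, ddof=1))

    def test_known_correlation_whitened_to_identity(self):
        """Two voxels with rho = 0.6: W Sigma W' = I analytically."""
        rho = 0.6
        sigma_true = np.array([[1.0, rho], [rho, 1.0]])
        W = mvpa.whitening_matrix(sigma_true)
        np.testing.assert_allclose(W @ sigma_true @ W.T, np.eye(2), atol=1e-10)
        # and empirically: whitened residual covariance approaches identity
        rng = np.random.default_rng(2)
        L = np.linalg.cholesky(sigma_true)
        R = rng.normal(size=(20000, 2)) @ L.T
        sigma_est, lam = mvpa.shrunk_covariance(R)
        Wh = mvpa.whitening_matrix(sigma_est)
        cov_w = np.cov((R @ Wh.T).T)
        np.testing.assert_allclose(cov_w, np.eye(2), atol=0.05)
        assert lam < 0.1  # plenty of data: shrinkage nearly vanishes

    def test_shrinkage_decays_with_frames_for_correlated_noise(self):
        """With genuinely correlated noise the off-diagonals are signal, so
        the analytic shrinkage weight falls as frames accumulate (it stays
        near 1 for truly independent voxels at any sample size)."""
        rng = np.random.default_rng(3)
        sigma_true = 0.5 * np.ones((6, 6)) + 0.5 * np.eye(6)
        L = np.linalg.cholesky(sigma_true)
        lams = []
        for t in (20, 2000):
            R = rng.normal(size=(t, 6)) @ L.T
            lams.append(mvpa.shrunk_covariance(R)[1])
        assert lams[0] > lams[1]
        assert lams[1] < 0.2

    def test_sklearn_ledoit_wolf_agrees_on_spherical_data(self):
        """On iid data the variance-retaining target coincides with the
        scaled-identity target, so intensities should be comparable."""
        sklearn_cov = pytest.importorskip("sklearn.covariance")
        rng = np.random.default_rng(4)
        R = rng.normal(size=(40, 6))
        _, lam = mvpa.shrunk_covariance(R)
        lw = sklearn_cov.LedoitWolf().fit(R)
        assert abs(lam - lw.shrinkage_) < 0.35

    def test_sphere_exceeding_df_rejected(self):
        rng = np.random.default_rng(5)
        with pytest.raises(ValueError):
            mvpa.whiten_betas(rng.normal(size=6), rng.normal(size=(5, 6)))


def _null_cohort(rng, n_sub=5, shape=(6, 6, 6), t_frames=40):
    betas, residuals = [], []
    for _ in range(n_sub):
        betas.append(
            {"a": rng.normal(size=shape), "b": rng.normal(size=shape)}
        )
        residuals.append(rng.normal(size=(t_frames, int(np.prod(shape)))))
    return betas, residuals


class TestCrossnobis:
    def test_zero_test_pattern_gives_zero_fold(self):
        rng = np.random.default_rng(0)
        betas, residuals = _null_cohort(rng)
        same = rng.normal(size=(6, 6, 6))
        betas[2] = {"a": same, "b": same.copy()}  # test diff identically zero
        mask = np.ones((6, 6, 6), dtype=bool)
        spheres = mvpa.searchlight_neighborhoods(mask, 4.0, 3.0)
        folds = mvpa.crossnobis_loso(betas, spheres, residuals, whiten=None)
        centers = ~np.isnan(folds[2])
        assert np.allclose(folds[2][centers], 0.0)

    def test_fold_count_equals_subjects(self):
        rng = np.random.default_rng(1)
        betas, residuals = _null_cohort(rng, n_sub=6)
        mask = np.ones((6, 6, 6), dtype=bool)
        spheres = mvpa.searchlight_neighborhoods(mask, 4.0, 3.0)
        folds = mvpa.crossnobis_loso(betas, spheres, residuals, whiten="diag")
        assert len(folds) == 6

    def test_planted_pattern_localized(self):
        """A shared noiseless pattern difference yields positive distance in
        its region and zero outside."""
        shape = (8, 8, 8)
        rng = np.random.default_rng(2)
        pattern = np.zeros(shape)
        pattern[2:5, 2:5, 2:5] = rng.normal(0, 1.0, size=(3, 3, 3))
        betas = [{"a": -pattern / 2, "b": pattern / 2} for _ in range(4)]
        residuals = [rng.normal(size=(40, int(np.prod(shape)))) for _ in range(4)]
        mask = np.ones(shape, dtype=bool)
        spheres = mvpa.searchlight_neighborhoods(mask, 4.0, 3.0)
        folds = mvpa.crossnobis_loso(betas, spheres, residuals, whiten=None)
        mean_map = np.nanmean(folds, axis=0)
        inside = mean_map[3, 3, 3]
        outside = mean_map[6, 6, 6]
        assert inside > 0.1
        assert outside == pytest.approx(0.0, abs=1e-12)

    def test_unbiased_under_null_while_naive_is_positive(self):
        """Cross-validation removes the positive bias of the naive squared
        distance (small-scale version of the calibration suite)."""
        rng = np.random.default_rng(3)
        cv_means, naive_means = [], []
        mask = np.ones((6, 6, 6), dtype=bool)
        spheres = mvpa.searchlight_neighborhoods(mask, 4.0, 3.0)
        for _ in range(30):
            betas, residuals = _null_cohort(rng, n_sub=5)
            folds = mvpa.crossnobis_loso(betas, spheres, residuals,
                                         whiten="diag")
            cv_means.append(np.nanmean(folds))
            naive_means.append(
                np.nanmean(mvpa.naive_distance_map(betas, spheres,
                                                   residuals, whiten="diag"))
            )
        cv = np.mean(cv_means)
        se = np.std(cv_means, ddof=1) / np.sqrt(len(cv_means))
        assert abs(cv) < 3 * se
        assert np.mean(naive_means) > 10 * se

    def test_rescaling_invariance_with_whitening(self):
        """Jointly rescaling betas and residuals per voxel leaves whitened
        distances unchanged (whitening absorbs the scale)."""
        rng = np.random.default_rng(4)
        betas, residuals = _null_cohort(rng, n_sub=4, shape=(5, 5, 5))
        mask = np.ones((5, 5, 5), dtype=bool)
        spheres = mvpa.searchlight_neighborhoods(mask, 4.0, 3.0)
        base = mvpa.crossnobis_loso(betas, spheres, residuals, whiten="diag")
        scale = rng.uniform(0.5, 2.0, size=125)
        betas2 = [
            {k: (v.reshape(-1) * scale).reshape(5, 5, 5) for k, v in b.items()}
            for b in betas
        ]
        residuals2 = [r * scale for r in residuals]
        scaled = mvpa.crossnobis_loso(betas2, spheres, residuals2, whiten="diag")
        for a, b in zip(base, scaled):
            np.testing.assert_allclose(np.nan_to_num(a), np.nan_to_num(b),
                                       atol=1e-10)

    def test_lw_whitening_path_runs_and_matches_diag_on_white_noise(self):
        rng = np.random.default_rng(5)
        betas, residuals = _null_cohort(rng, n_sub=4, t_frames=200)
        mask = np.ones((6, 6, 6), dtype=bool)
        spheres = mvpa.searchlight_neighborhoods(mask, 4.0, 3.0)
        lw = mvpa.crossnobis_loso(betas, spheres, residuals,
                                  whiten="lw_retain_var")
        dg = mvpa.crossnobis_loso(betas, spheres, residuals, whiten="diag")
        a = np.nan_to_num(np.stack(lw))
        b = np.nan_to_num(np.stack(dg))
        # with iid residuals the estimated covariances are near-diagonal
        assert np.corrcoef(a.ravel(), b.ravel())[0, 1] > 0.95

    def test_needs_three_subjects_and_two_labels(self):
        rng = np.random.default_rng(6)
        betas, residuals = _null_cohort(rng, n_sub=2)
        mask = np.ones((6, 6, 6), dtype=bool)
        spheres = mvpa.searchlight_neighborhoods(mask, 4.0, 3.0)
        with pytest.raises(ValueError):
            mvpa.crossnobis_loso(betas, spheres, residuals, whiten=None)


class TestSmoothing:
    def test_fwhm_zero_is_identity(self):
        rng = np.random.default_rng(0)
        vol = rng.normal(size=(5, 5, 5))
        np.testing.assert_array_equal(mvpa.smooth_map(vol, 0.0, 3.0), vol)

    def test_delta_profile_has_requested_fwhm(self):
        """A point source smoothed at 6-mm FWHM has SD 6/2.3548 mm."""
        vol = np.zeros((21, 21, 21))
        vol[10, 10, 10] = 1.0
        sm = mvpa.smooth_map(vol, 6.0, 3.0)
        x = (np.arange(21) - 10) * 3.0
        profile = sm[:, 10, 10]
        sd = np.sqrt(np.sum(profile * x**2) / np.sum(profile))
        assert sd == pytest.approx(6.0 / mvpa.FWHM_TO_SIGMA, rel=0.05)
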