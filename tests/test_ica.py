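import numpy as np
import pytest
from scipy import stats

from petidif.blood import apply_dispersion
from petidif.carotid import build_carotid_mask
from petidif.curves import FrameSchedule, TimeActivityCurve
from petidif.evaluation import amari_index
from petidif.ica import (ALDICA, ALDParams, MixtureMatrix, ald_log_density,
                         ald_rvs, ald_score, ald_skewness, arrange_matrix,
                         build_blood_mask, estimate_ald_params, ica_mle,
                         ica_pursuit, pca_reduce, smooth_roi)
from petidif.image import DynamicImage
from petidif.phantom import FengParams, bolus_input


def mixture_fixture(seed, n_voxels=5000, kappa=0.7):
    """Bolus + delayed/dispersed bolus mixed by sparse ALD spatial weights."""
    t = np.arange(0.0, 300.0, 2.0)
    a1 = bolus_input(t, FengParams())
    tf = np.arange(0.0, 300.0, 0.5)
    a2 = apply_dispersion(
        TimeActivityCurve(tf, bolus_input(tf, FengParams(t0=25.0))), 10.0)(t)
    A = np.column_stack([a1, a2])
    rng = np.random.default_rng(seed)
    S = np.abs(np.vstack([ald_rvs(ALDParams(1.0, 1.0, kappa), n_voxels, rng),
                          ald_rvs(ALDParams(1.0, 1.0, kappa), n_voxels, rng)]))
    return A @ S, A, t


class TestALD:
    def test_density_normalizes(self):
        for p in (ALDParams(0.0, 1.0, 1.0), ALDParams(2.0, 0.5, 0.4),
                  ALDParams(-1.0, 2.0, 3.0)):
            y = np.linspace(p.m - 60 * p.sigma, p.m + 60 * p.sigma, 400001)
            integral = np.trapezoid(np.exp(ald_log_density(y, p)), y)
            assert integral == pytest.approx(1.0, abs=1e-4)

    def test_symmetric_case_density_at_mode(self):
        p = ALDParams(0.0, 1.0, 1.0)
        assert np.exp(ald_log_density(0.0, p)) \
            == pytest.approx(1.0 / (p.sigma * np.sqrt(2.0)))

    def test_score_matches_numerical_derivative(self):
        p = ALDParams(0.5, 1.3, 0.7)
        for y in (-2.0, -0.5, 1.0, 3.0):  # away from the kink at m
            h = 1e-6
            num = -(ald_log_density(y + h, p) - ald_log_density(y - h, p)) \
                / (2 * h)
            assert ald_score(y, p) == pytest.approx(float(num), abs=1e-5)
        assert ald_score(p.m, p) == 0.0

    def test_unit_symmetric_score_value(self):
        p = ALDParams(0.0, np.sqrt(2.0), 1.0)
        assert ald_score(1.0, p) == pytest.approx(1.0)

    def test_skewness_sign_convention(self):
        rng = np.random.default_rng(0)
        right = ald_rvs(ALDParams(0.0, 1.0, 0.5), 200000, rng)
        left = ald_rvs(ALDParams(0.0, 1.0, 2.0), 200000, rng)
        assert stats.skew(right) > 0.5
        assert stats.skew(left) < -0.5
        assert ald_skewness(0.5) == pytest.approx(stats.skew(right), abs=0.05)

    def test_moment_estimation_recovers_parameters(self):
        rng = np.random.default_rng(1)
        truth = ALDParams(0.0, 1.0, 0.5)
        est = estimate_ald_params(ald_rvs(truth, 100000, rng))
        assert est.sigma == pytest.approx(truth.sigma, rel=0.05)
        assert est.kappa == pytest.approx(truth.kappa, rel=0.05)
        assert abs(est.m - truth.m) < 0.05 * truth.sigma

    def test_location_equivariance(self):
        rng = np.random.default_rng(2)
        y = ald_rvs(ALDParams(0.0, 1.0, 0.8), 50000, rng)
        e0 = estimate_ald_params(y)
        e5 = estimate_ald_params(y + 5.0)
        assert e5.m - e0.m == pytest.approx(5.0, abs=1e-9)
        assert e5.sigma == pytest.approx(e0.sigma)
        assert e5.kappa == pytest.approx(e0.kappa)

    def test_estimation_input_validation(self):
        with pytest.raises(ValueError):
            estimate_ald_params(np.ones(5))
        with pytest.raises(ValueError):
            estimate_ald_params(np.ones(100))


class TestMaskingAndMatrix:
    def test_blood_mask_uniform_and_max(self, ideal_phantom):
        img, truth = ideal_phantom
        mask = build_blood_mask(img)
        mean = img.early_mean()
        assert mask[np.unravel_index(np.argmax(mean), mean.shape)]
        # covers all vascular structures over all planes
        for label, role in truth.region_roles.items():
            if role in ("arterial", "venous"):
                m = truth.region_masks[label]
                assert (mask & m).sum() == m.sum()
        uniform = DynamicImage(np.ones((4, 4, 4, 10)), 2.0,
                               FrameSchedule.from_durations([10] * 10))
        assert build_blood_mask(uniform).all()

    def test_smooth_roi_identity_and_constant(self, ideal_phantom):
        img, _ = ideal_phantom
        mask = build_blood_mask(img)
        same = smooth_roi(img, mask, fwhm=0.0)
        np.testing.assert_array_equal(same.voxels, img.voxels)
        const = DynamicImage(np.ones((8, 8, 8, 10)), 2.0,
                             FrameSchedule.from_durations([10] * 10))
        ball = np.zeros((8, 8, 8), dtype=bool)
        ball[2:6, 2:6, 2:6] = True
        sm = smooth_roi(const, ball, fwhm=3.0)
        np.testing.assert_allclose(sm.voxels[ball, :], 1.0, rtol=1e-10)

    def test_smooth_roi_spreads_hot_voxel_but_conserves_mass(self):
        vox = np.zeros((12, 12, 12, 2))
        vox[6, 6, 6, :] = 100.0
        img = DynamicImage(vox, 2.0, FrameSchedule.from_durations([10, 10]))
        mask = np.zeros((12, 12, 12), dtype=bool)
        mask[2:10, 2:10, 2:10] = True
        sm = smooth_roi(img, mask, fwhm=3.0)
        assert sm.voxels[6, 6, 6, 0] < 100.0
        assert sm.voxels[mask, 0].sum() == pytest.approx(100.0, rel=0.01)

    def test_arrange_matrix_round_trip(self, ideal_phantom):
        img, _ = ideal_phantom
        mask = build_blood_mask(img)
        mat = arrange_matrix(img, mask)
        assert mat.values.shape == (img.n_frames, int(mask.sum()))
        j = 5
        x, y, z = mat.voxel_map[j]
        np.testing.assert_array_equal(mat.values[:, j], img.voxels[x, y, z, :])
        back = mat.scatter_back(img.shape[:3])
        np.testing.assert_array_equal(back[mask, :].T, mat.values)
        assert np.all(back[~mask, :] == 0)


class TestPCAReduce:
    def test_whitened_covariance_is_identity(self):
        X, _, _ = mixture_fixture(0, n_voxels=2000)
        X += np.random.default_rng(0).normal(0, 0.1, X.shape)
        Z, wh = pca_reduce(X, 2)
        cov = Z @ Z.T / Z.shape[1]
        np.testing.assert_allclose(cov, np.eye(2), atol=1e-8)
        assert wh.eigenvalues[0] >= wh.eigenvalues[1]

    def test_matches_sklearn_pca_spectrum(self):
        sklearn = pytest.importorskip("sklearn.decomposition")
        rng = np.random.default_rng(3)
        X = rng.normal(size=(12, 400)) * np.linspace(1, 3, 12)[:, None]
        _, wh = pca_reduce(X, 4)
        pca = sklearn.PCA(n_components=4).fit(X.T)
        np.testing.assert_allclose(
            wh.eigenvalues, pca.explained_variance_ * (400 - 1) / 400,
            rtol=1e-8)

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(6, 300))
        Z, wh = pca_reduce(X, 6)
        Xc = X - X.mean(axis=1, keepdims=True)
        recon = wh.eigenvectors @ (np.sqrt(wh.eigenvalues)[:, None] * Z)
        np.testing.assert_allclose(recon, Xc, atol=1e-8)

    def test_rank_deficiency_rejected(self):
        one = np.outer(np.arange(10.0), np.ones(50))
        with pytest.raises(ValueError):
            pca_reduce(one, 2)


class TestICAEstimation:
    def test_identity_mixing_recovered(self):
        """Whitened independent ALD sources: demixing is near-identity."""
        rng = np.random.default_rng(5)
        S = np.vstack([ald_rvs(ALDParams(0.0, 1.0, 0.6), 4000, rng),
                       ald_rvs(ALDParams(0.0, 1.0, 1.5), 4000, rng)])
        Z, wh = pca_reduce(S, 2)
        fit = ica_mle(Z, seed=0)
        # gain relative to the whitened mixing of the identity mix
        Aw = (wh.eigenvectors / np.sqrt(wh.eigenvalues)).T @ np.eye(2)
        assert amari_index(fit.W @ Aw) < 0.05

    def test_bolus_mixture_separated_by_both_modes(self):
        X, A, _ = mixture_fixture(11)
        Z, wh = pca_reduce(X, 2)
        Aw = (wh.eigenvectors / np.sqrt(wh.eigenvalues)).T @ A
        assert amari_index(ica_mle(Z, seed=0).W @ Aw) < 0.1
        assert amari_index(ica_pursuit(Z).W @ Aw) < 0.1

    def test_same_seed_identical_demixing(self):
        X, _, _ = mixture_fixture(12)
        Z, _ = pca_reduce(X, 2)
        W1 = ica_mle(Z, seed=3).W
        W2 = ica_mle(Z, seed=3).W
        np.testing.assert_array_equal(W1, W2)

    def test_huge_step_contained_by_backtracking(self):
        """An absurd learning rate is rejected by the likelihood check
        instead of corrupting the demixing matrix."""
        X, _, _ = mixture_fixture(13, n_voxels=500)
        Z, _ = pca_reduce(X, 2)
        fit = ica_mle(Z, lr=1e9, max_iter=5, seed=0)
        assert np.all(np.isfinite(fit.W))

    def test_non_finite_input_rejected(self):
        Z = np.full((2, 100), np.nan)
        with pytest.raises(ValueError):
            ica_mle(Z, seed=0)


class TestSelectionAndModel:
    def test_arterial_selected_by_earlier_peak(self):
        X, A, t = mixture_fixture(20)
        mat = MixtureMatrix(X, t, np.zeros((X.shape[1], 3), dtype=int))
        res = ALDICA(mat).fit(seed=0)
        chosen = res.arterial_tac
        assert abs(np.corrcoef(chosen.values, A[:, 0])[0, 1]) \
            > abs(np.corrcoef(chosen.values, A[:, 1])[0, 1])
        # selection recorded for audit
        assert res.selection["chosen"] == res.arterial_index
        assert len(res.selection["candidates"]) == 2

    def test_sign_flip_does_not_change_selection(self):
        X, A, t = mixture_fixture(21)
        mat = MixtureMatrix(X, t, np.zeros((X.shape[1], 3), dtype=int))
        res = ALDICA(mat).fit(seed=1)
        # component curves have positive global extrema after sign fixing
        for tac in res.component_tacs:
            assert tac.values[np.argmax(np.abs(tac.values))] > 0

    def test_phantom_arterial_component(self, realistic_phantom):
        img, truth = realistic_phantom
        res = ALDICA.from_image(img).fit(seed=0)
        tac, record = res.arterial_whole_blood()
        ca = np.corrcoef(tac.values, truth.arterial.values)[0, 1]
        cv = np.corrcoef(tac.values, truth.venous.values)[0, 1]
        assert ca > 0.99 and ca > cv
        assert record["chosen"] in (0, 1)

    def test_carotid_only_roi_flags_degeneracy(self, realistic_phantom):
        """With only arterial signal in the ROI the second component is not
        blood-like and must be flagged, not silently returned."""
        img, _ = realistic_phantom
        cmask = build_carotid_mask(img, n_planes=img.n_planes // 3)
        vol = cmask.as_volume(img.shape[:3])
        sm = smooth_roi(img, vol, fwhm=3.0)
        res = ALDICA(arrange_matrix(sm, vol)).fit(seed=0)
        assert len(res.degenerate) >= 1

    def test_scale_invariance_of_extraction(self, realistic_phantom):
        """Multiplying the image by c changes the extracted curve by c
        exactly, so one-point calibration makes the IDIF scale-free."""
        img, _ = realistic_phantom
        res1 = ALDICA.from_image(img).fit(seed=0)
        scaled = DynamicImage(img.voxels * 3.0, img.voxel_size, img.schedule)
        res3 = ALDICA.from_image(scaled).fit(seed=0)
        t1, _ = res1.arterial_whole_blood()
        t3, _ = res3.arterial_whole_blood()
        np.testing.assert_allclose(t3.values, 3.0 * t1.values, rtol=1e-8)

    def test_summary_mentions_arterial_choice(self, realistic_phantom):
        img, _ = realistic_phantom
        res = ALDICA.from_image(img).fit(seed=0)
        text = res.summary()
        assert "arterial component" in text and "kappa" in text
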