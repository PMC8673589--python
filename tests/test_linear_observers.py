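"""Covariance estimation and the linear observer family."""

import numpy as np
import pytest
from scipy import stats

from denoiseiq import linear_observers as lo
from denoiseiq import phantom_imaging as pi
from denoiseiq._roc import empirical_auc


def make_cov(mean0, mean1, k):
    mean0, mean1 = np.asarray(mean0, float), np.asarray(mean1, float)
    k = np.asarray(k, float)
    return lo.CovarianceEstimate(mean0=mean0, mean1=mean1, k0=k, k1=k)


class TestCovarianceEstimation:
    def test_single_sample_classes_rejected(self):
        with pytest.raises(ValueError):
            lo.estimate_covariance_empirical(np.zeros((1, 2, 2)),
                                             np.zeros((5, 2, 2)))

    def test_frobenius_error_decays(self, rng):
        p = 16
        a = rng.normal(size=(p, p))
        k_true = a @ a.T / p + np.eye(p)
        chol = np.linalg.cholesky(k_true)
        errs = []
        for n in (200, 3200):
            g = rng.normal(size=(n, p)) @ chol.T
            est = lo.estimate_covariance_empirical(g, g + 1.0)
            errs.append(np.linalg.norm(est.pooled - k_true))
        # 16x the samples -> ~4x smaller error
        assert errs[1] < errs[0] / 2.0

    def test_delta_mean_matches_signal(self):
        cfg = pi.study_32(n_observer_calibration=2500)
        data = pi.generate_dataset(cfg, seed=3, splits=("observer_calibration",))
        g0, g1 = data["observer_calibration"].split_classes()
        est = lo.estimate_covariance_empirical(g0, g1)
        sig = pi.render_signal(cfg.signal, cfg.system).ravel()
        # per-pixel SE includes noise and lumpy-background variance
        se = np.sqrt((np.diag(est.k0) + np.diag(est.k1)) / 2500)
        assert (np.abs(est.delta_mean - sig) / se).max() < 6

    def test_decomposition_reduces_to_background_cov(self, rng):
        b = rng.normal(10, 2, size=(300, 4, 4))
        quiet = pi.NoiseParams(gaussian_std=0.0, poisson=False)
        est = lo.estimate_covariance_decomposition(b, b + 1.0, quiet)
        emp = lo.estimate_covariance_empirical(b, b + 1.0)
        np.testing.assert_allclose(est.pooled, emp.pooled, atol=1e-9)

    def test_decomposition_matches_empirical_monte_carlo(self):
        """K_bg + diag(mean) + sigma^2 I equals the noisy-sample covariance."""
        cfg = pi.study_32(n_observer_calibration=4000,
                          noise=pi.NoiseParams(gaussian_std=10.0, poisson=True))
        rng = np.random.default_rng(17)
        bg0 = pi.render_background_stack(4000, cfg.background, cfg.system, rng)
        bg1 = bg0 + pi.render_signal(cfg.signal, cfg.system)[None]
        dec = lo.estimate_covariance_decomposition(bg0, bg1, cfg.noise)
        g0 = pi.add_noise(bg0, cfg.noise, rng)
        g1 = pi.add_noise(bg1, cfg.noise, rng)
        emp = lo.estimate_covariance_empirical(g0, g1)
        # diagonals dominated by noise variance ~ mean + sigma^2
        d_dec, d_emp = np.diag(dec.pooled), np.diag(emp.pooled)
        assert np.abs(d_dec - d_emp).mean() < 0.05 * d_dec.mean()
        # off-diagonal structure from the background agrees on average
        off = ~np.eye(len(d_dec), dtype=bool)
        resid = np.abs(dec.pooled - emp.pooled)[off].mean()
        assert resid < 0.15 * np.abs(dec.pooled[off]).mean() + 2.0


class TestHotellingFamily:
    def test_identity_covariance_gives_matched_filter(self):
        cov = make_cov([0, 0], [1, 2], np.eye(2))
        w = lo.hotelling_template(cov).w
        np.testing.assert_allclose(w, [1, 2])
        np.testing.assert_allclose(lo.npwmf_template(cov).w, [1, 2])

    def test_diagonal_solve(self):
        cov = make_cov([0, 0], [1, 1], [[2, 0], [0, 1]])
        np.testing.assert_allclose(lo.hotelling_template(cov).w, [0.5, 1.0])

    def test_ill_conditioned_rejected(self):
        k = np.array([[1.0, 1.0], [1.0, 1.0]])  # singular
        with pytest.raises(np.linalg.LinAlgError, match="rho_template"):
            lo.hotelling_template(make_cov([0, 0], [1, 0], k))

    def test_ho_auc_matches_closed_form(self, gaussian_toy):
        """Equal-covariance Gaussian: AUC = Phi(d / sqrt 2)."""
        toy = gaussian_toy
        est = lo.estimate_covariance_empirical(toy["g0"], toy["g1"])
        w = lo.hotelling_template(est).w
        auc = empirical_auc(lo.apply_linear_template(w, toy["g0"]),
                            lo.apply_linear_template(w, toy["g1"])).auc
        expected = stats.norm.cdf(toy["d"] / np.sqrt(2))
        assert auc == pytest.approx(expected, abs=0.02)

    def test_npwmf_ignores_covariance(self):
        a = make_cov([0, 0], [2, 3], np.eye(2))
        b = make_cov([0, 0], [2, 3], [[5, 1], [1, 3]])
        np.testing.assert_array_equal(lo.npwmf_template(a).w,
                                      lo.npwmf_template(b).w)


class TestRho:
    def test_lambda_range_enforced(self):
        cov = make_cov([0], [1], [[1.0]])
        with pytest.raises(ValueError):
            lo.rho_template(cov, 1.5)

    def test_reduces_to_ho_for_well_conditioned(self, gaussian_toy):
        est = lo.estimate_covariance_empirical(gaussian_toy["g0"],
                                               gaussian_toy["g1"])
        w_ho = lo.hotelling_template(est).w
        w_rho = lo.rho_template(est, 1e-7).w
        np.testing.assert_allclose(w_rho, w_ho, rtol=1e-6)

    def test_rank2_pseudo_inverse_hand_computed(self):
        u = np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 0.0]])
        k = u @ np.diag([4.0, 1.0]) @ u.T  # rank-2 3x3
        delta = np.array([2.0, 3.0, 5.0])
        cov = make_cov(np.zeros(3), delta, k)
        w = lo.rho_template(cov, 0.1).w
        # pinv on retained subspace: [2/4, 3/1, 0]
        np.testing.assert_allclose(w, [0.5, 3.0, 0.0], atol=1e-12)
        w_trunc = lo.rho_template(cov, 0.5).w  # keeps only sigma=4
        np.testing.assert_allclose(w_trunc, [0.5, 0.0, 0.0], atol=1e-12)

    def test_retained_rank_nonincreasing_in_lambda(self, rng):
        a = rng.normal(size=(12, 12))
        cov = make_cov(np.zeros(12), rng.normal(size=12), a @ a.T)
        ranks = [lo.rho_template(cov, lam).rank
                 for lam in (1e-7, 1e-4, 1e-2, 0.2, 0.9)]
        assert all(r1 >= r2 for r1, r2 in zip(ranks, ranks[1:]))

    def test_single_candidate_returned(self, gaussian_toy):
        toy = gaussian_toy
        est = lo.estimate_covariance_empirical(toy["g0"][:500], toy["g1"][:500])
        ens = pi.ImageEnsemble(
            images=np.concatenate([toy["g0"][:100], toy["g1"][:100]]),
            labels=np.repeat([0, 1], 100))
        cfg, tpl = lo.select_rho_lambda(est, ens, candidates=[1e-4])
        assert cfg.lam == 1e-4 and tpl.lam == 1e-4

    def test_selected_lambda_is_grid_argmax(self, gaussian_toy):
        toy = gaussian_toy
        est = lo.estimate_covariance_empirical(toy["g0"][:500], toy["g1"][:500])
        ens = pi.ImageEnsemble(
            images=np.concatenate([toy["g0"][:400], toy["g1"][:400]]),
            labels=np.repeat([0, 1], 400))
        cfg, tpl = lo.select_rho_lambda(est, ens)
        # exhaustive check: no fixed-lambda template beats the selection
        assert cfg.validation_auc[cfg.lam] == max(cfg.validation_auc.values())


class TestChannels:
    def test_dog_profiles_vanish_at_dc(self):
        cs = lo.dog_channel_matrix((32, 32))
        # DC response = sum of the spatial template
        assert np.abs(cs.t.sum(axis=1)).max() < 1e-10

    def test_default_channel_count(self):
        cs = lo.dog_channel_matrix((16, 16))
        assert cs.t.shape == (10, 256)
        assert cs.params.sigma0 == 0.005 and cs.params.alpha == 1.4 \
            and cs.params.q == 1.67

    def test_peak_frequency_matches_grid_search(self):
        """Radial profile peaks where a dense 1-D search says it should."""
        p = lo.DogChannelParams()
        rho = np.linspace(1e-6, 0.7, 200_000)
        for j in (4, 7, 10):
            sj = p.sigma0 * p.alpha ** j
            prof = np.exp(-0.5 * (rho / (p.q * sj)) ** 2) \
                - np.exp(-0.5 * (rho / sj) ** 2)
            peak_numeric = rho[np.argmax(prof)]
            # closed form: rho* = sj * Q * sqrt(4 ln Q / (Q^2 - 1))
            peak_closed = sj * p.q * np.sqrt(4 * np.log(p.q) / (p.q ** 2 - 1))
            assert peak_numeric == pytest.approx(peak_closed, rel=1e-3)

    def test_channelize_identity_and_linearity(self, rng):
        g = rng.normal(size=(4, 3, 3))
        ident = lo.ChannelSet(t=np.eye(9), params=lo.DogChannelParams(),
                              shape=(3, 3), center=(1, 1))
        np.testing.assert_allclose(lo.channelize(ident, g), g.reshape(4, 9))
        cs = lo.dog_channel_matrix((3, 3))
        v = lo.channelize(cs, g)
        np.testing.assert_allclose(lo.channelize(cs, 2 * g), 2 * v, atol=1e-10)

    def test_channelized_covariance_identity(self, rng):
        """K_v = T K_g T^T on Gaussian samples."""
        p = 16
        a = rng.normal(size=(p, p))
        k = a @ a.T / p + np.eye(p)
        g = rng.normal(size=(6000, p)) @ np.linalg.cholesky(k).T
        t = rng.normal(size=(3, p))
        v = g @ t.T
        kv_emp = np.cov(v, rowvar=False)
        kv_alg = t @ k @ t.T
        assert np.abs(kv_emp - kv_alg).max() < 0.12 * np.abs(kv_alg).max()


class TestCho:
    def test_zero_internal_noise_identity_channels_is_ho(self, gaussian_toy):
        toy = gaussian_toy
        n = 1000
        rng = np.random.default_rng(0)
        v0, v1 = toy["g0"][:n].reshape(n, -1), toy["g1"][:n].reshape(n, -1)
        t0 = lo.cho_statistics(v0, v1, v0, lo.InternalNoiseParams(0.0), rng)
        t1 = lo.cho_statistics(v0, v1, v1, lo.InternalNoiseParams(0.0), rng)
        est = lo.estimate_covariance_empirical(v0, v1)
        w = lo.hotelling_template(est).w
        # identical decisions: same AUC as the HO on the same data
        auc_cho = empirical_auc(t0, t1).auc
        auc_ho = empirical_auc(v0 @ w, v1 @ w).auc
        assert auc_cho == pytest.approx(auc_ho, abs=1e-12)

    def test_internal_noise_degrades_auc(self):
        cfg = pi.study_32(n_observer_calibration=600)
        data = pi.generate_dataset(cfg, seed=19, splits=("observer_calibration",))
        g0, g1 = data["observer_calibration"].split_classes()
        cs = lo.dog_channel_matrix((32, 32), center=cfg.signal.center)
        v0 = lo.channelize(cs, g0)
        v1 = lo.channelize(cs, g1)
        rng = np.random.default_rng(1)
        a_clean = empirical_auc(
            lo.cho_statistics(v0, v1, v0, lo.InternalNoiseParams(0.0), rng),
            lo.cho_statistics(v0, v1, v1, lo.InternalNoiseParams(0.0), rng)).auc
        rng = np.random.default_rng(2)
        a_noisy = empirical_auc(
            lo.cho_statistics(v0, v1, v0, lo.InternalNoiseParams(2.5), rng),
            lo.cho_statistics(v0, v1, v1, lo.InternalNoiseParams(2.5), rng)).auc
        assert a_noisy <= a_clean + 0.02


class TestTemplates:
    def test_zero_template_gives_chance_auc(self, rng):
        g = rng.normal(size=(50, 2, 2))
        t = lo.apply_linear_template(np.zeros(4), g)
        assert empirical_auc(t[:25], t[25:]).auc == 0.5

    def test_hand_computed_dot_product(self):
        img = np.array([[1.0, 2.0], [3.0, 4.0]])
        w = np.array([1.0, 0.5, -1.0, 2.0])
        assert lo.apply_linear_template(w, img[None])[0] == \
            pytest.approx(1 + 1 - 3 + 8)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            lo.apply_linear_template(np.zeros(5), np.zeros((2, 2, 2)))

    def test_auc_invariant_under_consistent_linear_map(self, gaussian_toy):
        """Invertible data transform + template recomputation preserves AUC."""
        toy = gaussian_toy
        n = 2000
        g0 = toy["g0"][:n].reshape(n, -1)
        g1 = toy["g1"][:n].reshape(n, -1)
        rng = np.random.default_rng(9)
        m = rng.normal(size=(25, 25)) + 5 * np.eye(25)
        est = lo.estimate_covariance_empirical(g0, g1)
        w = lo.hotelling_template(est).w
        auc = empirical_auc(g0 @ w, g1 @ w).auc
        h0, h1 = g0 @ m.T, g1 @ m.T
        est2 = lo.estimate_covariance_empirical(h0, h1)
        w2 = lo.hotelling_template(est2).w
        auc2 = empirical_auc(h0 @ w2, h1 @ w2).auc
        assert auc2 == pytest.approx(auc, abs=1e-9)
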