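"""Rician density, noise-scale estimation, and the per-pixel fits."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import integrate
from scipy import stats as sps

import t2mapping as t2


class TestLogpdf:
    def test_rayleigh_case(self):
        # nu=0, m=1, sigma=1: log(1 * exp(-0.5) * I0(0)) = -0.5
        assert t2.rician_logpdf(1.0, 0.0, 1.0) == pytest.approx(-0.5)

    def test_high_precision_value(self):
        # frozen 50-digit evaluation of log m - (m^2+nu^2)/2 + log I0(100)
        assert t2.rician_logpdf(10.0, 10.0, 1.0) == pytest.approx(
            -0.9176822170633706, abs=1e-12
        )

    def test_normalizes_to_one(self):
        val, _ = integrate.quad(
            lambda m: np.exp(t2.rician_logpdf(m, 3.0, 1.0)), 0.0, 50.0
        )
        assert val == pytest.approx(1.0, abs=1e-6)

    @given(
        m=st.floats(0.01, 50.0),
        nu=st.floats(0.0, 50.0),
        sigma=st.floats(0.1, 10.0),
    )
    def test_matches_scipy_rice(self, m, nu, sigma):
        ours = t2.rician_logpdf(m, nu, sigma)
        theirs = sps.rice.logpdf(m, b=nu / sigma, scale=sigma)
        if np.isfinite(theirs):
            assert ours == pytest.approx(theirs, rel=1e-9, abs=1e-9)
        else:
            # scipy underflows in the deep tail; the scaled-Bessel form
            # stays finite there but must agree that the density is tiny
            assert ours < -500.0

    def test_rejects_bad_sigma(self):
        with pytest.raises(ValueError):
            t2.rician_logpdf(1.0, 1.0, 0.0)


class TestRicianMean:
    def test_rayleigh_mean(self):
        assert t2.rician_mean(0.0, 1.0) == pytest.approx(np.sqrt(np.pi / 2))

    def test_high_snr_limit(self):
        # bias ~ sigma^2/(2 nu) = 0.05 at nu=10, sigma=1
        assert t2.rician_mean(10.0, 1.0) == pytest.approx(10.0, rel=0.006)
        assert t2.rician_mean(10.0, 1.0) > 10.0

    def test_high_precision_value(self):
        assert t2.rician_mean(2.0, 1.0) == pytest.approx(2.27238342806874, abs=1e-12)

    def test_monte_carlo_agreement(self, rng):
        n = 10**6
        draws = np.hypot(2.0 + rng.normal(0, 1, n), rng.normal(0, 1, n))
        se = draws.std(ddof=1) / np.sqrt(n)
        assert abs(draws.mean() - t2.rician_mean(2.0, 1.0)) < 3 * se


class TestBackgroundSigma:
    def test_recovers_sigma_from_rayleigh_background(self):
        noise = t2.add_rician_noise(np.zeros((100, 100)), sigma=5.0, seed=4)
        est = t2.estimate_background_sigma(noise, np.ones((100, 100), bool))
        assert est == pytest.approx(5.0, rel=0.02)

    def test_scale_equivariance(self):
        mask = np.ones((100, 100), bool)
        e1 = t2.estimate_background_sigma(
            t2.add_rician_noise(np.zeros((100, 100)), 1.0, seed=5), mask
        )
        e2 = t2.estimate_background_sigma(
            t2.add_rician_noise(np.zeros((100, 100)), 2.0, seed=5), mask
        )
        assert e2 / e1 == pytest.approx(2.0, rel=0.05)

    def test_all_zero_background_warns(self):
        with pytest.warns(UserWarning, match="all-zero"):
            est = t2.estimate_background_sigma(np.zeros((4, 4)), np.ones((4, 4), bool))
        assert est == 0.0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            t2.estimate_background_sigma(np.zeros((4, 4)), np.zeros((4, 4), bool))


class TestPixelMLE:
    def test_noiseless_recovery(self, grase):
        sig = t2.decay_signal(t2.DecayParams(100.0, 50.3), grase)
        fr = t2.fit_pixel_mle(sig, grase, sigma=0.01)
        assert fr.converged
        assert fr.t2_hat == pytest.approx(50.3, rel=1e-3)
        assert np.isfinite(fr.loglik)

    def test_parameter_recovery_in_the_mean(self, mese):
        # 500 replicate noisy pixels at true T2 = 67.7 ms, sigma = 2
        clean = t2.decay_signal(t2.DecayParams(100.0, 67.7), mese)
        noisy = t2.add_rician_noise(np.tile(clean, (500, 1)), 2.0, seed=9)
        t2_hats = np.array(
            [t2.fit_pixel_mle(noisy[i], mese, sigma=2.0).t2_hat for i in range(500)]
        )
        assert np.nanmean(t2_hats) == pytest.approx(67.7, rel=0.02)

    def test_joint_sigma_estimation(self, grase):
        clean = t2.decay_signal(t2.DecayParams(100.0, 60.0), grase)
        noisy = t2.add_rician_noise(np.tile(clean, (200, 1)), 2.0, seed=13)
        fits = [t2.fit_pixel_mle(noisy[i], grase) for i in range(200)]
        t2_mean = np.nanmean([f.t2_hat for f in fits])
        sig_mean = np.nanmean([f.sigma_hat for f in fits if f.converged])
        assert t2_mean == pytest.approx(60.0, rel=0.05)
        assert sig_mean == pytest.approx(2.0, rel=0.35)

    def test_scale_invariance(self, grase, rng):
        clean = t2.decay_signal(t2.DecayParams(50.0, 80.0), grase)
        noisy = t2.add_rician_noise(clean, 1.0, seed=21)
        a = t2.fit_pixel_mle(noisy, grase, sigma=1.0)
        b = t2.fit_pixel_mle(noisy * 7.5, grase, sigma=7.5)
        assert b.t2_hat == pytest.approx(a.t2_hat, rel=1e-6)
        assert b.s0_hat == pytest.approx(7.5 * a.s0_hat, rel=1e-6)

    def test_all_zero_signal_not_converged(self, grase):
        fr = t2.fit_pixel_mle(np.zeros(9), grase, sigma=1.0)
        assert not fr.converged
        assert np.isnan(fr.t2_hat)

    def test_flat_signal_not_converged(self, grase):
        fr = t2.fit_pixel_mle(np.full(9, 5.0), grase, sigma=1.0)
        assert not fr.converged

    def test_length_mismatch_rejected(self, grase):
        with pytest.raises(ValueError, match="length"):
            t2.fit_pixel_mle(np.ones(5), grase, sigma=1.0)

    def test_too_few_samples_rejected(self):
        sched = t2.EchoSchedule("MESE", (10.0, 20.0, 30.0))
        with pytest.raises(ValueError, match="4"):
            t2.fit_pixel_mle(np.ones(3), sched)  # joint sigma needs 4

    def test_grid_oracle_equivalence(self, grase, rng):
        # optimizer must never be beaten by the exhaustive 0.1-grid
        for _ in range(8):
            tt = rng.uniform(20, 120)
            s0 = rng.uniform(5, 15)
            sigma = rng.uniform(0.3, 1.0)
            clean = t2.decay_signal(t2.DecayParams(s0, tt), grase)
            noisy = t2.add_rician_noise(clean, sigma, seed=int(rng.integers(2**31)))
            fr = t2.fit_pixel_mle(noisy, grase, sigma=sigma, bounds=(1.0, 150.0))
            _, _, ll_grid = t2.grid_search_mle(noisy, grase, sigma, bounds=(1.0, 150.0))
            assert fr.loglik >= ll_grid - 1e-9


class TestPixelLSQ:
    def test_noiseless_recovery(self, mese):
        sig = t2.decay_signal(t2.DecayParams(42.0, 77.0), mese)
        fr = t2.fit_pixel_lsq(sig, mese)
        assert fr.converged
        assert fr.t2_hat == pytest.approx(77.0, rel=1e-6)
        assert fr.s0_hat == pytest.approx(42.0, rel=1e-6)

    def test_two_point_loglinear_exact(self):
        sched = t2.EchoSchedule("MESE", (10.0, 50.0))
        sig = t2.decay_signal(t2.DecayParams(100.0, 40.0), sched)
        fr = t2.fit_pixel_lsq(sig, sched)
        assert fr.t2_hat == pytest.approx(40.0, rel=1e-6)

    def test_noise_floor_inflates_lsq_more_than_mle(self, mese):
        # at first-echo SNR 3 the Rayleigh floor dominates late echoes
        sigma, tt = 1.0, 50.0
        s0 = 3.0 * sigma / np.exp(-mese.times[0] / tt)
        clean = t2.decay_signal(t2.DecayParams(s0, tt), mese)
        noisy = t2.add_rician_noise(np.tile(clean, (300, 1)), sigma, seed=2)
        mle = np.nanmean(
            [t2.fit_pixel_mle(noisy[i], mese, sigma=sigma).t2_hat for i in range(300)]
        )
        lsq = np.nanmean([t2.fit_pixel_lsq(noisy[i], mese).t2_hat for i in range(300)])
        assert lsq > mle > tt

    def test_gaussian_limit_agreement(self, grase):
        # at first-echo SNR 100 the Rician model is effectively Gaussian
        sigma, tt, s0 = 1.0, 60.0, 100.0 / np.exp(-grase.times[0] / 60.0)
        clean = t2.decay_signal(t2.DecayParams(s0, tt), grase)
        noisy = t2.add_rician_noise(np.tile(clean, (100, 1)), sigma, seed=6)
        diffs = []
        for i in range(100):
            a = t2.fit_pixel_mle(noisy[i], grase, sigma=sigma).t2_hat
            b = t2.fit_pixel_lsq(noisy[i], grase).t2_hat
            diffs.append(abs(a - b))
        assert np.mean(diffs) < 0.005 * tt


class TestFitMap:
    def test_uniform_region_noiseless(self, grase):
        clean = t2.decay_signal(t2.DecayParams(100.0, 50.3), grase)
        stack = t2.ImageStack(np.tile(clean, (6, 6, 1)))
        mask = np.zeros((6, 6), bool)
        mask[1:5, 1:5] = True
        maps = t2.fit_map(stack, mask, grase, method="MLE", sigma=0.01)
        np.testing.assert_allclose(maps.t2_map[mask], 50.3, rtol=1e-3)
        assert np.all(np.isnan(maps.t2_map[~mask]))
        assert not maps.converged_mask[~mask].any()

    def test_empty_mask_all_missing(self, grase):
        stack = t2.ImageStack(np.ones((4, 4, 9)))
        maps = t2.fit_map(stack, np.zeros((4, 4), bool), grase, sigma=1.0)
        assert np.all(np.isnan(maps.t2_map))

    def test_shape_mismatch_rejected(self, grase):
        stack = t2.ImageStack(np.ones((4, 4, 9)))
        with pytest.raises(ValueError, match="mask shape"):
            t2.fit_map(stack, np.zeros((5, 5), bool), grase, sigma=1.0)

    def test_echo_count_mismatch_rejected(self, t2prep):
        stack = t2.ImageStack(np.ones((4, 4, 9)))
        with pytest.raises(ValueError, match="echoes"):
            t2.fit_map(stack, np.ones((4, 4), bool), t2prep, sigma=1.0)

    def test_background_sigma_policy(self, grase):
        clean = t2.decay_signal(t2.DecayParams(100.0, 60.0), grase)
        data = np.zeros((12, 12, 9))
        data[4:8, 4:8, :] = clean
        noisy = t2.add_rician_noise(data, 1.5, seed=17)
        stack = t2.ImageStack(noisy)
        mask = np.zeros((12, 12), bool)
        mask[4:8, 4:8] = True
        bg = np.zeros((12, 12), bool)
        bg[:2, :] = True
        maps = t2.fit_map(stack, mask, grase, method="MLE", background_mask=bg)
        assert np.nanmean(maps.t2_map[mask]) == pytest.approx(60.0, rel=0.05)
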