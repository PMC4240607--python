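"""Capture-recapture, zero-truncated likelihood, mixtures, Gamma reservoir."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import supergenome as sg
from supergenome import ExpectedSpectrum, FrequencySpectrum
from supergenome.iid_models import (
    expected_spectrum_gamma_quadrature,
    mixture_expected_spectrum,
)


class TestCaptureRecapture:
    def test_arithmetic(self):
        sp = FrequencySpectrum(G=3, gamma=(100, 50, 0))
        unseen, total = sg.capture_recapture(sp)
        assert unseen == 200
        assert total == 350

    def test_no_singletons_infers_nothing_unseen(self):
        unseen, total = sg.capture_recapture(FrequencySpectrum(G=2, gamma=(0, 10)))
        assert unseen == 0
        assert total == 10

    def test_gamma2_zero_is_undefined_not_infinite(self):
        sp = FrequencySpectrum(G=2, gamma=(5, 0))
        with pytest.raises(ValueError, match="undefined"):
            sg.capture_recapture(sp)

    def test_simulation_matches_formula_expectation(self):
        # The gamma_1^2/gamma_2 rule overestimates unseen families on
        # homogeneous data by the factor C(G,1)^2 (1-Q)^2 / C(G,2) relative
        # to Chao-style 1/2 gamma_1^2/gamma_2; the simulated mean must match
        # the formula's own closed-form expectation, bias included.
        S, M, G = 2000, 200, 10
        Q = 1 - (1 - 1 / S) ** M
        seen = S * (1 - (1 - Q) ** G)
        # E[gamma_1]^2 / E[gamma_2] = S * G^2 (1-Q)^G / C(G,2)
        unseen_formula = S * G**2 * (1 - Q) ** G / math.comb(G, 2)
        expected_total = seen + unseen_formula
        res = sg.make_reservoir(S, "uniform")
        totals = [
            sg.capture_recapture(sg.frequency_spectrum(
                sg.sample_iid_genomes(res, M=M, G=G, seed=seed)
            ))[1]
            for seed in range(60)
        ]
        assert np.mean(totals) == pytest.approx(expected_total, rel=0.05)


class TestZeroTruncatedLoglik:
    def test_perfect_concentration_gives_zero(self):
        G = 4
        theta = np.zeros(G + 1)
        theta[G] = 1.0
        ll = sg.zero_truncated_loglik(
            FrequencySpectrum(G=G, gamma=(0, 0, 0, 9)), ExpectedSpectrum(G=G, theta=theta)
        )
        assert ll == 0.0

    def test_uniform_ratio_closed_form(self):
        G, N = 5, 20
        theta = np.full(G + 1, 1 / G)
        theta[0] = 0.0
        sp = FrequencySpectrum(G=G, gamma=(5, 5, 5, 5, 0))
        ll = sg.zero_truncated_loglik(sp, ExpectedSpectrum(G=G, theta=theta))
        assert ll == pytest.approx(-N * np.log(G))

    def test_matches_term_by_term_sum(self):
        rng = np.random.default_rng(0)
        G = 6
        theta = rng.dirichlet(np.ones(G + 1))
        gamma = rng.integers(0, 30, size=G)
        sp = FrequencySpectrum(G=G, gamma=tuple(gamma))
        exp = ExpectedSpectrum(G=G, theta=theta)
        by_hand = sum(
            gamma[g] * (np.log(theta[g + 1]) - np.log1p(-theta[0]))
            for g in range(G) if gamma[g] > 0
        )
        assert sg.zero_truncated_loglik(sp, exp) == pytest.approx(by_hand)

    def test_scales_linearly_in_counts(self):
        rng = np.random.default_rng(1)
        G = 5
        theta = rng.dirichlet(np.ones(G + 1))
        gamma = rng.integers(1, 10, size=G)
        exp = ExpectedSpectrum(G=G, theta=theta)
        l1 = sg.zero_truncated_loglik(FrequencySpectrum(G=G, gamma=tuple(gamma)), exp)
        l3 = sg.zero_truncated_loglik(FrequencySpectrum(G=G, gamma=tuple(3 * gamma)), exp)
        assert l3 == pytest.approx(3 * l1)

    def test_zero_probability_occupied_cell(self):
        G = 3
        theta = np.array([0.0, 0.5, 0.5, 0.0])
        sp = FrequencySpectrum(G=G, gamma=(1, 1, 1))
        assert sg.zero_truncated_loglik(sp, ExpectedSpectrum(G=G, theta=theta)) == -np.inf

    def test_empty_pangenome_model_is_error(self):
        G = 2
        theta = np.array([1.0, 0.0, 0.0])
        sp = FrequencySpectrum(G=G, gamma=(1, 0))
        with pytest.raises(ValueError, match="empty pan-genome"):
            sg.zero_truncated_loglik(sp, ExpectedSpectrum(G=G, theta=theta))


class TestExpectedSpectrumGamma:
    @settings(deadline=None, max_examples=30)
    @given(
        st.floats(min_value=0.01, max_value=100),
        st.floats(min_value=0.1, max_value=1000),
    )
    def test_normalization(self, alpha, s):
        th = sg.expected_spectrum_gamma(8, alpha, s)
        assert th.theta.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(th.theta >= 0)

    def test_degenerate_gamma_limit_is_binomial(self):
        from scipy import stats

        G, s = 10, 5.0
        Q = 1 - math.exp(-1 / s)
        th = sg.expected_spectrum_gamma(G, 1e8, s)
        ref = stats.binom.pmf(np.arange(G + 1), G, Q)
        assert np.abs(th.theta - ref).max() < 1e-6

    @pytest.mark.parametrize("alpha,s", [(1.0, 5.0), (0.05, 0.5), (20.0, 300.0)])
    def test_closed_form_equals_quadrature(self, alpha, s):
        import warnings

        cf = sg.expected_spectrum_gamma(10, alpha, s).theta
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            q = expected_spectrum_gamma_quadrature(10, alpha, s)
        q = q / q.sum()
        assert np.max(np.abs(cf - q) / np.maximum(q, 1e-300)) < 1e-8

    def test_rejects_nonpositive_parameters(self):
        with pytest.raises(ValueError):
            sg.expected_spectrum_gamma(5, 0.0, 1.0)
        with pytest.raises(ValueError):
            sg.expected_spectrum_gamma(5, 1.0, -2.0)

    def test_small_alpha_converges_to_ridge_limit(self):
        G, c = 10, 2.5
        lim = sg.zero_truncated_ridge_ratio(G, c)
        for alpha in (1e-5, 1e-7):
            th = sg.expected_spectrum_gamma(G, alpha, c / alpha)
            ratio = th.theta[1:] / (1 - th.theta[0])
            assert np.abs(ratio - lim).max() < 50 * alpha


class TestBinomialMixture:
    def test_k1_saturated(self):
        sp = FrequencySpectrum(G=5, gamma=(0, 0, 0, 0, 42))
        fit = sg.fit_binomial_mixture(sp, k=1)
        assert fit.logL == 0.0
        assert fit.S_hat == 42
        assert fit.n_free_params == 0

    def test_theta_normalized_at_random_parameters(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            k = rng.integers(1, 5)
            q = np.concatenate([[1.0], rng.uniform(0.01, 0.99, size=k - 1)])
            pi = rng.dirichlet(np.ones(k))
            th = mixture_expected_spectrum(10, q, pi)
            assert th.theta.sum() == pytest.approx(1.0, abs=1e-10)

    def test_recovers_generating_parameters(self):
        # 3 components q = (1, .5, .05), pi = (.3, .3, .4), S = 5000, G = 10
        gamma = sg.sample_mixture_spectrum([1, 0.5, 0.05], [0.3, 0.3, 0.4],
                                           5000, 10, seed=5)
        sp = FrequencySpectrum(G=10, gamma=tuple(gamma))
        fit = sg.fit_binomial_mixture(sp, k=3, n_starts=10, seed=0)
        assert fit.q[0] == 1.0
        assert fit.q[1] == pytest.approx(0.5, abs=0.05)
        assert fit.q[2] == pytest.approx(0.05, abs=0.02)
        assert fit.pi == pytest.approx([0.3, 0.3, 0.4], abs=0.06)
        assert fit.n_free_params == 4

    def test_bic_not_minimized_above_generating_k(self):
        gamma = sg.sample_mixture_spectrum([1, 0.5, 0.05], [0.3, 0.3, 0.4],
                                           5000, 10, seed=6)
        sp = FrequencySpectrum(G=10, gamma=tuple(gamma))
        bics = [sg.fit_binomial_mixture(sp, k, n_starts=6, seed=1).BIC
                for k in range(1, 6)]
        assert int(np.argmin(bics)) + 1 <= 3

    def test_homogeneous_s_hat_near_truth(self):
        # k = 2 (indispensable + one free) on uniform-reservoir data
        S, M, G = 2000, 200, 10
        m = sg.sample_iid_genomes(sg.make_reservoir(S, "uniform"), M=M, G=G, seed=8)
        sp = sg.frequency_spectrum(m)
        fit = sg.fit_binomial_mixture(sp, k=2, n_starts=10, seed=0)
        assert fit.S_hat == pytest.approx(S, rel=0.10)


class TestFitGammaReservoir:
    def test_recovers_s_in_homogeneous_limit(self):
        shats = []
        for seed in range(3):
            res = sg.make_reservoir(2000, 1e6, seed=seed)
            m = sg.sample_iid_genomes(res, 500, 10, seed=100 + seed)
            fit = sg.fit_gamma_reservoir(sg.frequency_spectrum(m))
            shats.append(fit.s)
        assert np.mean(shats) == pytest.approx(4.0, rel=0.15)

    def test_ridge_spectrum_hits_alpha_boundary(self):
        sp = sg.make_ridge_spectrum(10, 10.0, 300)
        fit = sg.fit_gamma_reservoir(sp)
        assert fit.alpha_at_lower_bound
        assert fit.alpha * fit.s == pytest.approx(10.0, rel=0.2)

    def test_profile_reports_constant_product_curve(self):
        sp = sg.make_ridge_spectrum(10, 10.0, 300)
        fit = sg.fit_gamma_reservoir(sp)
        prof = fit.profile
        assert np.allclose(prof["alpha"] * prof["s"], fit.alpha * fit.s)
        assert np.all(np.isfinite(prof["BIC"]))
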