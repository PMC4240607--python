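"""Uniform (F1) and Gamma (F2) gain models for reconstructed acquisitions."""

import math

import numpy as np
import pytest
from scipy import special

import supergenome as sg
from supergenome import GainSpectrum
from supergenome.gain_models import (
    fit_uniform_gains_zt,
    gain_occupancy_probs,
    gain_occupancy_probs_finite_mc,
    solve_uniform_S,
    uniform_gain_loglik,
    zero_truncated_gain_loglik,
)


class TestUniformGainLoglik:
    def test_single_draw_is_certain(self):
        # one acquisition is always a distinct family: L = S * 1 / S = 1
        assert uniform_gain_loglik(5.0, 1, 1) == pytest.approx(0.0)

    def test_two_distinct_draws(self):
        # P=2, K=2, S=3: probability both draws differ = (3*2)/9 = 2/3
        assert uniform_gain_loglik(3.0, 2, 2) == pytest.approx(math.log(2 / 3))

    def test_model_is_itself_an_approximation(self):
        # P=2, K=3, S=3: the occupancy form gives (3*2)*2/27 = 4/9, while
        # exhaustive enumeration of all 27 outcomes gives 18/27 = 2/3 for
        # "exactly 2 distinct" — the likelihood is approximate by design and
        # the implementation must reproduce ITS value, not the exact one.
        assert uniform_gain_loglik(3.0, 2, 3) == pytest.approx(math.log(4 / 9))
        outcomes = 0
        for a in range(3):
            for b in range(3):
                for c in range(3):
                    if len({a, b, c}) == 2:
                        outcomes += 1
        assert outcomes / 27 == pytest.approx(2 / 3)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="K >= P"):
            uniform_gain_loglik(10.0, 5, 3)
        assert uniform_gain_loglik(4.0, 5, 6) == -np.inf  # S <= P


class TestSolveUniformS:
    @pytest.mark.parametrize(
        "P,K,S_expected,dS_expected",
        [
            (1312, 1445, 7355, 1195),
            (1789, 2028, 7910, 939),
            (4805, 5600, 17805, 1137),
            (5346, 5923, 28387, 2205),
        ],
    )
    def test_published_estimates_reproduce(self, P, K, S_expected, dS_expected):
        fit = solve_uniform_S(P, K)
        assert fit.S_hat == pytest.approx(S_expected, rel=0.005)
        assert fit.delta_S == pytest.approx(dS_expected, rel=0.02)

    def test_root_matches_brute_force_argmax(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            P = int(rng.integers(20, 501))
            K = int(P * rng.uniform(1.05, 2.0)) + 1
            fit = solve_uniform_S(P, K)
            Ss = np.arange(P + 1, 100_001, dtype=float)
            ll = (special.gammaln(Ss + 1) - special.gammaln(Ss - P + 1)
                  + (K - P) * np.log(P) - K * np.log(Ss))
            S_bf = Ss[np.argmax(ll)]
            assert (abs(fit.S_hat - S_bf) <= max(0.02 * S_bf, 1.0))

    def test_root_is_a_maximum(self):
        fit = solve_uniform_S(500, 640)
        l0 = uniform_gain_loglik(fit.S_hat, 500, 640)
        assert l0 > uniform_gain_loglik(fit.S_hat * 0.95, 500, 640)
        assert l0 > uniform_gain_loglik(fit.S_hat * 1.05, 500, 640)

    def test_k_equal_p_reports_divergence(self):
        fit = solve_uniform_S(100, 100)
        assert fit.divergent
        assert math.isinf(fit.S_hat)

    def test_k_less_than_p_is_error(self):
        with pytest.raises(ValueError, match="fewer"):
            solve_uniform_S(10, 9)

    def test_consistency_bias_shrinks_with_coverage(self):
        # as K/S grows the estimate converges to the true reservoir size
        S_true = 4000
        res = sg.make_reservoir(S_true, "uniform")
        errs = []
        for ratio, seed in [(0.5, 1), (1.0, 2), (2.0, 3)]:
            sp = sg.sample_gain_spectrum(res, int(ratio * S_true), seed=seed)
            errs.append(abs(solve_uniform_S(sp.P, sp.K).S_hat - S_true) / S_true)
        assert errs[2] < errs[0]
        assert errs[2] < 0.1

    def test_ci_matches_exact_curvature(self):
        # Gaussian half-width vs numerical curvature of the exact log-Gamma
        # likelihood at the optimum (validates the Stirling expansion)
        for P, K in [(200, 260), (1312, 1445), (4805, 5600)]:
            fit = solve_uniform_S(P, K)
            h = fit.S_hat * 1e-4
            d2 = (
                uniform_gain_loglik(fit.S_hat + h, P, K)
                - 2 * uniform_gain_loglik(fit.S_hat, P, K)
                + uniform_gain_loglik(fit.S_hat - h, P, K)
            ) / h**2
            exact_delta = 2.0 / math.sqrt(-d2)
            assert fit.delta_S == pytest.approx(exact_delta, rel=0.05)


class TestGainOccupancyProbs:
    @pytest.mark.parametrize("alpha", [0.3, 1.0, 5.0, math.inf])
    def test_lambda_normalizes(self, alpha):
        S, K = 500.0, 1200
        lam = gain_occupancy_probs(np.arange(0, K + 1), S, K, alpha)
        assert lam.sum() == pytest.approx(1.0, abs=1e-8)

    def test_negative_binomial_limit_matches_finite_s_average(self):
        # large-S continuous limit vs explicit finite-S Monte Carlo (Eq.-level
        # oracle: sample rates, normalize, average exact binomial pmfs)
        ks = np.arange(0, 9)
        nb = gain_occupancy_probs(ks, 2000.0, 3000, alpha=0.5)
        mc = gain_occupancy_probs_finite_mc(ks, 2000, 3000, 0.5,
                                            n_reservoirs=150, seed=4)
        # MC standard error is ~1e-3 at these settings
        assert np.abs(nb - mc).max() < 5e-3

    def test_infinite_alpha_equals_uniform_binomial(self):
        spg = GainSpectrum(n=(50, 20, 5, 1))
        S = 800.0
        l_f2 = zero_truncated_gain_loglik(spg, S, alpha=math.inf)
        lam = gain_occupancy_probs(np.arange(0, 5), S, spg.K, math.inf)
        l_f1 = sum(
            n * (math.log(lam[k + 1]) - math.log1p(-lam[0]))
            for k, n in enumerate(spg.n) if n
        )
        assert abs(l_f2 - l_f1) < 1e-6


class TestFitGammaGains:
    def test_uniform_data_selects_uniform_model(self):
        chosen = 0
        res = sg.make_reservoir(5000, "uniform")
        for seed in range(10):
            spg = sg.sample_gain_spectrum(res, 3000, seed=seed)
            fit = sg.fit_gamma_gains(spg)
            chosen += fit.selected == "uniform"
        assert chosen >= 9

    def test_gamma_data_selects_gamma_and_recovers_parameters(self):
        alphas, Ss, chosen = [], [], 0
        for seed in range(10):
            res = sg.make_reservoir(5000, 0.3, seed=seed)
            spg = sg.sample_gain_spectrum(res, 6000, seed=100 + seed)
            fit = sg.fit_gamma_gains(spg)
            chosen += fit.selected == "gamma"
            alphas.append(fit.alpha)
            Ss.append(fit.S_hat)
        assert chosen >= 9
        assert all(0.15 <= a <= 0.6 for a in alphas)  # within factor 2 of 0.3
        assert all(abs(S - 5000) / 5000 < 0.3 for S in Ss)

    def test_uniform_fit_agrees_with_stationarity_root(self):
        # the zero-truncated binomial ML and the occupancy-equation root are
        # different estimators of the same quantity; on well-covered data
        # they must land close together
        res = sg.make_reservoir(3000, "uniform")
        spg = sg.sample_gain_spectrum(res, 4500, seed=7)
        S_zt, _ = fit_uniform_gains_zt(spg)
        S_eq = solve_uniform_S(spg.P, spg.K).S_hat
        assert S_zt == pytest.approx(S_eq, rel=0.15)

    def test_degenerate_spectrum_flags_divergence(self):
        spg = GainSpectrum(n=(25,))  # every family acquired exactly once
        fit = sg.fit_gamma_gains(spg)
        assert fit.divergent
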