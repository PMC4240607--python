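"""Reservoir-size estimators treating genomes as IID samples of the supergenome.

Three estimators share the same data — the gene frequency spectrum gamma_g —
and the same zero-truncated likelihood. A model supplies the probability
theta_g that a random reservoir family is present in exactly g of the G
genomes (including the unobservable g = 0 class); the data are scored with

    l = sum_g gamma_g * log( theta_g / (1 - theta_0) ),

the zero-truncated log-likelihood of Snipen-type pan-genome fitting: a
family enters the data only if it was seen at least once.

Models:

* capture-recapture — the classic gamma_1^2 / gamma_2 estimate of unseen
  families (homogeneous reservoir, moment-based; used as a reference);
* binomial mixture — k homogeneous sub-reservoirs, one indispensable
  (detection probability 1), 2k - 2 free parameters;
* Gamma reservoir — gain probabilities proportional to unit-mean
  Gamma(alpha) rates; in the infinite-(S, M) limit with s = S/M fixed,

      theta_g = C(G,g) * Integral dr P(r) (1 - e^{-r/s})^g e^{-(G-g) r/s}

  which has the closed form (binomial expansion + Gamma Laplace transform)

      theta_g = C(G,g) * sum_{j=0}^{g} (-1)^j C(g,j) (1 + (G-g+j)/(s*alpha))^{-alpha}.

The Gamma-reservoir likelihood is degenerate: as alpha -> 0 with alpha*s
fixed the fit quality converges to a plateau, so the maximizing alpha runs
into the search boundary and the implied reservoir size S = s*M diverges.
`fit_gamma_reservoir` reports this boundary diagnostic and a likelihood
profile along curves of constant alpha*s so the degeneracy is visible.
"""

from __future__ import annotations

import decimal
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, optimize, special, stats

from .spectra import FrequencySpectrum

__all__ = [
    "ExpectedSpectrum",
    "MixtureFit",
    "GammaReservoirFit",
    "capture_recapture",
    "zero_truncated_loglik",
    "mixture_expected_spectrum",
    "fit_binomial_mixture",
    "expected_spectrum_gamma",
    "expected_spectrum_gamma_quadrature",
    "zero_truncated_ridge_ratio",
    "fit_gamma_reservoir",
]


@dataclass(frozen=True)
class ExpectedSpectrum:
    """Model probabilities theta_g (g = 0..G) of a family occupying g genomes."""

    G: int
    theta: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        theta = np.asarray(self.theta, dtype=float)
        if theta.shape != (self.G + 1,):
            raise ValueError(f"theta must have length G+1 = {self.G + 1}")
        if (theta < -1e-12).any() or (theta > 1 + 1e-12).any():
            raise ValueError("theta entries must lie in [0, 1]")
        if abs(theta.sum() - 1.0) > 1e-10:
            raise ValueError("theta must sum to 1 (tol 1e-10)")
        theta = np.clip(theta, 0.0, 1.0)
        theta.setflags(write=False)
        object.__setattr__(self, "theta", theta)

    @property
    def theta0(self) -> float:
        return float(self.theta[0])


def capture_recapture(spectrum: FrequencySpectrum) -> tuple[float, float]:
    """Capture-recapture estimate (S_unseen, S_total) from gamma_1 and gamma_2.

    The most likely number of families not yet captured is gamma_1^2/gamma_2;
    the total reservoir estimate adds the observed pan-genome. Requires
    gamma_2 > 0 (with no doubly-seen families the estimator is undefined).
    """
    if spectrum.G < 2:
        raise ValueError("capture-recapture needs at least 2 genomes")
    g1, g2 = spectrum.gamma[0], spectrum.gamma[1]
    if g2 == 0:
        raise ValueError("capture-recapture estimator undefined: gamma_2 = 0")
    unseen = g1 * g1 / g2
    return unseen, unseen + spectrum.pangenome_size


def zero_truncated_loglik(
    spectrum: FrequencySpectrum, expected: ExpectedSpectrum
) -> float:
    """Zero-truncated log-likelihood of gamma_g under model theta_g.

    Terms with gamma_g = 0 contribute nothing even when theta_g = 0; a
    positive count on a zero-probability cell yields -inf.
    """
    if spectrum.G != expected.G:
        raise ValueError("spectrum and expected spectrum have different G")
    theta0 = expected.theta0
    if theta0 >= 1.0:
        raise ValueError("model predicts an empty pan-genome (theta_0 = 1)")
    gamma = spectrum.as_array()
    theta = expected.theta[1:]
    active = gamma > 0
    if (theta[active] == 0).any():
        return float("-inf")
    log_ratio = np.log(theta[active]) - math.log1p(-theta0)
    return float(np.dot(gamma[active], log_ratio))


# ---------------------------------------------------------------------------
# Binomial mixture model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MixtureFit:
    """Fitted binomial mixture: detection probabilities q (q[0] = 1 fixed),
    admixture fractions pi, zero-truncated logL, BIC and the implied
    reservoir size S_hat = pangenome / (1 - theta_0)."""

    k: int
    q: np.ndarray
    pi: np.ndarray
    logL: float
    BIC: float
    S_hat: float
    theta0: float
    converged: bool
    n_free_params: int
    bic_n_obs: int  # observation count used in the BIC penalty (= G)


def mixture_expected_spectrum(G: int, q: np.ndarray, pi: np.ndarray) -> ExpectedSpectrum:
    """theta_g = sum_m pi_m Binom(g; G, q_m)."""
    q = np.asarray(q, dtype=float)
    pi = np.asarray(pi, dtype=float)
    g = np.arange(G + 1)
    pmf = stats.binom.pmf(g[None, :], G, q[:, None])  # (k, G+1)
    theta = pi @ pmf
    theta = theta / theta.sum()
    return ExpectedSpectrum(G=G, theta=theta)


def _mixture_negloglik(z: np.ndarray, G: int, k: int, gamma: np.ndarray) -> float:
    q = np.empty(k)
    q[0] = 1.0
    q[1:] = special.expit(z[: k - 1])
    logits = np.concatenate([[0.0], z[k - 1:]])
    pi = np.exp(logits - logits.max())
    pi /= pi.sum()
    theta = mixture_expected_spectrum(G, q, pi).theta
    theta0 = theta[0]
    if theta0 >= 1.0 - 1e-15:
        return 1e300
    t = theta[1:]
    active = gamma > 0
    if (t[active] <= 0).any():
        return 1e300
    val = float(np.dot(gamma[active], np.log(t[active]) - math.log1p(-theta0)))
    if not np.isfinite(val):
        return 1e300
    return -val


def fit_binomial_mixture(
    spectrum: FrequencySpectrum,
    k: int,
    n_starts: int = 20,
    seed: int = 0,
) -> MixtureFit:
    """Maximum-likelihood binomial mixture fit with k components.

    One component is indispensable (detection probability fixed at 1); the
    remaining k - 1 detection probabilities and k - 1 admixture logits are
    optimized (2k - 2 free parameters) by multi-start quasi-Newton search on
    logit/softmax-transformed coordinates. Components are returned sorted by
    descending detection probability. BIC uses the number of spectrum cells
    G as the observation count.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    G = spectrum.G
    gamma = spectrum.as_array()
    N = spectrum.pangenome_size
    if k == 1:
        # Indispensable-only model: every reservoir family is in every genome.
        logL = 0.0 if gamma[:-1].sum() == 0 else float("-inf")
        return MixtureFit(
            k=1, q=np.array([1.0]), pi=np.array([1.0]), logL=logL,
            BIC=-2 * logL, S_hat=float(N), theta0=0.0, converged=True,
            n_free_params=0, bic_n_obs=G,
        )

    rng = np.random.default_rng(seed)
    best = None
    n_params = 2 * k - 2
    for _ in range(n_starts):
        z0 = np.concatenate([
            special.logit(rng.uniform(0.02, 0.98, size=k - 1)),
            rng.normal(0.0, 1.0, size=k - 1),
        ])
        res = optimize.minimize(
            _mixture_negloglik, z0, args=(G, k, gamma), method="Nelder-Mead",
            options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10},
        )
        res = optimize.minimize(
            _mixture_negloglik, res.x, args=(G, k, gamma), method="Nelder-Mead",
            options={"maxiter": 4000, "xatol": 1e-10, "fatol": 1e-12},
        )
        if best is None or res.fun < best.fun:
            best = res

    z = best.x
    q = np.empty(k)
    q[0] = 1.0
    q[1:] = special.expit(z[: k - 1])
    logits = np.concatenate([[0.0], z[k - 1:]])
    pi = np.exp(logits - logits.max())
    pi /= pi.sum()
    order = np.argsort(-q, kind="stable")
    q, pi = q[order], pi[order]
    theta0 = float(np.dot(pi, (1.0 - q) ** G))
    logL = -float(best.fun)
    converged = bool(best.fun < 1e299)
    return MixtureFit(
        k=k, q=q, pi=pi, logL=logL,
        BIC=-2 * logL + n_params * math.log(G),
        S_hat=N / (1.0 - theta0), theta0=theta0,
        converged=converged, n_free_params=n_params, bic_n_obs=G,
    )


# ---------------------------------------------------------------------------
# Gamma-reservoir model (infinite-size limit, s = S/M fixed)
# ---------------------------------------------------------------------------

def expected_spectrum_gamma(G: int, alpha: float, s: float) -> ExpectedSpectrum:
    """Occupancy probabilities for the Gamma-rate reservoir, closed form.

    Uses the Laplace transform of the unit-mean Gamma(alpha) rate density:
    E[e^{-m r / s}] = (1 + m/(s*alpha))^{-alpha}, evaluated in log space so
    that alpha -> 0 with alpha*s fixed stays accurate.
    """
    if alpha <= 0 or s <= 0:
        raise ValueError("alpha and s must be positive")
    if G < 1:
        raise ValueError("G must be >= 1")
    # The alternating sum is a g-th finite difference of the Laplace
    # transform and cancels catastrophically when s*alpha >> G (theta_g can
    # be ~1e-30 while individual terms are O(1)), so evaluate in extended
    # precision: float64 is restored only at the end.
    with decimal.localcontext() as ctx:
        ctx.prec = 50
        D = decimal.Decimal
        a = D(alpha)
        sa = D(s) * a
        laplace = [
            ((1 + D(m) / sa).ln() * -a).exp() for m in range(G + 1)
        ]
        theta = np.empty(G + 1)
        for g in range(G + 1):
            total = D(0)
            for j in range(g + 1):
                term = math.comb(g, j) * laplace[G - g + j]
                total = total + term if j % 2 == 0 else total - term
            theta[g] = float(math.comb(G, g) * total)
    theta = np.clip(theta, 0.0, None)
    theta /= theta.sum()
    return ExpectedSpectrum(G=G, theta=theta)


def expected_spectrum_gamma_quadrature(G: int, alpha: float, s: float) -> np.ndarray:
    """Adaptive-quadrature evaluation of the same integral (cross-check)."""
    if alpha <= 0 or s <= 0:
        raise ValueError("alpha and s must be positive")
    pdf = stats.gamma(a=alpha, scale=1.0 / alpha).pdf
    theta = np.empty(G + 1)
    # relative tolerance: the integrals span many orders of magnitude, and
    # quad's default absolute tolerance would swamp the small ones
    cut = 1.0 + 3.0 / math.sqrt(alpha)  # past the bulk of the unit-mean Gamma
    for g in range(G + 1):
        def integrand(r, g=g):
            e = np.exp(-r / s)
            return pdf(r) * (1.0 - e) ** g * e ** (G - g)
        lo, _ = integrate.quad(integrand, 0.0, cut, epsabs=0.0, epsrel=1e-11,
                               limit=500)
        hi, _ = integrate.quad(integrand, cut, np.inf, epsabs=0.0, epsrel=1e-11,
                               limit=500)
        theta[g] = math.comb(G, g) * (lo + hi)
    return theta


def zero_truncated_ridge_ratio(G: int, c: float) -> np.ndarray:
    """Limit of theta_g / (1 - theta_0) as alpha -> 0 with alpha*s = c fixed.

    Expanding the Laplace transform (1 + m/(s*alpha))^{-alpha} to first order
    in alpha leaves

        ratio_g = C(G,g) * sum_j (-1)^{j+1} C(g,j) ln(1 + (G-g+j)/c)
                  / ln(1 + G/c),   g = 1..G.

    This is the occupancy distribution of the "infinite supergenome" regime:
    every spectrum on the alpha*s = c ridge converges to it, which is why the
    reservoir size cannot be identified there.
    """
    if c <= 0:
        raise ValueError("c must be positive")
    with decimal.localcontext() as ctx:
        ctx.prec = 50
        D = decimal.Decimal
        logs = [(1 + D(m) / D(c)).ln() for m in range(G + 1)]
        ratio = np.empty(G)
        for g in range(1, G + 1):
            total = D(0)
            for j in range(g + 1):
                term = math.comb(g, j) * logs[G - g + j]
                total = total - term if j % 2 == 0 else total + term
            ratio[g - 1] = float(math.comb(G, g) * total / logs[G])
    return ratio


@dataclass(frozen=True)
class GammaReservoirFit:
    """Fitted Gamma-reservoir model with degeneracy diagnostics.

    ``alpha_at_lower_bound`` is the signature of the likelihood ridge along
    alpha*s = const: the data are then consistent with an arbitrarily large
    (formally infinite) supergenome. ``profile`` tabulates (alpha, s, logL,
    BIC) along the constant-product curve through the optimum.
    """

    alpha: float
    s: float
    logL: float
    BIC: float
    alpha_at_lower_bound: bool
    converged: bool
    profile: dict[str, np.ndarray]
    bic_n_obs: int


def _gamma_loglik(spectrum: FrequencySpectrum, alpha: float, s: float) -> float:
    try:
        return zero_truncated_loglik(spectrum, expected_spectrum_gamma(spectrum.G, alpha, s))
    except ValueError:
        return float("-inf")


def fit_gamma_reservoir(
    spectrum: FrequencySpectrum,
    alpha_grid: np.ndarray | None = None,
    s_grid: np.ndarray | None = None,
    profile_alphas: np.ndarray | None = None,
) -> GammaReservoirFit:
    """Fit (alpha, s) by grid search refined with Nelder-Mead.

    The search is confined to the grid's bounding box; an optimum on the
    lower alpha edge is flagged rather than chased, because along
    alpha*s = const the likelihood approaches a finite plateau as
    alpha -> 0 and no interior maximum exists there.
    """
    if alpha_grid is None:
        alpha_grid = np.logspace(-3, 3, 25)
    if s_grid is None:
        s_grid = np.logspace(-1, 5, 31)
    if not (np.all(alpha_grid > 0) and np.all(s_grid > 0)):
        raise ValueError("grids must be positive")
    if spectrum.pangenome_size == 0:
        raise ValueError("degenerate spectrum: no families observed")

    ll = np.array([
        [_gamma_loglik(spectrum, a, s) for s in s_grid] for a in alpha_grid
    ])
    ia, is_ = np.unravel_index(np.argmax(ll), ll.shape)
    x0 = np.log([alpha_grid[ia], s_grid[is_]])
    lo = np.log([alpha_grid.min(), s_grid.min()])
    hi = np.log([alpha_grid.max(), s_grid.max()])

    def neg(x: np.ndarray) -> float:
        x = np.clip(x, lo, hi)
        v = _gamma_loglik(spectrum, math.exp(x[0]), math.exp(x[1]))
        return -v if np.isfinite(v) else 1e300

    res = optimize.minimize(neg, x0, method="Nelder-Mead",
                            options={"maxiter": 2000, "xatol": 1e-9, "fatol": 1e-11})
    xb = np.clip(res.x, lo, hi)
    alpha_hat, s_hat = float(math.exp(xb[0])), float(math.exp(xb[1]))
    logL = -float(neg(xb))
    if -res.fun < ll[ia, is_]:  # refinement should never lose to the grid
        alpha_hat, s_hat = float(alpha_grid[ia]), float(s_grid[is_])
        logL = float(ll[ia, is_])

    at_lower = alpha_hat <= alpha_grid.min() * 1.0001 or math.isclose(
        xb[0], lo[0], abs_tol=1e-6
    )
    G = spectrum.G
    bic = -2 * logL + 2 * math.log(G)

    if profile_alphas is None:
        profile_alphas = np.logspace(-3, -1, 11)
    c = alpha_hat * s_hat
    prof_ll = np.array([
        _gamma_loglik(spectrum, a, c / a) for a in profile_alphas
    ])
    profile = {
        "alpha": np.asarray(profile_alphas, dtype=float),
        "s": c / np.asarray(profile_alphas, dtype=float),
        "logL": prof_ll,
        "BIC": -2 * prof_ll + 2 * math.log(G),
    }
    return GammaReservoirFit(
        alpha=alpha_hat, s=s_hat, logL=logL, BIC=bic,
        alpha_at_lower_bound=bool(at_lower),
        converged=bool(res.success or np.isfinite(logL)),
        profile=profile, bic_n_obs=G,
    )
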