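# Methods

## The estimation problem

A group of G related prokaryotic genomes exchanges genes with a reservoir
(supergenome) of S gene families. Only two kinds of summary data are
realistically available: the gene frequency spectrum γ_g (the number of
families present in exactly g of the G genomes, g = 1..G) and — when a
phylogeny and an ancestral-reconstruction tool are available — the gain
spectrum n_k (the number of families acquired k times over the tree, with
totals P = Σ n_k distinct families and K = Σ k·n_k acquisitions). Every
estimator in this package is a likelihood for one of these two summaries
under an explicit model of how genomes sample the reservoir.

Families never sampled are invisible, so all spectrum likelihoods are
zero-truncated: the model occupancy probabilities θ_g (g = 0..G) enter as
θ_g/(1−θ_0), and the data are scored as l = Σ_{g≥1} γ_g log[θ_g/(1−θ_0)].
This treats the γ_g as independent, which they are not; the
`likelihood_validation` module quantifies the consequences (below).

## Models on the frequency spectrum

**Capture–recapture.** The number of unseen families is estimated as
γ₁²/γ₂ and added to the observed pan-genome. We implement this classical
form as-is and document its bias: on homogeneous data the expectation of
γ₁²/γ₂ is G²(1−Q)^G/C(G,2) per reservoir family, a factor
2(G−1)/G ≈ 2 above the true unseen fraction (1−Q)^G (the unbiased variant
would carry a factor ½, as in Chao's estimator). The unit tests assert
agreement with this closed-form expectation, not with the truth; the
estimator is kept as a quick reference, not a recommendation. γ₂ = 0 raises
an error rather than returning infinity.

**Binomial mixture.** The reservoir consists of k homogeneous
sub-reservoirs; a family of component m is present in each genome
independently with detection probability q_m, so
θ_g = Σ_m π_m C(G,g) q_m^g (1−q_m)^{G−g}. One component is indispensable
(q = 1, fixed), leaving 2k−2 free parameters (k−1 detection probabilities,
k−1 admixture logits). The zero-truncated likelihood is maximized by
multi-start Nelder–Mead (default 20 seeded starts) on logit/softmax
coordinates; ties go to the first-found optimum and components are reported
sorted by descending q for identifiability. The implied reservoir size is
the standard zero-truncation inflation S_hat = (Σ γ_g)/(1−θ_0); θ_0 counts
only the non-indispensable components. For k = 1 the model is saturated at
θ_G = 1 and S_hat equals the pan-genome.

**Gamma-rate reservoir.** Gain probabilities are p_i = r_i/Σr_j with r_i
drawn from a unit-mean Gamma(α) (scale 1/α); the unit mean is a
normalization, not an assumption, because only relative rates matter. In
the limit S, M → ∞ with s = S/M fixed,

θ_g = C(G,g) ∫ dr P(r) (1−e^{−r/s})^g e^{−(G−g) r/s}
    = C(G,g) Σ_{j=0}^{g} (−1)^j C(g,j) (1 + (G−g+j)/(sα))^{−α}.

The two free parameters are α (shape, dimensionless) and s (reservoir size
in units of genome size). As α → 0 with c = α·s fixed, the zero-truncated
occupancy ratios converge to

ratio_g = C(G,g) Σ_j (−1)^{j+1} C(g,j) ln(1+(G−g+j)/c) / ln(1+G/c),

a limit that depends only on c: the likelihood surface has a ridge along
α·s = const and the reservoir size is unidentifiable on it.
`fit_gamma_reservoir` therefore reports, besides the best (α, s) on a
log-spaced grid (α ∈ [10⁻³, 10³], s ∈ [10⁻¹, 10⁵] by default, refined by
Nelder–Mead within the grid box), an explicit `alpha_at_lower_bound` flag
and a likelihood profile along the constant-product curve through the
optimum. A boundary optimum is the fingerprint of data consistent with an
arbitrarily large reservoir and should be read as "size not identifiable",
never as an estimate.

**Gene replacement on a tree.** The IID-sampling assumption is relaxed by
evolving genomes along a rooted phylogeny with branch lengths in
substitutions/site. A genome is M slots; each slot loses its occupant at
rate R (per unit branch length) and the loss is immediately repaired by a
reservoir draw. Because only a slot's final occupant on a branch is
observable, a branch is simulated exactly as one Bernoulli(e^{−Rt})
survival per slot plus one reservoir draw on failure — distributionally
identical to simulating every intermediate replacement and orders of
magnitude faster. The root genome is M draws *with replacement* from the
reservoir (how the source model seeds the root is ambiguous; with
replacement is consistent with genomes containing paralogs, and at
realistic S/M the difference is negligible). θ_g has no closed form on a
general tree and is estimated by Monte Carlo, by default 10⁴ independent
instances, each with a fresh reservoir; θ sums to 1 exactly per instance.
Fitting (α, s, R) uses a grid with common random numbers — the same seed at
every parameter point, so Monte-Carlo noise largely cancels between
points — plus the analytic R = ∞ endpoint, which is exactly the IID
closed-form model. Monte-Carlo θ_g = 0 cells under occupied spectrum cells
would give l = −∞, so the fit applies add-one smoothing to the aggregated
instance counts ((count+1)/(n_reps·S + G + 1)); the `smoothed` flag records
this. R at the top of its grid (or the R = ∞ endpoint winning) means the
genomes are consistent with independent reservoir samples.

## Models on the gain spectrum

**Uniform gains (F1).** The probability of P distinct families in K ≥ P
acquisitions from a homogeneous reservoir of size S is approximated by
L(S) = [S!/(S−P)!]·P^{K−P}/S^K. This occupancy form is itself approximate
(for P=2, K=3, S=3 it gives 4/9 where exhaustive enumeration gives 2/3); we
implement it faithfully, since the published estimates derive from it, and
the test suite records the discrepancy explicitly. Stirling expansion
log n! ≈ (n+1/2) log n − n gives the stationarity condition

ln(S/(S−P)) − K/S − P/(2S(S−P)) = 0

and the Gaussian 95% confidence half-width

ΔS = 2·[1/(S−P) − 1/S − K/S² + 1/(2S²) − 1/(2(S−P)²)]^{−1/2}.

The derivative changes sign twice (the Stirling form diverges artificially
as S → P⁺); the ML root is the *upper* sign change, bracketed by a
geometric scan above P and polished by Brent's method (relative tolerance
1e-12, bracket up to 10¹³). K = P (and any spectrum without an interior
maximum) is reported as a divergent estimate with a flag, not an error: the
likelihood then increases without bound in S. The exact log-Gamma form of
the likelihood is also exposed (`uniform_gain_loglik`) and the tests verify
that the Stirling root tracks its integer argmax and that ΔS matches its
numerical curvature.

**Gamma gains (F2).** Gain probabilities vary as normalized unit-mean
Gamma(α) rates. The exact occupancy probability λ_k that a random reservoir
family is drawn k of K times is an average of Binomial(K, p_i) over the
random reservoir; for the large S of interest we evaluate it in the
Gamma–Poisson limit, a negative binomial with shape α and mean μ = K/S.
An explicit finite-S Monte-Carlo evaluator (sample S rates, normalize,
average exact binomial pmfs) is kept in the package as the validation
oracle for this limit; tests require agreement within Monte-Carlo error at
S ≥ 1000. The α → ∞ limit is evaluated *exactly* as Binomial(K, 1/S) —
the uniform model — so the F2 → F1 collapse holds to machine precision
rather than approximately. The fit profiles S out by bounded 1-D
maximization of the zero-truncated likelihood at each α of a log grid
(default [10⁻², 10³]), refines α locally, and compares F1 vs F2 by
BIC = −2l + c·ln P with c = 1 and 2 parameters respectively. α pinned at
the top of the grid means the data are uniform-consistent; at the bottom,
the same size divergence as in the spectrum models.

**BIC convention.** We use the standard penalized form
BIC = −2·logL + (#free parameters)·ln(n), minimized, with n = P
(observed families) for gain models and n = G (spectrum cells) for spectrum
models. The observation count for spectrum models is genuinely
conventional; it is recorded in each fit object (`bic_n_obs`) so users can
re-penalize. Absolute BIC values are therefore not comparable across
conventions — only differences within one convention are meaningful.

## Validation of the zero-truncated approximation

For systems small enough that distinct spectra recur (guard G·M ≤ 200), the
probability of each γ-spectrum can be estimated directly: sample genome
sets, tally spectra. `snipen_vs_direct` runs the canonical design — G = 5,
M = 10, uniform reservoirs S ∈ {10, 15, 20, 25, 30, 40, 45, 50}, 10⁶
samples per S — and, for every spectrum observed at ≥ 4 reservoir sizes,
correlates log direct probability with the approximate log-likelihood
(computed from the exact finite-(S, M) θ_g: Q = 1−(1−1/S)^M,
θ_g = C(G,g)Q^g(1−Q)^{G−g}) across S. Direct probabilities of spectra
unobserved at some S are treated as missing, not zero; spectra with
zero-variance series on either axis have no defined correlation and are
excluded (their count is reported). The experiment yields a mean
per-spectrum Pearson r of ≈ 0.64 with SD ≈ 0.46 (seed-stable to ±0.01):
the approximation tracks the direct likelihood on average — enough to make
S-maximization meaningful — but with large scatter for individual spectra.

## Synthetic data: what it emulates, and what it does not

The generators mirror the study design the estimators were built for:
groups of G = 10 related genomes of ≈ 4000–5000 families. Tests and the
shipped defaults scale the genome to M of a few hundred so the suite runs
in minutes; all statistical shapes (occupancy distributions, overdispersion
of Gamma gains, tree-induced correlation) are preserved by construction,
only absolute counts shrink. The generators are pure functions of
(parameters, seed).

`make_ridge_spectrum` deserves a note: it returns the *expected* (rounded)
spectrum of the α → 0 ridge distribution (default study condition c = 10,
300 families, G = 10), noise-free by construction. It exists to probe the
geometry of the likelihood ridge — flatness along α·s = const and the
boundary optimum — which multinomial sampling noise at realistic pan-genome
sizes obscures (the O(α)·N and √N fluctuation terms exceed the ridge's
intrinsic variation). The flatness analysis: along the ridge the
per-family Kullback–Leibler divergence from the limit distribution at
c = 10 is ≤ 1.5·10⁻³ over α ∈ [10⁻³, 10⁻¹], so 300 families keep the total
log-likelihood variation below 0.5.

What passing tests do **not** show about real data: genomes here are
exchangeable samples (or evolve on a known, correct tree); gene families
are independent; acquisition counts are error-free integers. Real
gene-content matrices inherit homology-clustering noise, real trees are
estimated, and Count-style acquisition counts are posterior expectations
thresholded into integers (the reader accepts either integers or, behind an
explicit flag, rounds posteriors at 0.5). None of these error sources is
modelled.

## Numerical choices

- The Gamma-reservoir closed form is a g-th finite difference of the Gamma
  Laplace transform and cancels catastrophically when sα ≫ G (θ_g can be
  10⁻³⁰ while terms are O(1)). It is evaluated in 50-digit decimal
  arithmetic and converted to float at the end; the adaptive-quadrature
  cross-check (relative tolerance 10⁻¹¹, domain split at the Gamma bulk)
  agrees to better than 10⁻⁸ everywhere in α ∈ [0.01, 100] × s ∈ [0.1, 1000].
- All likelihoods are computed in log space; (1+x/(sα))^{−α} as
  exp(−α·log1p(x/(sα))), negative-binomial λ_0 via log1p/expm1.
- γ_g = 0 terms contribute 0 even when θ_g = 0; γ_g > 0 on θ_g = 0 yields
  −∞ (and, inside optimizers, a large finite penalty).
- Optimizer non-convergence is flagged on the result object, never silent;
  grid optima are never lost to a failed refinement (the refined point must
  beat the grid point to replace it).
- Seeds: every stochastic routine takes an explicit seed and is
  reproducible bit-for-bit; fits with internal restarts derive their starts
  from a single seed argument.

## Known limitations

- The occupancy likelihood L(S) for gains is approximate even as a model
  (see the P=2, K=3 example); its estimates inherit that approximation.
- The capture–recapture form follows the γ₁²/γ₂ convention and is biased
  upward on homogeneous data by ≈ 2(G−1)/G on the unseen count.
- The binomial-mixture likelihood surface is multimodal in k ≥ 3; the
  multi-start default (20) is adequate for G = 10 spectra but not proven
  global.
- Monte-Carlo tree-model fits are noisy at small n_reps; common random
  numbers mitigate but do not eliminate this, and the default grids are
  coarse. The fit is a diagnostic instrument (is R finite? is the ridge
  flat?) more than a precision estimator.
- Branch lengths are taken at face value in substitutions/site; no
  rate-across-branches or per-family loss-rate variation is modelled.
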