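# supergenome

Estimators of the size and composition of the prokaryotic **supergenome** —
the reservoir of gene families available to a group of related genomes
through horizontal gene transfer. The supergenome is distinct from the
*pan-genome*, the set of families actually observed in sequenced isolates:
the pan-genome is what you have seen, the supergenome is what there is to
see. Its size must be inferred through an explicit model of how genomes
sample the reservoir.

The package is aimed at comparative genomicists who already have, for a
group of genomes, a gene-content matrix (genomes × gene-family copy
numbers, from all-vs-all homology clustering), optionally a phylogenetic
tree, and optionally per-family acquisition counts from an
ancestral-reconstruction tool such as Count. It implements, in one
consistent likelihood framework, the estimator family these data support:

| data | model | function |
|---|---|---|
| frequency spectrum γ_g | capture–recapture (γ₁²/γ₂) | `capture_recapture` |
| frequency spectrum γ_g | binomial mixture, k sub-reservoirs | `fit_binomial_mixture` |
| frequency spectrum γ_g | Gamma-distributed gain probabilities | `fit_gamma_reservoir` |
| spectrum + tree | gene replacement along branches, Monte-Carlo θ_g | `fit_tree_model` |
| acquisition counts n_k | uniform gains (occupancy likelihood) | `solve_uniform_S` |
| acquisition counts n_k | Gamma gains vs uniform, BIC comparison | `fit_gamma_gains` |

All spectrum models share the zero-truncated log-likelihood

```
l = Σ_g γ_g · log[ θ_g / (1 − θ_0) ],
```

where θ_g is the model probability that a random reservoir family occupies
exactly g of the G genomes and the truncation accounts for never-sampled
families being invisible. For the Gamma-rate reservoir (unit-mean Gamma(α)
rates, relative size s = S/M) the occupancy probabilities have the closed
form

```
θ_g = C(G,g) Σ_{j=0}^{g} (−1)^j C(g,j) (1 + (G−g+j)/(sα))^(−α),
```

whose likelihood is *degenerate*: it depends, for small α, only on the
product α·s, so the reservoir size cannot be identified from gene
frequencies alone — `fit_gamma_reservoir` reports this boundary diagnostic
and a profile along α·s = const rather than pretending to a point estimate.

The robust alternative uses reconstructed acquisition counts. With P
families acquired at least once in K total acquisitions from a homogeneous
reservoir of size S,

```
L(S) = S!/(S−P)! · P^(K−P) / S^K,
```

and the maximum-likelihood S solves the Stirling-expanded stationarity
condition `ln(S/(S−P)) − K/S − P/(2S(S−P)) = 0`, with a Gaussian 95%
confidence half-width from the curvature at the root. A seeded
synthetic-data module generates every input type (reservoirs, IID genome
samples, on-tree evolution, multinomial gain draws, test trees), so every
estimator has an end-to-end recovery test with no external data.

## Worked example

```python
import supergenome as sg

# Uniform-gain estimate from reconstructed acquisitions:
# 1312 families acquired at least once in 1445 acquisitions.
fit = sg.solve_uniform_S(P=1312, K=1445)
print(f"S_hat = {fit.S_hat:.0f}, delta_S = {fit.delta_S:.0f}")
# S_hat = 7355, delta_S = 1195

# Model comparison on synthetic overdispersed gains:
res = sg.make_reservoir(5000, 0.3, seed=0)     # Gamma(0.3) gain rates
gains = sg.sample_gain_spectrum(res, 6000, seed=1)
f2 = sg.fit_gamma_gains(gains)
print(f"alpha_hat = {f2.alpha:.3f}, S_hat = {f2.S_hat:.0f}")
print(f"BIC uniform = {f2.uniform_BIC:.1f}, BIC gamma = {f2.BIC:.1f}, "
      f"selected = {f2.selected}")
# alpha_hat = 0.405, S_hat = 4139
# BIC uniform = 9194.2, BIC gamma = 7461.8, selected = gamma

# The size degeneracy of spectrum-only Gamma-reservoir fits:
sp = sg.make_ridge_spectrum(10, 10.0, 300)
d = sg.fit_gamma_reservoir(sp)
print(f"alpha = {d.alpha:.4g}, s = {d.s:.4g}, alpha*s = {d.alpha*d.s:.3g}, "
      f"boundary = {d.alpha_at_lower_bound}")
# alpha = 0.001, s = 1.037e+04, alpha*s = 10.4, boundary = True
```

The first block reproduces a published uniform-gain estimate exactly. The
second shows the gains-based estimator recovering a 5000-family reservoir
(within its sampling error) and the BIC correctly preferring the Gamma-gain
model on Gamma-generated data. The third shows why spectrum-only estimates
are untrustworthy: the fitted α runs into the search boundary with α·s
pinned, i.e. the data are equally consistent with an arbitrarily large
reservoir.

A `supergenome` console script exposes the same operations on files
(`supergenome fit-gains --gains gains.csv --mode both`,
`supergenome fit-gamma --spectrum spectrum.csv`,
`supergenome simulate-tree --tree t.nwk --s 4 -R 5 --out matrix.tsv`, ...);
run `supergenome --help` for the full list.

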