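"""Seeded generators for every input the estimators consume.

A *reservoir* (supergenome) is a set of S gene families with normalized gain
probabilities p_i — uniform, or derived from unit-mean Gamma(alpha) rates.
Genomes are assembled by drawing genes from the reservoir: IID sampling for
the random-genome estimators, branch-wise replacement for the tree model,
and bare multinomial acquisition draws for the gain-count models.

Default scales mirror the empirical design the estimators were built for —
groups of G = 10 related bacterial genomes of roughly 4000–5000 gene
families each — scaled down (M of a few hundred) where a test only needs the
statistical shape, not the magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra import GainSpectrum, GeneContentMatrix, PhyloTree

__all__ = [
    "Reservoir",
    "make_reservoir",
    "sample_iid_genomes",
    "sample_gain_spectrum",
    "sample_mixture_spectrum",
    "make_test_tree",
]


@dataclass(frozen=True)
class Reservoir:
    """A supergenome of S families with normalized gain probabilities.

    ``rates`` holds the unnormalized unit-mean gain rates when the reservoir
    was built from a Gamma distribution (shape ``alpha``); both are None for
    a uniform reservoir.
    """

    p: np.ndarray
    alpha: float | None = None
    rates: np.ndarray | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.ndim != 1 or p.size < 1:
            raise ValueError("p must be a non-empty 1-D array")
        if (p < 0).any():
            raise ValueError("gain probabilities must be non-negative")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("gain probabilities must sum to 1 (tol 1e-12)")
        p.setflags(write=False)
        object.__setattr__(self, "p", p)

    @property
    def S(self) -> int:
        return self.p.size

    @property
    def is_uniform(self) -> bool:
        return self.alpha is None


def make_reservoir(
    S: int, alpha: float | str = "uniform", seed: int | None = None
) -> Reservoir:
    """Build a reservoir of S families.

    ``alpha="uniform"`` gives p_i = 1/S. A numeric ``alpha`` draws S rates
    from Gamma(shape=alpha, scale=1/alpha) (unit mean) and normalizes them
    into gain probabilities.
    """
    if S < 1:
        raise ValueError("S must be >= 1")
    if isinstance(alpha, str):
        if alpha != "uniform":
            raise ValueError(f"unknown reservoir kind {alpha!r}")
        return Reservoir(p=np.full(S, 1.0 / S))
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    rng = np.random.default_rng(seed)
    rates = rng.gamma(shape=alpha, scale=1.0 / alpha, size=S)
    total = rates.sum()
    if total <= 0:  # tiny alpha can underflow every rate to 0
        rates = np.full(S, 1.0)
        total = float(S)
    return Reservoir(p=rates / total, alpha=float(alpha), rates=rates)


def sample_iid_genomes(
    reservoir: Reservoir, M: int, G: int, seed: int | None = None
) -> GeneContentMatrix:
    """Assemble G genomes of M genes each by IID draws from the reservoir.

    Draws are with replacement, so genomes can contain multiple copies of a
    family; the presence probability of family i in one genome is
    Q_i = 1 - (1 - p_i)^M.
    """
    if M < 1 or G < 1:
        raise ValueError("M and G must be >= 1")
    rng = np.random.default_rng(seed)
    S = reservoir.S
    if reservoir.is_uniform:
        draws = rng.integers(0, S, size=(G, M))
    else:
        cum = np.cumsum(reservoir.p)
        cum[-1] = 1.0
        draws = np.searchsorted(cum, rng.random((G, M)), side="right")
    counts = np.zeros((G, S), dtype=np.int64)
    for i in range(G):
        counts[i] = np.bincount(draws[i], minlength=S)
    seen = counts.sum(axis=0) > 0
    return GeneContentMatrix(
        genome_ids=tuple(f"genome{i+1}" for i in range(G)),
        family_ids=tuple(f"fam{j}" for j in np.flatnonzero(seen)),
        counts=counts[:, seen],
    )


def sample_gain_spectrum(
    reservoir: Reservoir, K: int, seed: int | None = None
) -> GainSpectrum:
    """Tally n_k after K categorical acquisition draws from the reservoir."""
    if K < 1:
        raise ValueError("K must be >= 1")
    rng = np.random.default_rng(seed)
    per_family = rng.multinomial(K, reservoir.p)
    return GainSpectrum.from_counts(per_family)


def sample_mixture_spectrum(
    q: np.ndarray,
    pi: np.ndarray,
    S: int,
    G: int,
    seed: int | None = None,
) -> np.ndarray:
    """Simulate a gene frequency spectrum from a binomial mixture reservoir.

    Each of S families belongs to component m with probability pi_m and is
    independently present in each of G genomes with that component's
    detection probability q_m. Returns the observed (zero-truncated) counts
    gamma_1..gamma_G.
    """
    q = np.asarray(q, dtype=float)
    pi = np.asarray(pi, dtype=float)
    if q.shape != pi.shape:
        raise ValueError("q and pi must have the same length")
    if abs(pi.sum() - 1.0) > 1e-9:
        raise ValueError("pi must sum to 1")
    rng = np.random.default_rng(seed)
    comp = rng.choice(q.size, size=S, p=pi)
    occupancy = rng.binomial(G, q[comp])
    gamma = np.bincount(occupancy, minlength=G + 1)[1:]
    return gamma.astype(np.int64)


def make_ridge_spectrum(G: int, alpha_s: float, n_families: int):
    """Frequency spectrum of the size-degenerate ("infinite supergenome") regime.

    Returns the expected (rounded) counts of ``n_families`` observed families
    distributed according to the alpha -> 0 limit of the Gamma-reservoir
    occupancy distribution with ``alpha_s = alpha * s`` fixed. Such a
    spectrum is noise-free by construction: it probes the geometry of the
    likelihood ridge (flat along alpha*s = const) rather than sampling
    variation, which is exactly the regime where the reservoir size is
    unidentifiable.
    """
    from .iid_models import zero_truncated_ridge_ratio
    from .spectra import FrequencySpectrum

    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    ratio = zero_truncated_ridge_ratio(G, alpha_s)
    gamma = np.round(n_families * ratio).astype(np.int64)
    return FrequencySpectrum(G=G, gamma=tuple(int(x) for x in gamma))


def make_test_tree(
    kind: str, G: int, branch_len: float, seed: int | None = None
) -> PhyloTree:
    """Build a G-leaf tree with all branch lengths equal to ``branch_len``.

    Kinds: ``star`` (root with G pendant leaves), ``balanced`` (repeated
    bifurcation, ultrametric when G is a power of two), ``caterpillar``
    (ladder). Leaf labels are genome1..genomeG so simulated matrices line up
    with :func:`sample_iid_genomes` output.
    """
    if G < 2:
        raise ValueError("a tree needs at least 2 leaves")
    if branch_len < 0:
        raise ValueError("branch_len must be non-negative")
    labels = [f"genome{i+1}" for i in range(G)]
    t = branch_len
    if kind == "star":
        newick = "(" + ",".join(f"{lab}:{t}" for lab in labels) + ");"
    elif kind == "caterpillar":
        sub = f"{labels[0]}:{t}"
        for lab in labels[1:]:
            sub = f"({sub},{lab}:{t}):{t}"
        # outermost grouping is the root; strip its branch length
        newick = sub.rsplit(":", 1)[0] + ";"
    elif kind == "balanced":
        items = [f"{lab}:{t}" for lab in labels]
        while len(items) > 1:
            nxt = []
            for i in range(0, len(items) - 1, 2):
                nxt.append(f"({items[i]},{items[i+1]}):{t}")
            if len(items) % 2:
                nxt.append(items[-1])
            items = nxt
        newick = items[0].rsplit(":", 1)[0] + ";"
    else:
        raise ValueError(f"unknown tree kind {kind!r}")
    return PhyloTree.from_newick(newick)
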