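"""Direct Monte-Carlo likelihood of frequency spectra vs the zero-truncated
approximation.

The zero-truncated spectrum likelihood treats the gamma_g counts as
independent, which they are not (they share families and sum to the
pan-genome size). For small systems the true likelihood of a spectrum can be
estimated directly: repeatedly assemble G genomes of M genes from the
reservoir, compute the spectrum, and tally how often each distinct spectrum
occurs. Comparing the direct log-probability of a spectrum across reservoir
sizes S with the approximate log-likelihood at the same S shows how well the
approximation tracks the quantity actually being maximized when S is
estimated: for each spectrum observed at several S we report the Pearson
correlation of the two series.

The approximate likelihood here uses the exact finite-(S, M) occupancy
probabilities of a uniform reservoir: Q = 1 - (1 - 1/S)^M and
theta_g = C(G,g) Q^g (1 - Q)^{G-g}.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .iid_models import ExpectedSpectrum
from .synthetic_data import Reservoir

__all__ = [
    "theta_finite",
    "theta_finite_uniform",
    "spectrum_approx_loglik",
    "direct_spectrum_distribution",
    "snipen_vs_direct",
    "SnipenDirectResult",
]


def theta_finite(G: int, M: int, p: np.ndarray) -> ExpectedSpectrum:
    """Exact finite-(S, M) occupancy probabilities for gain probabilities p.

    Per-family presence probability in one genome is Q_i = 1 - (1 - p_i)^M;
    theta_g averages the binomial occupancy pmf over families. Sums to 1
    exactly (up to float rounding).
    """
    p = np.asarray(p, dtype=float)
    Q = 1.0 - (1.0 - p) ** M
    g = np.arange(G + 1)
    theta = stats.binom.pmf(g[None, :], G, Q[:, None]).mean(axis=0)
    return ExpectedSpectrum(G=G, theta=theta / theta.sum())


def theta_finite_uniform(G: int, M: int, S: int) -> ExpectedSpectrum:
    """Finite-(S, M) occupancy probabilities for the uniform reservoir."""
    if S < 1:
        raise ValueError("S must be >= 1")
    Q = 1.0 - (1.0 - 1.0 / S) ** M
    theta = stats.binom.pmf(np.arange(G + 1), G, Q)
    return ExpectedSpectrum(G=G, theta=theta / theta.sum())


def spectrum_approx_loglik(gamma: np.ndarray, expected: ExpectedSpectrum) -> float:
    """Zero-truncated log-likelihood of a raw gamma vector (g = 1..G)."""
    gamma = np.asarray(gamma, dtype=float)
    theta = expected.theta
    log_ratio = np.where(
        theta[1:] > 0, np.log(np.maximum(theta[1:], 1e-300)), -np.inf
    ) - math.log1p(-theta[0])
    active = gamma > 0
    if not active.any():
        return 0.0
    return float(np.dot(gamma[active], log_ratio[active]))


def _pack_keys(gamma: np.ndarray, bits: int) -> np.ndarray:
    """Encode integer spectra rows as single int64 keys (little-endian)."""
    G = gamma.shape[1]
    shifts = (np.arange(G) * bits).astype(np.int64)
    return (gamma.astype(np.int64) << shifts[None, :]).sum(axis=1)


def _unpack_key(key: int, G: int, bits: int) -> tuple[int, ...]:
    mask = (1 << bits) - 1
    return tuple((key >> (bits * g)) & mask for g in range(G))


def _sample_spectrum_keys(
    G: int,
    M: int,
    reservoir: Reservoir,
    n_samples: int,
    rng: np.random.Generator,
    batch: int = 20_000,
) -> dict[int, int]:
    """Tally packed spectrum keys over n_samples simulated genome sets."""
    S = reservoir.S
    bits = max(int(S).bit_length() + 1, 4)
    if bits * G > 62:
        raise ValueError("system too large to key spectra into int64")
    p_cum = None
    if not reservoir.is_uniform:
        p_cum = np.cumsum(reservoir.p)
        p_cum[-1] = 1.0
    tally: dict[int, int] = {}
    done = 0
    b_idx = g_idx = None
    while done < n_samples:
        B = min(batch, n_samples - done)
        if b_idx is None or b_idx.shape[0] != B:
            b_idx = np.arange(B)[:, None, None]
            g_idx = np.arange(G)[None, :, None]
        if p_cum is None:
            draws = rng.integers(0, S, size=(B, G, M))
        else:
            draws = np.searchsorted(p_cum, rng.random((B, G, M)), side="right")
        presence = np.zeros((B, G, S), dtype=bool)
        presence[b_idx, g_idx, draws] = True
        occ = presence.sum(axis=1)  # (B, S): genomes containing each family
        gamma = np.empty((B, G), dtype=np.int64)
        for g in range(1, G + 1):
            gamma[:, g - 1] = (occ == g).sum(axis=1)
        keys, counts = np.unique(_pack_keys(gamma, bits), return_counts=True)
        for k, c in zip(keys.tolist(), counts.tolist()):
            tally[k] = tally.get(k, 0) + c
        done += B
    return tally


def direct_spectrum_distribution(
    G: int,
    M: int,
    reservoir: Reservoir,
    n_samples: int,
    seed: int | None = None,
) -> dict[tuple[int, ...], float]:
    """Empirical distribution over gamma-spectra of simulated genome sets.

    Only feasible for small systems (guard: G*M <= 200) where distinct
    spectra recur often enough for their probabilities to be estimable.
    Returns a mapping from the spectrum tuple (gamma_1..gamma_G) to its
    estimated probability; the values sum to 1.
    """
    if G * M > 200:
        raise ValueError("direct computation restricted to G*M <= 200")
    if n_samples < 10_000:
        raise ValueError("need at least 1e4 samples for stable estimates")
    rng = np.random.default_rng(seed)
    bits = max(int(reservoir.S).bit_length() + 1, 4)
    tally = _sample_spectrum_keys(G, M, reservoir, n_samples, rng)
    return {
        _unpack_key(k, G, bits): c / n_samples for k, c in tally.items()
    }


@dataclass(frozen=True)
class SnipenDirectResult:
    """Per-spectrum correlations between direct and approximate log-likelihoods.

    ``table`` has one row per spectrum observed at >= ``min_S_occurrences``
    reservoir sizes: the spectrum, the number of sizes it occurred at, and
    the Pearson r of (log direct probability, approximate log-likelihood)
    across those sizes. Spectra whose series have zero variance on either
    axis have no defined correlation and are excluded from the summary
    (counted in ``n_zero_variance``). ``overall_r`` pools every
    (spectrum, S) point into one cloud.
    """

    table: pd.DataFrame = field(repr=False)
    mean_r: float
    sd_r: float
    n_spectra: int
    n_zero_variance: int
    overall_r: float
    n_samples: int
    S_list: tuple[int, ...]


def snipen_vs_direct(
    G: int,
    M: int,
    S_list: list[int],
    n_samples: int = 1_000_000,
    seed: int | None = None,
    min_S_occurrences: int = 4,
) -> SnipenDirectResult:
    """Correlate direct and approximate log-likelihoods across reservoir sizes.

    For each uniform reservoir size S the direct probability of every
    observed spectrum is estimated from ``n_samples`` genome-set draws, and
    the approximate (zero-truncated, exact finite-(S, M) theta) likelihood of
    the same spectrum is computed. Spectra observed at fewer than
    ``min_S_occurrences`` sizes are dropped; direct probabilities at sizes
    where a spectrum was never observed are treated as missing, not zero.
    """
    if len(S_list) < min_S_occurrences:
        raise ValueError(f"need at least {min_S_occurrences} reservoir sizes")
    rng = np.random.default_rng(seed)
    S_list = [int(S) for S in S_list]
    bits = max(int(max(S_list)).bit_length() + 1, 4)
    if bits * G > 62:
        raise ValueError("system too large to key spectra into int64")

    # Per S: spectrum-key tallies and the approximate log-likelihood pieces.
    tallies: list[dict[int, int]] = []
    log_ratio: list[np.ndarray] = []  # log(theta_g / (1 - theta_0)), g = 1..G
    for S in S_list:
        res = Reservoir(p=np.full(S, 1.0 / S))
        # re-tally with the shared key width so keys match across S
        tally = _sample_spectrum_keys(G, M, res, n_samples, rng)
        fixed_bits = max(int(S).bit_length() + 1, 4)
        if fixed_bits != bits:
            tally = {
                _repack(k, G, fixed_bits, bits): c for k, c in tally.items()
            }
        tallies.append(tally)
        th = theta_finite_uniform(G, M, S)
        log_ratio.append(np.log(th.theta[1:]) - math.log1p(-th.theta0))

    counts_at: dict[int, list[tuple[int, int]]] = {}
    for i, tally in enumerate(tallies):
        for k, c in tally.items():
            counts_at.setdefault(k, []).append((i, c))

    rows = []
    n_zero_var = 0
    pooled_x: list[float] = []
    pooled_y: list[float] = []
    log_n = math.log(n_samples)
    for key, obs in counts_at.items():
        gamma = np.asarray(_unpack_key(key, G, bits), dtype=np.int64)
        x = np.array([math.log(c) - log_n for _, c in obs])
        y = np.array([float(np.dot(gamma, log_ratio[i])) for i, _ in obs])
        pooled_x.extend(x)
        pooled_y.extend(y)
        if len(obs) < min_S_occurrences:
            continue
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            n_zero_var += 1
            r = math.nan
        else:
            r = float(np.corrcoef(x, y)[0, 1])
        rows.append({"spectrum": tuple(int(v) for v in gamma), "n_S": len(obs), "r": r})

    table = pd.DataFrame(rows, columns=["spectrum", "n_S", "r"])
    valid = table["r"].dropna()
    overall = float(np.corrcoef(pooled_x, pooled_y)[0, 1]) if len(pooled_x) > 1 else math.nan
    return SnipenDirectResult(
        table=table,
        mean_r=float(valid.mean()) if len(valid) else math.nan,
        sd_r=float(valid.std(ddof=1)) if len(valid) > 1 else math.nan,
        n_spectra=int(len(valid)),
        n_zero_variance=n_zero_var,
        overall_r=overall,
        n_samples=n_samples,
        S_list=tuple(S_list),
    )


def _repack(key: int, G: int, from_bits: int, to_bits: int) -> int:
    mask = (1 << from_bits) - 1
    out = 0
    for g in range(G):
        out |= ((key >> (from_bits * g)) & mask) << (to_bits * g)
    return out
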