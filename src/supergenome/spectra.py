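"""Core data containers and spectrum computations.

The universal empirical input is the gene content matrix: a genomes x
gene-families table of non-negative integer copy numbers, typically produced
by all-vs-all homology clustering. From it we derive the gene frequency
spectrum (the counts ``gamma_g`` of families present in exactly ``g`` of the
``G`` genomes) and the pan-genome growth curve ``P(g)``. Reconstructed
gene-acquisition counts are summarised by the gain spectrum (``n_k``
families acquired ``k`` times, with totals ``P`` and ``K``).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "GeneContentMatrix",
    "FrequencySpectrum",
    "GainSpectrum",
    "PhyloTree",
    "frequency_spectrum",
    "pangenome_curve",
    "read_gene_content_matrix",
    "write_gene_content_matrix",
    "read_frequency_spectrum",
    "write_frequency_spectrum",
    "read_gain_spectrum",
    "write_gain_spectrum",
    "read_gain_counts",
]


@dataclass(frozen=True, eq=False)
class GeneContentMatrix:
    """Genomes x gene-families copy-number matrix.

    Parameters
    ----------
    genome_ids
        Row identifiers (one per genome).
    family_ids
        Column identifiers (one per gene family / cluster).
    counts
        Integer array of shape ``(n_genomes, n_families)``; ``counts[i, j]``
        is the copy number of family ``j`` in genome ``i``.
    """

    genome_ids: tuple[str, ...]
    family_ids: tuple[str, ...]
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D array")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(counts == np.floor(counts)):
                raise ValueError("copy numbers must be integers")
            counts = counts.astype(np.int64)
        if counts.shape != (len(self.genome_ids), len(self.family_ids)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.genome_ids)} genomes x {len(self.family_ids)} families"
            )
        if counts.shape[0] < 1 or counts.shape[1] < 1:
            raise ValueError("need at least one genome and one family")
        if (counts < 0).any():
            raise ValueError("copy numbers must be non-negative")
        if (counts.sum(axis=0) == 0).any():
            raise ValueError("every family must be present in at least one genome")
        if len(set(self.genome_ids)) != len(self.genome_ids):
            raise ValueError("genome ids must be unique")
        if len(set(self.family_ids)) != len(self.family_ids):
            raise ValueError("family ids must be unique")
        object.__setattr__(self, "genome_ids", tuple(self.genome_ids))
        object.__setattr__(self, "family_ids", tuple(self.family_ids))
        counts.setflags(write=False)
        object.__setattr__(self, "counts", counts)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneContentMatrix):
            return NotImplemented
        return (
            self.genome_ids == other.genome_ids
            and self.family_ids == other.family_ids
            and np.array_equal(self.counts, other.counts)
        )

    @property
    def n_genomes(self) -> int:
        return len(self.genome_ids)

    @property
    def n_families(self) -> int:
        return len(self.family_ids)

    @property
    def presence(self) -> np.ndarray:
        """Boolean presence/absence view (copy number > 0)."""
        return self.counts > 0

    def genome_sizes(self) -> np.ndarray:
        """Total gene copies per genome (the per-genome M)."""
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.genome_ids), columns=list(self.family_ids)
        )


@dataclass(frozen=True)
class FrequencySpectrum:
    """Gene frequency spectrum: gamma[g-1] families occur in exactly g genomes."""

    G: int
    gamma: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.G < 1:
            raise ValueError("G must be >= 1")
        if len(self.gamma) != self.G:
            raise ValueError(f"gamma must have length G={self.G}")
        if any(x < 0 for x in self.gamma):
            raise ValueError("gamma counts must be non-negative")
        object.__setattr__(self, "gamma", tuple(int(x) for x in self.gamma))

    @property
    def pangenome_size(self) -> int:
        """Number of distinct families observed: sum of gamma_g."""
        return int(sum(self.gamma))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.gamma, dtype=np.int64)


@dataclass(frozen=True)
class GainSpectrum:
    """Acquisition-count spectrum: n[k-1] families acquired exactly k times.

    ``P`` (families acquired at least once) and ``K`` (total acquisitions)
    are derived and exposed as properties.
    """

    n: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.n) < 1:
            raise ValueError("gain spectrum must have at least one entry")
        if any(x < 0 for x in self.n):
            raise ValueError("n_k counts must be non-negative")
        object.__setattr__(self, "n", tuple(int(x) for x in self.n))

    @property
    def P(self) -> int:
        return int(sum(self.n))

    @property
    def K(self) -> int:
        return int(sum((k + 1) * nk for k, nk in enumerate(self.n)))

    @property
    def k_max(self) -> int:
        return len(self.n)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.n, dtype=np.int64)

    @classmethod
    def from_counts(cls, acquisitions: Sequence[int]) -> "GainSpectrum":
        """Build from per-family acquisition counts (zeros are dropped)."""
        acq = np.asarray(acquisitions, dtype=np.int64)
        if (acq < 0).any():
            raise ValueError("acquisition counts must be non-negative")
        acq = acq[acq > 0]
        if acq.size == 0:
            raise ValueError("no family was acquired at least once")
        tally = np.bincount(acq)[1:]
        return cls(n=tuple(int(x) for x in tally))


class PhyloTree:
    """Rooted phylogenetic tree with branch lengths (substitutions/site).

    Thin wrapper around :class:`dendropy.Tree` enforcing the invariants the
    simulator relies on: a single root, non-negative branch lengths and
    unique leaf labels.
    """

    def __init__(self, tree: dendropy.Tree):
        tree = tree.clone(depth=1)
        leaves = [lf.taxon.label if lf.taxon else None for lf in tree.leaf_node_iter()]
        if any(lab is None for lab in leaves):
            raise ValueError("all leaves must be labelled")
        if len(set(leaves)) != len(leaves):
            raise ValueError("leaf labels must be unique")
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            if edge.length is not None and edge.length < 0:
                raise ValueError("branch lengths must be non-negative")
        self._tree = tree
        self._leaf_labels = tuple(leaves)

    @property
    def tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def leaf_labels(self) -> tuple[str, ...]:
        return self._leaf_labels

    @property
    def n_leaves(self) -> int:
        return len(self._leaf_labels)

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls(tree)

    @classmethod
    def read(cls, path: str | Path) -> "PhyloTree":
        tree = dendropy.Tree.get(path=str(path), schema="newick")
        return cls(tree)

    def to_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")

    def edges(self) -> list[tuple[int, int, float]]:
        """Flatten to (parent_index, child_index, branch_length) triples.

        Node 0 is the root; leaves are assigned the last ``n_leaves``
        indices in ``leaf_labels`` order. Missing branch lengths count as 0.
        """
        nodes = list(self._tree.preorder_node_iter())
        index = {id(n): i for i, n in enumerate(nodes)}
        out = []
        for node in nodes[1:]:
            t = node.edge.length if node.edge.length is not None else 0.0
            out.append((index[id(node.parent_node)], index[id(node)], float(t)))
        return out

    def node_count(self) -> int:
        return sum(1 for _ in self._tree.preorder_node_iter())

    def leaf_indices(self) -> dict[str, int]:
        """Map leaf label -> preorder node index (matching :meth:`edges`)."""
        nodes = list(self._tree.preorder_node_iter())
        return {
            n.taxon.label: i for i, n in enumerate(nodes) if n.is_leaf()
        }


def frequency_spectrum(matrix: GeneContentMatrix) -> FrequencySpectrum:
    """Tally gamma_g: families present (copy number > 0) in exactly g genomes.

    Copy numbers greater than one collapse to presence; paralogs do not
    inflate the spectrum.
    """
    g_per_family = matrix.presence.sum(axis=0)
    gamma = np.bincount(g_per_family, minlength=matrix.n_genomes + 1)[1:]
    return FrequencySpectrum(G=matrix.n_genomes, gamma=tuple(int(x) for x in gamma))


def pangenome_curve(
    matrix: GeneContentMatrix,
    max_subsets: int = 10_000,
    seed: int | None = None,
) -> np.ndarray:
    """Average pan-genome size P(g) over genome subsets of each size g.

    For each g = 1..G the number of distinct families in a g-genome subset is
    averaged over all C(G, g) subsets when that count does not exceed
    ``max_subsets``, otherwise over ``max_subsets`` uniformly drawn subsets
    (seeded). P(g) is non-decreasing in expectation and P(G) is the
    pan-genome size.
    """
    if max_subsets < 1:
        raise ValueError("max_subsets must be >= 1")
    presence = matrix.presence
    G = matrix.n_genomes
    rng = np.random.default_rng(seed)
    curve = np.empty(G, dtype=float)
    for g in range(1, G + 1):
        n_subsets = math.comb(G, g)
        if n_subsets <= max_subsets:
            sizes = [
                int(np.any(presence[list(idx)], axis=0).sum())
                for idx in itertools.combinations(range(G), g)
            ]
        else:
            sizes = [
                int(np.any(presence[rng.choice(G, size=g, replace=False)], axis=0).sum())
                for _ in range(max_subsets)
            ]
        curve[g - 1] = float(np.mean(sizes))
    return curve


# ---------------------------------------------------------------------------
# File formats: TSV gene-content matrix, two-column CSV spectra.
# ---------------------------------------------------------------------------

def read_gene_content_matrix(path: str | Path, transposed: bool = False) -> GeneContentMatrix:
    """Read a TSV gene-content matrix.

    Default orientation: first column genome ids, header row family ids.
    Set ``transposed=True`` when rows are families and columns genomes; the
    dialect is never guessed.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if transposed:
        df = df.T
    counts = df.to_numpy()
    return GeneContentMatrix(
        genome_ids=tuple(str(i) for i in df.index),
        family_ids=tuple(str(c) for c in df.columns),
        counts=counts,
    )


def write_gene_content_matrix(matrix: GeneContentMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="genome")


def read_frequency_spectrum(path: str | Path) -> FrequencySpectrum:
    """Read a (g, gamma_g) two-column CSV; missing g default to 0."""
    df = pd.read_csv(path)
    g = df.iloc[:, 0].to_numpy(dtype=np.int64)
    counts = df.iloc[:, 1].to_numpy(dtype=np.int64)
    if (g < 1).any():
        raise ValueError("occupancy g must be >= 1")
    G = int(g.max())
    gamma = np.zeros(G, dtype=np.int64)
    gamma[g - 1] = counts
    return FrequencySpectrum(G=G, gamma=tuple(int(x) for x in gamma))


def write_frequency_spectrum(spectrum: FrequencySpectrum, path: str | Path) -> None:
    pd.DataFrame(
        {"g": np.arange(1, spectrum.G + 1), "gamma_g": spectrum.gamma}
    ).to_csv(path, index=False)


def read_gain_spectrum(path: str | Path) -> GainSpectrum:
    """Read a (k, n_k) two-column CSV; missing k default to 0."""
    df = pd.read_csv(path)
    k = df.iloc[:, 0].to_numpy(dtype=np.int64)
    counts = df.iloc[:, 1].to_numpy(dtype=np.int64)
    if (k < 1).any():
        raise ValueError("acquisition multiplicity k must be >= 1")
    n = np.zeros(int(k.max()), dtype=np.int64)
    n[k - 1] = counts
    return GainSpectrum(n=tuple(int(x) for x in n))


def write_gain_spectrum(spectrum: GainSpectrum, path: str | Path) -> None:
    pd.DataFrame(
        {"k": np.arange(1, spectrum.k_max + 1), "n_k": spectrum.n}
    ).to_csv(path, index=False)


def read_gain_counts(
    path: str | Path, round_probabilities: bool = False
) -> GainSpectrum:
    """Read a per-family acquisition table (family_id, n_acquisitions) CSV.

    Ancestral-reconstruction tools may report posterior expected gains as
    floats; with ``round_probabilities=True`` values are rounded to the
    nearest integer (>= 0.5 counts as an acquisition). Without the flag,
    non-integer values are an error.
    """
    df = pd.read_csv(path)
    vals = df.iloc[:, 1].to_numpy(dtype=float)
    if round_probabilities:
        vals = np.floor(vals + 0.5)
    elif not np.all(vals == np.floor(vals)):
        raise ValueError(
            "non-integer acquisition counts; pass round_probabilities=True to round"
        )
    return GainSpectrum.from_counts(vals.astype(np.int64))
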