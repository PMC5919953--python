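"""Alignment-free composition-vector phylogeny of whole proteomes.

A proteome is summarized by the frequencies of its length-k peptides
after subtracting a (k-2)-order Markov background: for each observed
k-peptide a = a1..ak with frequency f(a), the background prediction is

    f0(a) = f(a1..a_{k-1}) * f(a2..a_k) / f(a2..a_{k-1})

and the vector entry is (f - f0)/f0 (0 where f0 = 0). The subtraction
removes the shared compositional/mutational signal and leaves the
selection-shaped deviations that carry phylogenetic information. The
dissimilarity between genomes u, v is d = (1 - cos(u, v))/2 in [0, 1],
and the distance matrix is resolved into an unrooted binary tree by
neighbor joining.

k defaults to 6 (usual practice for proteome composition vectors);
peptides spanning ambiguity or stop characters are skipped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "CompositionVector",
    "composition_vector",
    "cv_distance",
    "distance_matrix",
    "read_proteome",
    "write_phylip",
    "TreeNode",
    "neighbor_joining",
]

_AMINO = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class CompositionVector:
    """Sparse background-subtracted k-peptide deviation vector."""

    genome_id: str
    k: int
    entries: Mapping[str, float]

    @property
    def norm(self) -> float:
        return math.sqrt(sum(v * v for v in self.entries.values()))


def _kmer_freqs(sequences: Sequence[str], k: int) -> dict[str, float]:
    counts: dict[str, int] = {}
    total = 0
    for seq in sequences:
        s = seq.upper()
        for i in range(len(s) - k + 1):
            kmer = s[i : i + k]
            if any(c not in _AMINO for c in kmer):
                continue
            counts[kmer] = counts.get(kmer, 0) + 1
            total += 1
    if total == 0:
        return {}
    return {kmer: c / total for kmer, c in counts.items()}


def composition_vector(
    genome_id: str, sequences: Iterable[str], k: int = 6
) -> CompositionVector:
    """Background-subtracted k-peptide vector of one proteome.

    Sequences shorter than k contribute nothing; if every sequence is
    too short the proteome is rejected. k must be >= 3 (the background
    needs (k-1)- and (k-2)-peptides).
    """
    if k < 3:
        raise ValueError(f"k must be >= 3, got {k}")
    seqs = [s for s in sequences if len(s) >= k]
    if not seqs:
        raise ValueError(f"{genome_id}: no sequence of length >= k={k}")
    f_k = _kmer_freqs(seqs, k)
    f_k1 = _kmer_freqs(seqs, k - 1)
    f_k2 = _kmer_freqs(seqs, k - 2)
    entries: dict[str, float] = {}
    for kmer, f in f_k.items():
        denom = f_k2.get(kmer[1:-1], 0.0)
        if denom > 0:
            f0 = f_k1.get(kmer[:-1], 0.0) * f_k1.get(kmer[1:], 0.0) / denom
        else:
            f0 = 0.0
        entries[kmer] = (f - f0) / f0 if f0 > 0 else 0.0
    return CompositionVector(genome_id, k, entries)


def cv_distance(u: CompositionVector, v: CompositionVector) -> float:
    """d = (1 - cosine(u, v))/2 over the union of supports, in [0, 1]."""
    if u.k != v.k:
        raise ValueError(f"k mismatch: {u.k} vs {v.k}")
    nu, nv = u.norm, v.norm
    if nu == 0.0 or nv == 0.0:
        raise ValueError("zero-norm composition vector")
    small, large = (u.entries, v.entries) if len(u.entries) <= len(v.entries) \
        else (v.entries, u.entries)
    dot = sum(val * large.get(kmer, 0.0) for kmer, val in small.items())
    cosine = max(-1.0, min(1.0, dot / (nu * nv)))
    return (1.0 - cosine) / 2.0


def distance_matrix(
    vectors: Sequence[CompositionVector],
) -> tuple[list[str], np.ndarray]:
    """Symmetric zero-diagonal pairwise CV-distance matrix."""
    labels = [v.genome_id for v in vectors]
    n = len(vectors)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = cv_distance(vectors[i], vectors[j])
    return labels, d


def read_proteome(fasta_path: str | Path) -> list[str]:
    """All protein sequences of a predicted-proteome FASTA."""
    return [str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")]


def write_phylip(labels: Sequence[str], matrix: np.ndarray,
                 path: str | Path) -> None:
    """Square PHYLIP distance-matrix format (10-char padded names)."""
    with open(path, "w") as fh:
        fh.write(f"{len(labels):5d}\n")
        for lab, row in zip(labels, matrix):
            name = lab[:10].ljust(10)
            fh.write(name + "  " + "  ".join(f"{x:.6f}" for x in row) + "\n")


@dataclass
class TreeNode:
    """Minimal phylogenetic tree node (name on leaves, length to parent)."""

    name: str | None = None
    length: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf():
            return [self]
        return [leaf for c in self.children for leaf in c.leaves()]

    def n_edges(self) -> int:
        return sum(1 + c.n_edges() for c in self.children)

    def to_newick(self) -> str:
        if self.is_leaf():
            return f"{self.name};"
        inner = ",".join(c._newick_inner() for c in self.children)
        return f"({inner});"

    def _newick_inner(self) -> str:
        if self.is_leaf():
            return f"{self.name}:{self.length:.6f}"
        inner = ",".join(c._newick_inner() for c in self.children)
        label = self.name or ""
        return f"({inner}){label}:{self.length:.6f}"


def neighbor_joining(labels: Sequence[str], matrix: np.ndarray) -> TreeNode:
    """Neighbor joining on a symmetric distance matrix.

    Standard agglomeration: repeatedly join the pair minimizing the
    Q-criterion, with the usual limb-length formulas, until three nodes
    remain; those are resolved by the three-point formulas around a
    final trifurcating root (the unrooted tree). On an additive matrix
    the tree's leaf-to-leaf path lengths reproduce the input exactly.
    Negative limb lengths are clamped to zero with the deficit moved to
    the sister limb, keeping pairwise path lengths intact. Determinism:
    Q-ties are broken by smallest index pair.
    """
    d = np.asarray(matrix, dtype=float).copy()
    n = d.shape[0]
    if d.shape != (n, n) or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square and symmetric")
    if len(labels) != n or n < 3:
        raise ValueError("need >= 3 labeled taxa")
    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in labels]
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # smallest index pair among the minima, for determinism
        flat = np.flatnonzero(np.isclose(q, q.min(), rtol=0, atol=1e-12))
        ii, jj = divmod(int(flat[0]), m)
        if ii > jj:
            ii, jj = jj, ii
        a, b = active[ii], active[jj]
        li = 0.5 * sub[ii, jj] + (r[ii] - r[jj]) / (2 * (m - 2))
        lj = sub[ii, jj] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        child_a, child_b = nodes[a], nodes[b]
        child_a.length = li
        child_b.length = lj
        parent = TreeNode(children=[child_a, child_b])
        # distances from the new node to every other active node
        d = np.pad(d, ((0, 1), (0, 1)))
        for kk in active:
            if kk in (a, b):
                continue
            d[-1, kk] = d[kk, -1] = 0.5 * (d[a, kk] + d[b, kk] - d[a, b])
        nodes.append(parent)
        active = [x for x in active if x not in (a, b)] + [len(nodes) - 1]

    # resolve the last three nodes around a trifurcating root
    x, y, z = active
    lx = 0.5 * (d[x, y] + d[x, z] - d[y, z])
    ly = 0.5 * (d[x, y] + d[y, z] - d[x, z])
    lz = 0.5 * (d[x, z] + d[y, z] - d[x, y])
    for idx, limb in ((x, lx), (y, ly), (z, lz)):
        nodes[idx].length = max(0.0, limb)
    root = TreeNode(children=[nodes[x], nodes[y], nodes[z]])
    return root
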