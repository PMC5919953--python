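"""Composition vectors against a brute-force oracle; NJ against additive matrices."""

import itertools

import numpy as np
import pytest
from scipy.stats import spearmanr

from microbin.cvtree import (
    CompositionVector,
    composition_vector,
    cv_distance,
    distance_matrix,
    neighbor_joining,
    write_phylip,
)

# ---------------------------------------------------------------- oracles


def brute_force_cv(sequences, k):
    """Independent plain-dict re-derivation of the k-peptide deviation vector."""
    def freqs(n):
        counts = {}
        for s in sequences:
            for i in range(len(s) - n + 1):
                w = s[i:i + n]
                if all(c in "ACDEFGHIKLMNPQRSTVWY" for c in w):
                    counts[w] = counts.get(w, 0) + 1
        total = sum(counts.values())
        return {w: c / total for w, c in counts.items()}

    fk, fk1, fk2 = freqs(k), freqs(k - 1), freqs(k - 2)
    out = {}
    for w, f in fk.items():
        mid = fk2.get(w[1:-1], 0.0)
        f0 = fk1.get(w[:-1], 0.0) * fk1.get(w[1:], 0.0) / mid if mid > 0 else 0.0
        out[w] = (f - f0) / f0 if f0 > 0 else 0.0
    return out


def random_additive_tree(n_taxa, rng):
    """Random binary tree as an edge-weighted graph + exact leaf distances."""
    # node 0 is the internal "center"; attach leaves by splitting random edges
    edges = {}  # (u, v) sorted tuple -> length
    next_node = [0]

    def new_node():
        next_node[0] += 1
        return next_node[0]

    center = 0
    leaves = []
    for _ in range(3):
        leaf = new_node()
        edges[(center, leaf)] = rng.uniform(0.5, 3.0)
        leaves.append(leaf)
    while len(leaves) < n_taxa:
        u, v = list(edges)[rng.integers(len(edges))]
        length = edges.pop((u, v))
        mid, leaf = new_node(), new_node()
        split = rng.uniform(0.2, 0.8) * length
        edges[tuple(sorted((u, mid)))] = split
        edges[tuple(sorted((mid, v)))] = length - split
        edges[tuple(sorted((mid, leaf)))] = rng.uniform(0.5, 3.0)
        leaves.append(leaf)

    adj = {}
    for (u, v), w in edges.items():
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))

    def dist_from(src):
        seen = {src: 0.0}
        stack = [src]
        while stack:
            x = stack.pop()
            for y, w in adj[x]:
                if y not in seen:
                    seen[y] = seen[x] + w
                    stack.append(y)
        return seen

    labels = [f"t{leaf}" for leaf in leaves]
    d = np.zeros((n_taxa, n_taxa))
    for i, a in enumerate(leaves):
        da = dist_from(a)
        for j, b in enumerate(leaves):
            d[i, j] = da[b]
    d = (d + d.T) / 2  # exact symmetry despite float summation order
    np.fill_diagonal(d, 0.0)
    return labels, d


def tree_leaf_distances(root):
    """Pairwise leaf path lengths of a TreeNode tree (test-side walk)."""
    paths = {}

    def walk(node, trail):
        trail = trail + [(id(node), node.length)]
        if node.is_leaf():
            paths[node.name] = trail
        for c in node.children:
            walk(c, trail)

    for c in root.children:
        walk(c, [])
    out = {}
    for a, b in itertools.combinations(sorted(paths), 2):
        pa, pb = paths[a], paths[b]
        shared = 0
        while (shared < min(len(pa), len(pb))
               and pa[shared][0] == pb[shared][0]):
            shared += 1
        total = sum(w for _, w in pa[shared:]) + sum(w for _, w in pb[shared:])
        out[(a, b)] = total
    return out


def tree_splits(root):
    """Non-trivial bipartitions of the leaf set induced by internal edges."""
    everyone = frozenset(l.name for l in root.leaves())
    res = set()

    def walk(node):
        for c in node.children:
            if not c.is_leaf():
                below = frozenset(l.name for l in c.leaves())
                res.add(frozenset({below, everyone - below}))
            walk(c)

    walk(root)
    return res


# ---------------------------------------------------- composition vectors


class TestCompositionVector:
    def test_matches_bruteforce_on_two_sequence_proteome(self):
        seqs = ["MKVLAAGMKVLA", "GMKVAAGL"]
        v = composition_vector("g", seqs, k=3)
        oracle = brute_force_cv(seqs, 3)
        assert set(v.entries) == set(oracle)
        for kmer, val in oracle.items():
            assert v.entries[kmer] == pytest.approx(val)

    def test_zero_entropy_string_has_zero_deviation(self):
        v = composition_vector("g", ["A" * 40], k=3)
        assert list(v.entries.values()) == [0.0]

    def test_identical_proteomes_identical_vectors(self):
        seqs = ["MKVLAAGMKVLA", "GMKVAAGL"]
        u = composition_vector("a", seqs, k=4)
        v = composition_vector("b", list(seqs), k=4)
        assert u.entries == v.entries

    def test_concatenation_order_free(self):
        a = composition_vector("a", ["MKVLAAG", "GMKVAAGL"], k=3)
        b = composition_vector("b", ["GMKVAAGL", "MKVLAAG"], k=3)
        assert a.entries == b.entries

    def test_ambiguity_characters_skipped(self):
        v = composition_vector("g", ["MKXVL" * 5], k=3)
        assert not any("X" in kmer for kmer in v.entries)

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError):
            composition_vector("g", ["MK"], k=6)
        with pytest.raises(ValueError):
            composition_vector("g", ["MKVLAA"], k=2)


class TestCvDistance:
    def test_self_distance_zero(self):
        v = composition_vector("g", ["MKVLAAGMKVLA"], k=3)
        assert cv_distance(v, v) == pytest.approx(0.0)

    def test_orthogonal_supports_give_half(self):
        u = CompositionVector("a", 3, {"AAA": 1.0})
        v = CompositionVector("b", 3, {"CCC": 1.0})
        assert cv_distance(u, v) == pytest.approx(0.5)

    def test_opposite_vectors_give_one(self):
        u = CompositionVector("a", 3, {"AAA": 1.0, "CCC": -2.0})
        v = CompositionVector("b", 3, {"AAA": -1.0, "CCC": 2.0})
        assert cv_distance(u, v) == pytest.approx(1.0)

    def test_k_mismatch_and_zero_norm_rejected(self):
        u = CompositionVector("a", 3, {"AAA": 1.0})
        with pytest.raises(ValueError):
            cv_distance(u, CompositionVector("b", 4, {"AAAA": 1.0}))
        with pytest.raises(ValueError):
            cv_distance(u, CompositionVector("b", 3, {}))

    def test_matrix_symmetric_zero_diagonal_bounded(self):
        rng = np.random.default_rng(0)
        vectors = []
        for g in range(4):
            seqs = ["".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 80))
                    for _ in range(5)]
            vectors.append(composition_vector(f"g{g}", seqs, k=3))
        labels, d = distance_matrix(vectors)
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        assert (d >= 0).all() and (d <= 1).all()

    def test_distance_tracks_mutation_load(self):
        """More substitutions from a common ancestor => larger CV distance."""
        rates = [0.05, 0.1, 0.2, 0.3, 0.4, 0.5]
        alphabet = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype="S1")
        correlations = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            ancestor = rng.choice(alphabet, size=(40, 120))
            anc_seqs = [row.tobytes().decode() for row in ancestor]
            v_anc = composition_vector("anc", anc_seqs, k=4)
            dists = []
            for r in rates:
                mutated = ancestor.copy()
                mask = rng.random(mutated.shape) < r
                mutated[mask] = rng.choice(alphabet, size=int(mask.sum()))
                seqs = [row.tobytes().decode() for row in mutated]
                dists.append(cv_distance(v_anc, composition_vector("m", seqs, k=4)))
            correlations.append(spearmanr(rates, dists).statistic)
        assert np.mean(correlations) > 0.9


# ---------------------------------------------------------------- NJ


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float)
        tree = neighbor_joining(["A", "B", "C"], d)
        limbs = {c.name: c.length for c in tree.children}
        assert limbs == pytest.approx({"A": 1.0, "B": 1.0, "C": 3.0})

    @pytest.mark.parametrize("n_taxa", [4, 5, 6, 7, 8])
    def test_recovers_additive_matrices_exactly(self, n_taxa):
        rng = np.random.default_rng(n_taxa)
        labels, d = random_additive_tree(n_taxa, rng)
        tree = neighbor_joining(labels, d)
        paths = tree_leaf_distances(tree)
        idx = {lab: i for i, lab in enumerate(labels)}
        for (a, b), length in paths.items():
            assert length == pytest.approx(d[idx[a], idx[b]], abs=1e-9)

    @pytest.mark.parametrize("n_taxa", [4, 6, 8])
    def test_topology_agrees_with_reference_nj(self, n_taxa):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(100 + n_taxa)
        labels, d = random_additive_tree(n_taxa, rng)
        mine = tree_splits(neighbor_joining(labels, d))
        ref_tree = skbio_nj(DistanceMatrix(d, ids=labels))
        everyone = frozenset(labels)
        ref = set()
        for node in ref_tree.traverse(include_self=False):
            if not node.is_tip():
                below = frozenset(t.name for t in node.tips())
                if 1 < len(below) < len(labels) - 1:
                    ref.add(frozenset({below, everyone - below}))
        assert mine == ref

    def test_unrooted_binary_edge_count(self):
        for n in (4, 5, 9):
            rng = np.random.default_rng(n)
            labels, d = random_additive_tree(n, rng)
            tree = neighbor_joining(labels, d)
            assert tree.n_edges() == 2 * n - 3
            assert sorted(l.name for l in tree.leaves()) == sorted(labels)

    def test_label_permutation_only_renames_leaves(self):
        rng = np.random.default_rng(42)
        labels, d = random_additive_tree(5, rng)
        perm = rng.permutation(len(labels))
        plabels = [labels[i] for i in perm]
        pd_ = d[np.ix_(perm, perm)]
        t1 = tree_splits(neighbor_joining(labels, d))
        t2 = tree_splits(neighbor_joining(plabels, pd_))
        assert t1 == t2

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            neighbor_joining(["A", "B"], np.zeros((2, 2)))
        asym = np.array([[0, 1, 2], [9, 0, 1], [2, 1, 0]], float)
        with pytest.raises(ValueError):
            neighbor_joining(["A", "B", "C"], asym)

    def test_newick_and_phylip_outputs(self, tmp_path):
        d = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float)
        tree = neighbor_joining(["A", "B", "C"], d)
        nwk = tree.to_newick()
        assert nwk.endswith(";") and "A:" in nwk
        write_phylip(["A", "B", "C"], d, tmp_path / "m.phylip")
        lines = (tmp_path / "m.phylip").read_text().splitlines()
        assert lines[0].strip() == "3"
        assert len(lines) == 4
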