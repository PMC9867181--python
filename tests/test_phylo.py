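import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sscoi.phylo import (
    DistanceMatrix,
    Edge,
    UnrootedTree,
    bootstrap_support,
    distance_matrix,
    nj_tree,
    p_distance,
)

from tests.conftest import make_alignment

ACGT = "ACGT"
FULL = "ACGTRYSWKMBDHVN-"


def brute_force_p_distance(a, b):
    comparable = [(x, y) for x, y in zip(a, b) if x in ACGT and y in ACGT]
    n = len(comparable)
    mismatches = sum(1 for x, y in comparable if x != y)
    return mismatches / n, n


class TestPDistance:
    def test_identical(self):
        assert p_distance("ACGT", "ACGT") == (0.0, 4)

    def test_one_difference(self):
        assert p_distance("ACGT", "ACGA") == (0.25, 4)

    def test_pairwise_deletion_hand_count(self):
        # sites 1,2,4 comparable, all matching
        assert p_distance("AC-TN", "ACGTA") == (0.0, 3)

    def test_zero_comparable_sites_is_error(self):
        with pytest.raises(ValueError, match="undefined"):
            p_distance("NNNN", "ACGT")

    def test_unequal_lengths(self):
        with pytest.raises(ValueError, match="unequal lengths"):
            p_distance("ACG", "ACGT")

    @given(
        st.integers(0, 2**31),
        st.integers(20, 80),
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force(self, seed, length):
        rng = np.random.default_rng(seed)
        a = "".join(rng.choice(list(FULL), size=length))
        b = "".join(rng.choice(list(FULL), size=length))
        expected_pairs = [(x, y) for x, y in zip(a, b) if x in ACGT and y in ACGT]
        if not expected_pairs:
            with pytest.raises(ValueError):
                p_distance(a, b)
        else:
            assert p_distance(a, b) == brute_force_p_distance(a, b)


class TestDistanceMatrix:
    def test_identical_sequences_all_zero(self):
        aln = make_alignment(
            [(f"s{i}", "sp", "target", "ACGTACGT") for i in range(4)]
        )
        dm = distance_matrix(aln)
        assert np.all(dm.d == 0)
        assert np.all(dm.n_comparable == 8)

    def test_three_sequences_match_per_pair_calls(self):
        rows = [
            ("a", "sp", "target", "ACGTAC-TNA"),
            ("b", "sp", "target", "ACGAACGTAA"),
            ("c", "sp", "non_target", "TCGTACGTTT"),
        ]
        aln = make_alignment(rows)
        dm = distance_matrix(aln)
        for i in range(3):
            for j in range(3):
                if i == j:
                    continue
                d, n = p_distance(rows[i][3], rows[j][3])
                assert dm.d[i, j] == pytest.approx(d)
                assert dm.n_comparable[i, j] == n

    def test_exactly_one_zero_offdiagonal_pair(self):
        aln = make_alignment(
            [
                ("a", "sp", "target", "ACGT"),
                ("b", "sp", "target", "ACGT"),
                ("c", "sp", "non_target", "TTTT"),
            ]
        )
        dm = distance_matrix(aln)
        off = [(i, j) for i in range(3) for j in range(3) if i < j and dm.d[i, j] == 0]
        assert off == [(0, 1)]

    def test_complete_deletion_drops_columns_globally(self):
        aln = make_alignment(
            [
                ("a", "sp", "target", "ACGTA"),
                ("b", "sp", "target", "ACGTT"),
                ("c", "sp", "non_target", "AC-TA"),
            ]
        )
        dm = distance_matrix(aln, deletion="complete")
        # the column with the gap in c is dropped for every pair
        off = ~np.eye(3, dtype=bool)
        assert np.all(dm.n_comparable[off] == 4)
        assert dm.d[0, 1] == pytest.approx(0.25)

    def test_error_names_pair(self):
        aln = make_alignment(
            [
                ("ok1", "sp", "target", "ACGT"),
                ("ok2", "sp", "target", "ACGT"),
                ("bad", "sp", "non_target", "NNNN"),
            ]
        )
        with pytest.raises(ValueError, match="bad"):
            distance_matrix(aln)

    @given(st.integers(0, 10**6), st.integers(3, 8), st.integers(10, 40))
    @settings(max_examples=50, deadline=None)
    def test_symmetric_zero_diagonal_property(self, seed, n_seqs, length):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n_seqs):
            seq = "".join(rng.choice(list("ACGTN-"), size=length, p=[0.23] * 4 + [0.04, 0.04]))
            rows.append((f"s{i}", "sp", "target", seq))
        try:
            dm = distance_matrix(make_alignment(rows))
        except ValueError:
            return  # some pair had no comparable sites; valid outcome
        assert np.allclose(dm.d, dm.d.T)
        assert np.all(np.diag(dm.d) == 0)
        assert np.all((dm.d >= 0) & (dm.d <= 1))


def matrix_from(labels, d):
    d = np.asarray(d, dtype=float)
    return DistanceMatrix(
        labels=tuple(labels), d=d, n_comparable=np.full(d.shape, 100, dtype=np.int64)
    )


def random_additive_tree(n_leaves, rng):
    """Random binary unrooted tree with positive branch lengths; returns
    (tree, labels). Built by sequential random leaf attachment."""
    labels = [f"L{i}" for i in range(n_leaves)]
    tree = UnrootedTree(leaf_labels={0: labels[0], 1: labels[1], 2: labels[2]})
    next_id = n_leaves  # internal ids after leaf ids
    center = next_id
    next_id += 1
    for leaf in range(3):
        tree.edges.append(Edge(center, leaf, float(rng.uniform(0.005, 0.05))))
    for leaf in range(3, n_leaves):
        tree.leaf_labels[leaf] = labels[leaf]
        edge = tree.edges[rng.integers(0, len(tree.edges))]
        split = next_id
        next_id += 1
        frac = float(rng.uniform(0.2, 0.8))
        tree.edges.append(Edge(edge.u, split, edge.length * frac))
        tree.edges.append(Edge(split, edge.v, edge.length * (1 - frac)))
        tree.edges.append(Edge(split, leaf, float(rng.uniform(0.005, 0.05))))
        tree.edges.remove(edge)
    return tree, labels


def leaf_distance_matrix(tree, labels):
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = tree.leaf_path_length(labels[i], labels[j])
    return matrix_from(labels, d)


class TestNJ:
    def test_spec_additive_quartet(self):
        # additive matrix of ((A:1,B:2):1,C:3,D:4)
        d = [
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0],
        ]
        tree = nj_tree(matrix_from("ABCD", d))
        assert set(tree.bipartitions()) == {frozenset({"C", "D"})}
        internal = [e for e in tree.edges if e.u not in tree.leaf_labels and e.v not in tree.leaf_labels]
        assert len(internal) == 1
        assert internal[0].length == pytest.approx(1.0)
        leaf_lengths = {
            tree.leaf_labels[e.v if e.v in tree.leaf_labels else e.u]: e.length
            for e in tree.edges
            if e.u in tree.leaf_labels or e.v in tree.leaf_labels
        }
        assert leaf_lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0})
        for i, a in enumerate("ABCD"):
            for j, b in enumerate("ABCD"):
                if i < j:
                    assert tree.leaf_path_length(a, b) == pytest.approx(d[i][j], abs=1e-9)

    def test_three_taxa_closed_form(self):
        d = [[0, 3, 5], [3, 0, 6], [5, 6, 0]]
        tree = nj_tree(matrix_from("ABC", d))
        expected = {"A": 1.0, "B": 2.0, "C": 4.0}  # (dAB+dAC-dBC)/2 etc.
        for e in tree.edges:
            leaf = e.v if e.v in tree.leaf_labels else e.u
            assert e.length == pytest.approx(expected[tree.leaf_labels[leaf]])

    def test_all_zero_matrix(self):
        tree = nj_tree(matrix_from("ABCD", np.zeros((4, 4))))
        assert all(e.length == 0 for e in tree.edges)
        assert len(tree.edges) == 5

    def test_fewer_than_three_labels(self):
        with pytest.raises(ValueError, match="at least 3"):
            nj_tree(matrix_from("AB", np.zeros((2, 2))))

    def test_binary_shape(self):
        for n in (4, 7, 12):
            rng = np.random.default_rng(n)
            tree, labels = random_additive_tree(n, rng)
            recovered = nj_tree(leaf_distance_matrix(tree, labels))
            assert len(recovered.edges) == 2 * n - 3
            internal_nodes = recovered.nodes() - set(recovered.leaf_labels)
            assert len(internal_nodes) == n - 2

    @pytest.mark.parametrize("seed", range(20))
    def test_recovers_random_additive_topologies(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        tree, labels = random_additive_tree(n, rng)
        dm = leaf_distance_matrix(tree, labels)
        recovered = nj_tree(dm)
        assert set(recovered.bipartitions()) == set(tree.bipartitions())
        for i in range(n):
            for j in range(i + 1, n):
                assert recovered.leaf_path_length(labels[i], labels[j]) == pytest.approx(
                    dm.d[i, j], abs=1e-9
                )


def perfectly_informative_quartet(n_cols=40):
    rows = [
        ("A", "sp1", "target", "A" * n_cols),
        ("B", "sp1", "target", "A" * n_cols),
        ("C", "sp2", "non_target", "C" * n_cols),
        ("D", "sp2", "non_target", "C" * n_cols),
    ]
    return make_alignment(rows)


class TestBootstrap:
    def test_perfect_alignment_support_100(self):
        tree = bootstrap_support(perfectly_informative_quartet(), replicates=50, seed=3)
        supports = [e.support for e in tree.edges if e.support is not None]
        assert supports == [100]

    def test_deterministic_for_fixed_seed(self, plain_panel):
        aln, _ = plain_panel
        t1 = bootstrap_support(aln, replicates=25, seed=7)
        t2 = bootstrap_support(aln, replicates=25, seed=7)
        s1 = sorted((frozenset(p), t1.edges[i].support) for p, i in t1.bipartitions().items())
        s2 = sorted((frozenset(p), t2.edges[i].support) for p, i in t2.bipartitions().items())
        assert s1 == s2

    def test_supports_in_range(self, plain_panel):
        aln, _ = plain_panel
        tree = bootstrap_support(aln, replicates=20, seed=11)
        for e in tree.edges:
            if e.support is not None:
                assert 0 <= e.support <= 100

    def test_replicates_below_one_is_error(self, plain_panel):
        aln, _ = plain_panel
        with pytest.raises(ValueError, match="replicates"):
            bootstrap_support(aln, replicates=0, seed=1)

    def test_undefined_replicate_skipped_with_warning(self):
        # record 'b' has one comparable column; resampling often misses it
        aln = make_alignment(
            [
                ("a", "sp1", "target", "ACGT"),
                ("b", "sp1", "target", "ANNN"),
                ("c", "sp2", "non_target", "TCGT"),
                ("d", "sp2", "non_target", "TCGA"),
            ]
        )
        with pytest.warns(UserWarning, match="skipped"):
            bootstrap_support(aln, replicates=30, seed=5)
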