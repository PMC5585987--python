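"""Distance matrices, NJ/UPGMA construction, bootstrap supports, Newick IO."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from genefam.phylogeny import (
    DistanceMatrix,
    PhylogenyError,
    Tree,
    assign_subfamilies,
    bootstrap_supports,
    nj_tree,
    p_distance,
    upgma_tree,
)
from tests.tree_oracle import best_topology, enumerate_topologies


class TestPDistance:
    def test_identical_sequences(self):
        dm = p_distance([("a", "ACDE"), ("b", "ACDE")])
        assert dm.d[0, 1] == 0.0

    def test_single_mismatch(self):
        dm = p_distance([("a", "ACDE"), ("b", "ACDF")])
        assert dm.d[0, 1] == pytest.approx(0.25)

    def test_complete_deletion_drops_gap_columns(self):
        # hand count: column 2 has a gap in c, so distances run over 3 columns
        aln = [("a", "ACDE"), ("b", "ACDF"), ("c", "AC-E")]
        dm = p_distance(aln)
        assert dm.d[0, 1] == pytest.approx(1 / 3)
        assert dm.d[0, 2] == 0.0
        assert dm.d[1, 2] == pytest.approx(1 / 3)

    def test_all_gap_columns_error(self):
        with pytest.raises(PhylogenyError):
            p_distance([("a", "--"), ("b", "AC")])

    @given(st.integers(0, 2**31 - 1))
    def test_symmetric_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        seqs = ["".join(rng.choice(list("ACDE"), size=20)) for _ in range(4)]
        dm = p_distance([(f"t{i}", s) for i, s in enumerate(seqs)])
        assert np.allclose(dm.d, dm.d.T) and (dm.d >= 0).all()


def _random_additive_matrix(rng, labels):
    """Distance matrix generated from a random topology with positive branches."""
    topologies = enumerate_topologies(labels)
    edges, n_nodes = topologies[rng.integers(0, len(topologies))]
    lengths = {frozenset(e): rng.uniform(0.05, 0.5) for e in edges}
    adj = {}
    for a, b in edges:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        stack = [(i, None, 0.0)]
        while stack:
            node, prev, dist = stack.pop()
            if node < n and node != i:
                d[i, node] = dist
            for nxt in adj[node]:
                if nxt != prev:
                    stack.append((nxt, node, dist + lengths[frozenset((node, nxt))]))
    return DistanceMatrix(labels=list(labels), d=d)


class TestNeighborJoining:
    def test_additive_quartet_exact(self):
        # tree ((A:1,B:2):1,C:3,D:4): additive distances
        d = np.array([[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float)
        tree = nj_tree(DistanceMatrix(["A", "B", "C", "D"], d))
        oracle = best_topology(["A", "B", "C", "D"], d)
        assert oracle["residual"] < 1e-18
        assert tree.bipartitions() == oracle["bipartitions"]
        lengths = {l.name: l.branch_length for l in tree.root.leaves()}
        assert lengths == pytest.approx({"A": 1, "B": 2, "C": 3, "D": 4})

    @pytest.mark.parametrize("n_taxa", [4, 5, 6])
    def test_additive_recovery_matches_bruteforce(self, n_taxa):
        """On additive matrices NJ finds the unique zero-residual topology."""
        rng = np.random.default_rng(42 + n_taxa)
        labels = [f"t{i}" for i in range(n_taxa)]
        for _ in range(5):
            dm = _random_additive_matrix(rng, labels)
            oracle = best_topology(labels, dm.d)
            assert oracle["residual"] < 1e-18
            assert nj_tree(dm).bipartitions() == oracle["bipartitions"]

    def test_three_taxa_closed_form(self):
        d = np.array([[0, 0.4, 0.6], [0.4, 0, 0.8], [0.6, 0.8, 0]])
        tree = nj_tree(DistanceMatrix(["A", "B", "C"], d))
        lengths = {l.name: l.branch_length for l in tree.root.leaves()}
        assert lengths == pytest.approx({"A": 0.1, "B": 0.3, "C": 0.5})

    def test_input_order_invariance(self):
        rng = np.random.default_rng(5)
        labels = [f"t{i}" for i in range(6)]
        dm = _random_additive_matrix(rng, labels)
        perm = [3, 0, 5, 1, 4, 2]
        dm2 = DistanceMatrix([labels[i] for i in perm], dm.d[np.ix_(perm, perm)])
        assert nj_tree(dm).bipartitions() == nj_tree(dm2).bipartitions()

    def test_matches_skbio_on_random_matrix(self):
        import skbio

        rng = np.random.default_rng(9)
        labels = [f"t{i}" for i in range(7)]
        dm = _random_additive_matrix(rng, labels)
        dm = DistanceMatrix(labels, (dm.d + dm.d.T) / 2)  # exact symmetry
        ours = nj_tree(dm).bipartitions()
        sk = skbio.tree.nj(skbio.DistanceMatrix(dm.d, ids=labels))
        theirs = set()
        allset = frozenset(labels)
        anchor = min(allset)
        for node in sk.non_tips():
            side = frozenset(t.name for t in node.tips())
            if anchor in side:
                side = allset - side
            if 1 < len(side) < len(labels) - 1:
                theirs.add(side)
        assert ours == theirs

    def test_fewer_than_three_taxa_error(self):
        with pytest.raises(PhylogenyError):
            nj_tree(DistanceMatrix(["a", "b"], np.array([[0, 1], [1, 0.0]])))


class TestUpgma:
    def test_hand_ultrametric_instance(self):
        d = np.array([
            [0.0, 0.2, 0.5, 0.5],
            [0.2, 0.0, 0.5, 0.5],
            [0.5, 0.5, 0.0, 0.3],
            [0.5, 0.5, 0.3, 0.0],
        ])
        tree = upgma_tree(DistanceMatrix(["A", "B", "C", "D"], d))
        assert tree.is_ultrametric()
        assert tree.clade_leafsets() == {frozenset("AB"), frozenset("CD")}
        newick = tree.to_newick()
        assert "A:0.100000" in newick and "C:0.150000" in newick

    def test_two_taxa_cherry(self):
        tree = upgma_tree(DistanceMatrix(["A", "B"], np.array([[0, 0.4], [0.4, 0.0]])))
        assert tree.to_newick() == "(A:0.200000,B:0.200000);"

    def test_tie_breaks_to_lowest_index_pair(self):
        d = np.array([[0, 0.2, 0.2], [0.2, 0, 0.4], [0.2, 0.4, 0.0]])
        tree = upgma_tree(DistanceMatrix(["A", "B", "C"], d))
        assert frozenset("AB") in tree.clade_leafsets()

    @given(st.integers(0, 2**31 - 1))
    def test_always_ultrametric(self, seed):
        rng = np.random.default_rng(seed)
        n = 5
        x = rng.uniform(0.05, 1.0, size=(n, n))
        d = (x + x.T) / 2
        np.fill_diagonal(d, 0.0)
        tree = upgma_tree(DistanceMatrix([f"t{i}" for i in range(n)], d))
        assert tree.is_ultrametric()

    def test_cophenetic_matches_scipy_average_linkage(self):
        from scipy.cluster.hierarchy import average, cophenet
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(3)
        n = 6
        x = rng.uniform(0.1, 1.0, size=(n, n))
        d = (x + x.T) / 2
        np.fill_diagonal(d, 0.0)
        labels = [f"t{i}" for i in range(n)]
        tree = upgma_tree(DistanceMatrix(labels, d))

        depth = {}          # node depth from root, by id
        leafdepth = {}

        def walk(node, acc):
            acc = acc + (node.branch_length or 0.0)
            depth[id(node)] = acc
            if node.is_leaf:
                leafdepth[node.name] = acc
            for c in node.children:
                walk(c, acc)

        walk(tree.root, 0.0)

        def mrca(a, b):
            node = tree.root
            while True:
                nxt = [c for c in node.children if {a, b} <= c.leaf_names()]
                if not nxt:
                    return node
                node = nxt[0]

        ours = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                a, b = labels[i], labels[j]
                dm_ab = leafdepth[a] + leafdepth[b] - 2 * depth[id(mrca(a, b))]
                ours[i, j] = ours[j, i] = dm_ab
        expected = squareform(cophenet(average(squareform(d))))
        assert np.allclose(ours, expected, atol=1e-9)


class TestNewick:
    def test_write_read_write_idempotent(self):
        d = np.array([[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float)
        tree = nj_tree(DistanceMatrix(["A", "B", "C", "D"], d))
        s1 = tree.to_newick()
        s2 = Tree.from_newick(s1, rooted=False).to_newick()
        assert s1 == s2

    def test_supports_survive_round_trip(self):
        s = "((A:0.100000,B:0.200000)95:0.050000,C:0.300000,D:0.400000);"
        tree = Tree.from_newick(s, rooted=False)
        assert tree.internal_nodes()[0].support == 95
        assert tree.to_newick() == s

    def test_parse_error(self):
        with pytest.raises(PhylogenyError):
            Tree.from_newick("(A,B")


class TestBootstrap:
    def _clean_alignment(self):
        # every column supports the AB|CDE split
        col_ab = {"A": "A", "B": "A", "C": "C", "D": "C", "E": "C"}
        seqs = {t: col_ab[t] * 30 for t in "ABCDE"}
        # add distinguishing columns so distances are not degenerate
        extra = {"A": "AAAA", "B": "AAAC", "C": "CCGA", "D": "CCTT", "E": "CGTT"}
        return [(t, seqs[t] + extra[t]) for t in "ABCDE"]

    def test_unanimous_split_gets_full_support(self):
        tree = bootstrap_supports(self._clean_alignment(), "nj", replicates=50, seed=1)
        supports = {frozenset(n.leaf_names()): n.support for n in tree.internal_nodes()}
        allset = frozenset("ABCDE")
        ab = {k if "A" not in k else allset - k: v for k, v in supports.items() if v is not None}
        assert any(v == 100.0 for k, v in ab.items() if k == frozenset("CDE") or k == frozenset("AB"))

    def test_same_seed_reproducible(self):
        t1 = bootstrap_supports(self._clean_alignment(), "nj", replicates=40, seed=7)
        t2 = bootstrap_supports(self._clean_alignment(), "nj", replicates=40, seed=7)
        assert t1.to_newick() == t2.to_newick()

    def test_two_seeds_within_sampling_noise(self):
        """Supports from two seeds differ < 15 points per edge (binomial SE bound)."""
        rng = np.random.default_rng(2)
        bases = "ACDE"
        seqs = {t: "" for t in "ABCDE"}
        for _ in range(120):
            kind = rng.integers(0, 10)
            col = {t: "A" for t in "ABCDE"}
            if kind < 7:      # AB | CDE signal
                col.update({"C": "C", "D": "C", "E": "C"})
            else:             # conflicting AC signal
                col.update({"B": "C", "D": "C", "E": "C"})
            noise = "ABCDE"[rng.integers(0, 5)]
            col[noise] = bases[rng.integers(0, 4)]
            for t in "ABCDE":
                seqs[t] += col[t]
        aln = list(seqs.items())
        t1 = bootstrap_supports(aln, "nj", replicates=100, seed=1)
        t2 = bootstrap_supports(aln, "nj", replicates=100, seed=2)
        s1 = {n.leaf_names(): n.support for n in t1.internal_nodes() if n.support is not None}
        s2 = {n.leaf_names(): n.support for n in t2.internal_nodes() if n.support is not None}
        assert s1.keys() == s2.keys()
        for k in s1:
            assert abs(s1[k] - s2[k]) < 15.0

    def test_supports_in_range_on_bundle(self, bundle):
        from Bio import SeqIO

        aln = [(r.id, str(r.seq)) for r in SeqIO.parse(str(bundle.paths["alignment"]), "fasta")]
        tree = bootstrap_supports(aln, "upgma", replicates=20, seed=0)
        vals = [n.support for n in tree.internal_nodes() if n.support is not None]
        assert vals and all(0.0 <= v <= 100.0 for v in vals)


class TestSubfamilies:
    def test_six_planted_clades_recovered(self, bundle):
        from Bio import SeqIO

        aln = [(r.id, str(r.seq)) for r in SeqIO.parse(str(bundle.paths["alignment"]), "fasta")]
        tree = nj_tree(p_distance(aln))
        labels = assign_subfamilies(tree, bundle.ground_truth["anchors"])
        assert labels == bundle.ground_truth["subfamily"]
        assert len(set(labels.values())) == 6

    def test_conflicting_anchors_leave_unassigned(self):
        tree = Tree.from_newick("((X:1,(A1:1,B1:1):1):1,C1:1);")
        labels = assign_subfamilies(tree, {"A1": "I", "B1": "II", "C1": "III"})
        assert labels["X"] == "unassigned"

    def test_anchors_only_identity(self):
        tree = Tree.from_newick("((A:1,B:1):1,C:1);")
        anchors = {"A": "I", "B": "I", "C": "II"}
        assert assign_subfamilies(tree, anchors) == anchors

    def test_missing_anchor_error(self):
        tree = Tree.from_newick("((A:1,B:1):1,C:1);")
        with pytest.raises(PhylogenyError):
            assign_subfamilies(tree, {"Z": "I"})
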