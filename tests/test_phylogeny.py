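import numpy as np
import pytest

from panrbh import (
    DistanceMatrix,
    SimulationParams,
    core_distance_matrix,
    neighbor_joining,
    simulate_pangenome,
    write_newick,
)
from panrbh.phylogeny import TreeNode


def tree_splits(tree: TreeNode, taxa: frozenset) -> set:
    """Non-trivial bipartitions induced by the tree's internal edges."""
    out = set()

    def rec(node):
        lv = frozenset(node.leaves())
        if 2 <= len(lv) <= len(taxa) - 2:
            out.add(frozenset([lv, taxa - lv]))
        for c in node.children:
            rec(c)

    for c in tree.children:
        rec(c)
    return out


def random_additive_tree(taxa, rng):
    """Random binary tree with positive branch lengths; returns the
    leaf-to-leaf path-distance matrix and the set of true bipartitions."""
    adj = {}  # node -> {nbr: length}

    def connect(u, v, ln):
        adj.setdefault(u, {})[v] = ln
        adj.setdefault(v, {})[u] = ln

    def disconnect(u, v):
        del adj[u][v]
        del adj[v][u]

    center = "int0"
    n_int = 1
    for t in taxa[:3]:
        connect(center, t, float(rng.uniform(0.2, 1.0)))
    for t in taxa[3:]:
        edges = [(u, v) for u in adj for v in adj[u] if u < v]
        u, v = edges[rng.integers(len(edges))]
        ln = adj[u][v]
        w = f"int{n_int}"
        n_int += 1
        split = float(rng.uniform(0.2, 0.8)) * ln
        disconnect(u, v)
        connect(u, w, split)
        connect(w, v, ln - split)
        connect(w, t, float(rng.uniform(0.2, 1.0)))

    def dists_from(src):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            x = stack.pop()
            for y, ln in adj[x].items():
                if y not in dist:
                    dist[y] = dist[x] + ln
                    stack.append(y)
        return dist

    n = len(taxa)
    D = np.zeros((n, n))
    for i, t in enumerate(taxa):
        d = dists_from(t)
        for j, s in enumerate(taxa):
            D[i, j] = d[s]

    full = frozenset(taxa)
    splits = set()
    internal_edges = [
        (u, v) for u in adj for v in adj[u]
        if u < v and u.startswith("int") and v.startswith("int")
    ]
    for u, v in internal_edges:
        # leaves on v's side after cutting edge (u, v)
        saved = adj[u][v]
        disconnect(u, v)
        side = frozenset(k for k in dists_from(v) if not k.startswith("int"))
        connect(u, v, saved)
        splits.add(frozenset([side, full - side]))
    return DistanceMatrix(list(taxa), D), splits


class TestNeighborJoining:
    def test_three_taxa_branch_lengths(self):
        dm = DistanceMatrix(["A", "B", "C"],
                            np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0.0]]))
        tree = neighbor_joining(dm)
        lengths = {c.name: c.length for c in tree.children}
        assert lengths == pytest.approx({"A": 1.0, "B": 1.0, "C": 3.0})

    def test_four_taxon_additive_recovery(self):
        # tree ((A:1,B:2):1,(C:3,D:4)); path distances below
        d = np.array([
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0.0],
        ])
        dm = DistanceMatrix(list("ABCD"), d)
        tree = neighbor_joining(dm)
        taxa = frozenset("ABCD")
        assert tree_splits(tree, taxa) == {
            frozenset([frozenset("AB"), frozenset("CD")])
        }
        leaf_len = {}

        def rec(n):
            for c in n.children:
                if c.name:
                    leaf_len[c.name] = c.length
                rec(c)

        rec(tree)
        assert leaf_len == pytest.approx({"A": 1, "B": 2, "C": 3, "D": 4})

    def test_equidistant_taxa_deterministic(self):
        d = np.ones((4, 4)) - np.eye(4)
        dm = DistanceMatrix(list("ABCD"), d)
        a = write_newick(neighbor_joining(dm))
        b = write_newick(neighbor_joining(dm))
        assert a == b

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["A", "B"], np.zeros((2, 2))))

    @pytest.mark.parametrize("n_taxa", [5, 6, 8])
    def test_recovers_random_additive_trees(self, n_taxa):
        rng = np.random.default_rng(n_taxa)
        taxa = [f"t{i:02d}" for i in range(n_taxa)]
        for _ in range(20):
            dm, true_splits = random_additive_tree(taxa, rng)
            tree = neighbor_joining(dm)
            assert tree_splits(tree, frozenset(taxa)) == true_splits

    def test_topology_invariant_under_taxon_permutation(self):
        rng = np.random.default_rng(4)
        taxa = [f"t{i}" for i in range(6)]
        dm, true_splits = random_additive_tree(taxa, rng)
        perm = [3, 0, 5, 1, 4, 2]
        dm2 = DistanceMatrix([dm.taxa[i] for i in perm],
                             dm.d[np.ix_(perm, perm)])
        assert tree_splits(neighbor_joining(dm2), frozenset(taxa)) == true_splits

    def test_matches_independent_nj_implementation(self):
        """Same topology as scikit-bio's NJ on a random non-additive matrix."""
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(11)
        n = 6
        taxa = [f"t{i}" for i in range(n)]
        raw = rng.uniform(0.2, 1.0, size=(n, n))
        d = (raw + raw.T) / 2
        np.fill_diagonal(d, 0.0)
        ours = neighbor_joining(DistanceMatrix(taxa, d))
        theirs = skbio.tree.nj(skbio.DistanceMatrix(d, ids=taxa))
        their_splits = set()
        full = frozenset(taxa)
        for node in theirs.non_tips():
            side = frozenset(t.name for t in node.tips())
            if 2 <= len(side) <= n - 2:
                their_splits.add(frozenset([side, full - side]))
        assert tree_splits(ours, full) == their_splits


class TestCoreDistanceMatrix:
    def test_identical_genomes_zero_distance(self, small_sim):
        proteomes, truth = small_sim
        dm = core_distance_matrix(truth.families, proteomes)
        off = dm.d[~np.eye(len(dm.taxa), dtype=bool)]
        assert np.allclose(off, 0.0, atol=1e-12)

    def test_divergence_ordering_and_symmetry(self):
        params = SimulationParams(
            n_genomes=4, core_size=8, kappa=5.0, alpha=0.7,
            divergence=0.15, gene_length_range=(60, 100),
            clade_assignment={"g1": 0, "g2": 0, "g3": 1, "g4": 1},
            within_clade_divergence=0.02, seed=5,
        )
        proteomes, truth = simulate_pangenome(params)
        dm = core_distance_matrix(truth.families, proteomes)
        assert np.allclose(dm.d, dm.d.T)
        i = {t: k for k, t in enumerate(dm.taxa)}
        within = dm.d[i["g1"], i["g2"]]
        assert within < dm.d[i["g1"], i["g3"]]
        assert within < dm.d[i["g2"], i["g4"]]

    def test_no_core_families_rejected(self, small_sim):
        proteomes, _ = small_sim
        with pytest.raises(ValueError, match="core"):
            core_distance_matrix([], proteomes)


class TestNewick:
    def test_three_taxon_serialization(self):
        dm = DistanceMatrix(["A", "B", "C"],
                            np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0.0]]))
        assert write_newick(neighbor_joining(dm)) == "(A:1,B:1,C:3);"

    def test_negative_length_clamped(self):
        t = TreeNode(children=[TreeNode("A", -1e-9), TreeNode("B", 1.0),
                               TreeNode("C", 2.0)])
        assert write_newick(t) == "(A:0,B:1,C:2);"

    def test_round_trip_via_dendropy(self):
        dendropy = pytest.importorskip("dendropy")
        rng = np.random.default_rng(3)
        taxa = [f"t{i}" for i in range(6)]
        dm, _ = random_additive_tree(taxa, rng)
        nwk = write_newick(neighbor_joining(dm))
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        assert {lf.taxon.label for lf in tree.leaf_node_iter()} == set(taxa)
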