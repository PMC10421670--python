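import math

import dendropy
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from polyphylo import treekit as tk

from conftest import assert_ultrametric, random_tree, tree_depths


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------


class TestNewick:
    def test_support_read(self):
        t = tk.read_newick("((A:1,B:1)90:1,C:2);")
        labels = [nd.label for nd in t.preorder_internal_node_iter() if nd.label]
        assert labels == ["90"]

    def test_roundtrip_canonical(self):
        s = "((A:1,B:1)90:1,C:2);"
        t = tk.read_newick(s)
        assert tk.write_newick(tk.read_newick(tk.write_newick(t))) == tk.write_newick(t)

    def test_posterior_rescaled(self):
        t = tk.read_newick("((A:1,B:1)0.94:1,C:2);")
        assert [nd.label for nd in t.preorder_internal_node_iter() if nd.label] == ["94"]

    @pytest.mark.parametrize("bad", ["((A,B)", "(A,B))C;"])
    def test_unbalanced_errors_with_offset(self, bad):
        with pytest.raises(ValueError, match="offset"):
            tk.read_newick(bad)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_roundtrip_random_trees(self, seed):
        rng = np.random.default_rng(seed)
        labels = [f"t{i}" for i in range(int(rng.integers(4, 9)))]
        t = random_tree(rng, labels)
        s = tk.write_newick(t)
        assert tk.write_newick(tk.read_newick(s)) == s


# ---------------------------------------------------------------------------
# Rooting
# ---------------------------------------------------------------------------


class TestOutgroupRooting:
    def test_single_outgroup(self):
        t = tk.read_newick("(A:1,B:1,(C:1,O:1):1);")
        r = tk.root_by_outgroup(t, ["O"])
        sides = [
            frozenset(lf.taxon.label for lf in k.leaf_iter())
            for k in r.seed_node.child_nodes()
        ]
        assert frozenset({"O"}) in sides

    def test_outgroup_pair_on_stem(self):
        t = tk.read_newick("((A:1,B:1):1,(C:1,(O1:1,O2:1):1):1);")
        r = tk.root_by_outgroup(t, ["O1", "O2"])
        sides = [
            frozenset(lf.taxon.label for lf in k.leaf_iter())
            for k in r.seed_node.child_nodes()
        ]
        assert frozenset({"O1", "O2"}) in sides

    def test_all_taxa_outgroup_errors(self):
        t = tk.read_newick("(A:1,B:1,C:1);")
        with pytest.raises(ValueError):
            tk.root_by_outgroup(t, ["A", "B", "C"])

    def test_non_monophyletic_errors(self):
        t = tk.read_newick("((A:1,O1:1):1,(B:1,O2:1):1,C:1);")
        with pytest.raises(ValueError, match="monophyletic"):
            tk.root_by_outgroup(t, ["O1", "O2"])

    def test_support_preserved_across_rooting(self):
        t = tk.read_newick("((A:1,B:1)77:1,(C:1,O:2)88:1,D:1);")
        r = tk.root_by_outgroup(t, ["O"])
        smap = tk._support_by_split(r)
        ab = tk.make_split({"A", "B"}, {"C", "D", "O"})
        assert smap.get(ab) == "77"


def _mad_oracle(tree, n_grid=2000):
    """Grid-search oracle: deviation of pair (i,j) for a root point is
    |d_i - d_j| / d_ij with d_i the path distance from leaf i to the point."""
    leaves = sorted(tree.leaf_node_iter(), key=lambda l: l.taxon.label)
    names = [l.taxon.label for l in leaves]
    # path distances leaf->node via parent chains
    def path_to_root(nd):
        out = {}
        d = 0.0
        while nd is not None:
            out[id(nd)] = d
            d += nd.edge.length or 0.0
            nd = nd.parent_node
        return out

    chains = {l.taxon.label: path_to_root(l) for l in leaves}

    def leaf_point_dist(name, child, frac_from_child, L):
        ch = chains[name]
        if id(child) in ch:
            return ch[id(child)] + frac_from_child
        # ascend: find deepest ancestor of child present in leaf's chain
        nd = child
        up = 0.0
        while id(nd) not in ch:
            up += nd.edge.length or 0.0
            nd = nd.parent_node
        return ch[id(nd)] + (up - frac_from_child)

    D = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            # distance via any common point: use root of chains
            ci, cj = chains[names[i]], chains[names[j]]
            shared = [k for k in ci if k in cj]
            D[(i, j)] = min(ci[k] + cj[k] for k in shared)
    best = None
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        L = nd.edge.length or 0.0
        if L == 0:
            continue
        xs = np.linspace(0.0, L, n_grid + 1)
        di = np.array(
            [[leaf_point_dist(nm, nd, x, L) for x in xs] for nm in names]
        )
        ss = np.zeros_like(xs)
        npairs = 0
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                ss += ((di[i] - di[j]) / D[(i, j)]) ** 2
                npairs += 1
        scores = np.sqrt(ss / npairs)
        k = int(np.argmin(scores))
        if best is None or scores[k] < best[0]:
            below = frozenset(lf.taxon.label for lf in nd.leaf_iter())
            best = (float(scores[k]), below, float(xs[k]))
    return best


class TestMADRooting:
    def test_clocklike_midpoint(self):
        t = tk.read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        r, score = tk.mad_root(t, return_score=True)
        assert score == pytest.approx(0.0, abs=1e-12)
        depth = tree_depths(r)
        tips = [depth[lf] for lf in r.leaf_node_iter()]
        assert max(tips) == pytest.approx(min(tips), abs=1e-9)

    def test_matches_grid_oracle_random_trees(self, rng):
        for _ in range(20):
            t = random_tree(rng, [f"t{i}" for i in range(6)])
            r, score = tk.mad_root(t, return_score=True)
            o_score, o_below, o_x = _mad_oracle(t)
            assert score == pytest.approx(o_score, abs=1e-5)
            sides = {
                frozenset(lf.taxon.label for lf in k.leaf_iter())
                for k in r.seed_node.child_nodes()
            }
            all_taxa = frozenset(f"t{i}" for i in range(6))
            assert o_below in sides or (all_taxa - o_below) in sides

    def test_recovers_root_edge_of_ultrametric_tree(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 8))
            # random coalescent-style ultrametric tree
            import dendropy

            tns = dendropy.TaxonNamespace()
            nodes = []
            for i in range(n):
                nd = dendropy.Node()
                nd.taxon = tns.require_taxon(label=f"t{i}")
                nd.age = 0.0
                nodes.append(nd)
            h = 0.0
            while len(nodes) > 1:
                h += float(rng.uniform(0.2, 1.0))
                i, j = sorted(rng.choice(len(nodes), 2, replace=False))
                parent = dendropy.Node()
                parent.age = h
                for k in (j, i):
                    ch = nodes.pop(k)
                    parent.add_child(ch)
                    ch.edge.length = h - ch.age
                nodes.append(parent)
            tree = dendropy.Tree(taxon_namespace=tns)
            tree.seed_node = nodes[0]
            tree.is_rooted = True
            original = {
                frozenset(lf.taxon.label for lf in k.leaf_iter())
                for k in tree.seed_node.child_nodes()
            }
            r = tk.mad_root(tree)
            recovered = {
                frozenset(lf.taxon.label for lf in k.leaf_iter())
                for k in r.seed_node.child_nodes()
            }
            assert recovered == original
            assert_ultrametric(r, rel_tol=1e-6)

    def test_zero_length_tree_errors(self):
        t = tk.read_newick("((A:0,B:0):0,(C:0,D:0):0);")
        with pytest.raises(ValueError):
            tk.mad_root(t)


# ---------------------------------------------------------------------------
# Collapsing / bipartitions / RF
# ---------------------------------------------------------------------------


class TestCollapseAndSplits:
    def test_collapse_boundary_strict(self):
        t = tk.read_newick("(((A:1,B:1)32:1,C:1)33:1,(D:1,E:1)100:1);")
        c = tk.collapse_low_support(t, 33)
        splits = tk.bipartitions(c)
        assert tk.make_split({"A", "B"}, {"C", "D", "E"}) not in splits
        assert tk.make_split({"A", "B", "C"}, {"D", "E"}) in splits

    def test_collapse_identity_at_full_support(self):
        t = tk.read_newick("(((A:1,B:1)100:1,C:1)100:1,(D:1,E:1)100:1);")
        assert tk.write_newick(tk.collapse_low_support(t, 33)) == tk.write_newick(t)

    def test_full_collapse_gives_star(self):
        t = tk.read_newick("(((A:1,B:1)10:1,C:1)5:1,(D:1,E:1)1:1);")
        c = tk.collapse_low_support(t, 33)
        assert len(tk.bipartitions(c)) == 0
        assert len(c.seed_node.child_nodes()) == 5

    def test_rf_identical_zero(self):
        t1 = tk.read_newick("(((A,B),C),(D,E));")
        t2 = tk.read_newick("(((B,A),C),(E,D));")
        assert tk.rf_distance(t1, t2) == 0

    def test_rf_one_nni_is_two(self):
        t1 = tk.read_newick("(((A,B),C),(D,E));")
        t2 = tk.read_newick("(((A,C),B),(D,E));")
        assert tk.rf_distance(t1, t2) == 2

    def test_rf_star_vs_binary(self):
        star = tk.read_newick("(A,B,C,D,E);")
        binary = tk.read_newick("(((A,B),C),(D,E));")
        assert tk.rf_distance(star, binary) == 2

    def test_rf_too_few_shared_taxa(self):
        t1 = tk.read_newick("((A,B),(C,X));")
        t2 = tk.read_newick("((A,B),(Y,Z));")
        with pytest.raises(ValueError):
            tk.rf_distance(t1, t2)


# ---------------------------------------------------------------------------
# Distances and NJ
# ---------------------------------------------------------------------------


class TestK2P:
    def test_identical_zero(self):
        dm = tk.k2p_distance_matrix({"a": "ACGTACGT", "b": "ACGTACGT"})
        assert dm.values[0, 1] == 0.0

    def test_formula_two_transitions_one_transversion(self):
        a = "A" * 100
        b = "G" + "G" + "C" + "A" * 97  # 2 transitions (A->G), 1 transversion (A->C)
        dm = tk.k2p_distance_matrix({"a": a, "b": b})
        P, Q = 0.02, 0.01
        expect = -0.5 * math.log((1 - 2 * P - Q) * math.sqrt(1 - 2 * Q))
        assert dm.values[0, 1] == pytest.approx(expect, rel=1e-12)
        assert expect == pytest.approx(0.03070, abs=5e-6)

    @pytest.mark.parametrize(
        "b",
        ["GGAA", "TCAA"],  # P=0.5 (1-2P-Q=0) and Q=0.5 (1-2Q=0)
    )
    def test_saturated_flag(self, b):
        dm = tk.k2p_distance_matrix({"a": "AAAA", "b": b})
        assert dm.saturated[0, 1]
        assert np.isnan(dm.values[0, 1])

    def test_pairwise_deletion(self):
        dm = tk.k2p_distance_matrix({"a": "ACGT--AA", "b": "ACGTGGAA"})
        assert dm.values[0, 1] == 0.0  # gap columns excluded

    def test_k2p_converges_to_truth_on_simulated_data(self, rng):
        from polyphylo import simdata as sd

        cfg = sd.SimulationConfig(
            n_loci=1, locus_length=50_000, g=1.0, clock_rate=0.01, kappa=1.0, seed=5
        )
        tree = tk.read_newick("(x:5,y:5);")
        aln = sd.evolve_alignment(tree, cfg, rng=rng)
        dm = tk.k2p_distance_matrix(aln)
        assert dm.values[0, 1] == pytest.approx(0.1, rel=0.05)


class TestNeighborJoining:
    def test_additive_matrix_exact(self):
        m = np.array(
            [[0, 3, 3.5, 2.5], [3, 0, 4.5, 3.5], [3.5, 4.5, 0, 2], [2.5, 3.5, 2, 0]]
        )
        t = tk.neighbor_joining(tk.DistanceMatrix(["A", "B", "C", "D"], m))
        assert tk.make_split({"A", "B"}, {"C", "D"}) in tk.bipartitions(t)
        # internal edge length 1 (four-point condition)
        internal = [
            nd.edge.length
            for nd in t.preorder_node_iter()
            if not nd.is_leaf() and nd.parent_node is not None
        ]
        assert sum(internal) == pytest.approx(1.0)
        # terminal lengths recovered exactly
        lens = {
            lf.taxon.label: lf.edge.length for lf in t.leaf_node_iter()
        }
        assert lens == pytest.approx({"A": 1, "B": 2, "C": 1.5, "D": 0.5})

    def test_three_taxa_exact(self):
        m = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]])
        t = tk.neighbor_joining(tk.DistanceMatrix(["A", "B", "C"], m))
        lens = {lf.taxon.label: lf.edge.length for lf in t.leaf_node_iter()}
        assert lens == pytest.approx({"A": 1, "B": 2, "C": 3})

    def test_asymmetric_errors(self):
        m = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            tk.neighbor_joining(tk.DistanceMatrix(["A", "B", "C"], m))

    def test_ultrametric_matrix_clocklike_tree(self):
        # ultrametric distances -> clocklike NJ tree (root-to-tip depths equal
        # after rooting at the deepest split midpoint)
        m = np.array(
            [[0, 2, 8, 8], [2, 0, 8, 8], [8, 8, 0, 4], [8, 8, 4, 0]], dtype=float
        )
        t = tk.neighbor_joining(tk.DistanceMatrix(["A", "B", "C", "D"], m))
        r = tk.mad_root(t)
        assert_ultrametric(r, rel_tol=1e-9)


class TestBootstrap:
    def _aln(self):
        # conflict-free signal: identical background plus sites splitting AB|CD
        bg = "ACGT" * 8
        return {
            "A": bg + "A" * 8,
            "B": bg + "A" * 8,
            "C": bg + "G" * 8,
            "D": bg + "G" * 8,
        }

    def test_clean_signal_support_100(self):
        t = tk.bootstrap_support(self._aln(), n=50, seed=0)
        smap = tk._support_by_split(t)
        assert smap[tk.make_split({"A", "B"}, {"C", "D"})] == "100"

    def test_fixed_seed_reproducible(self, rng):
        from polyphylo import simdata as sd

        cfg = sd.SimulationConfig(n_loci=1, locus_length=300, g=0.5, seed=9)
        tree = tk.read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        aln = sd.evolve_alignment(tree, cfg, rng=np.random.default_rng(4))
        t1 = tk.bootstrap_support(aln, n=40, seed=123)
        t2 = tk.bootstrap_support(aln, n=40, seed=123)
        assert tk.write_newick(t1) == tk.write_newick(t2)

    def test_n_one_supports_binary(self):
        t = tk.bootstrap_support(self._aln(), n=1, seed=3)
        for _, v in tk._support_by_split(t).items():
            assert v in ("0", "100")

    def test_n_nonpositive_errors(self):
        with pytest.raises(ValueError):
            tk.bootstrap_support(self._aln(), n=0, seed=1)

    def test_support_monotone_in_signal_strength(self):
        # two conflicting signals; support for AB|CD grows with its share
        bg = "ACGT" * 20
        def aln(k):
            s1 = {"A": "A", "B": "A", "C": "G", "D": "G"}  # AB|CD
            s2 = {"A": "A", "B": "G", "C": "A", "D": "G"}  # AC|BD
            return {
                x: bg + s1[x] * (20 + k) + s2[x] * (20 - k) for x in "ABCD"
            }

        supports = []
        for k in (2, 8, 16):
            t = tk.bootstrap_support(aln(k), n=200, seed=7)
            smap = tk._support_by_split(t)
            supports.append(int(smap[tk.make_split({"A", "B"}, {"C", "D"})]))
        assert supports == sorted(supports)
        assert supports[-1] > supports[0]


# ---------------------------------------------------------------------------
# Likelihood engine
# ---------------------------------------------------------------------------


class TestFitBranchLengths:
    def test_two_taxon_jc_closed_form(self):
        phat = 0.1
        aln = {"x": "A" * 90 + "C" * 10, "y": "A" * 90 + "G" * 10}
        t, _ = tk.fit_branch_lengths(tk.read_newick("(x:0.1,y:0.1);"), aln)
        total = sum(nd.edge.length for nd in t.preorder_node_iter() if nd.parent_node)
        expect = -0.75 * math.log(1 - 4 / 3 * phat)
        assert total == pytest.approx(expect, abs=1e-6)

    def test_identical_sequences_zero_lengths(self):
        aln = {"x": "ACGT" * 25, "y": "ACGT" * 25}
        t, _ = tk.fit_branch_lengths(tk.read_newick("(x:0.3,y:0.3);"), aln)
        for nd in t.preorder_node_iter():
            if nd.parent_node:
                assert nd.edge.length == pytest.approx(0.0, abs=1e-6)

    def test_lnl_invariant_under_rerooting(self, rng):
        from polyphylo import simdata as sd

        cfg = sd.SimulationConfig(n_loci=1, locus_length=400, g=0.5, seed=2)
        tree = tk.read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        aln = sd.evolve_alignment(tree, cfg, rng=rng)
        t1 = tk.read_newick("((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1);")
        t2 = tk.read_newick("(((A:0.1,B:0.1):0.05,C:0.1):0.05,D:0.1);")
        _, l1 = tk.fit_branch_lengths(t1, aln)
        _, l2 = tk.fit_branch_lengths(t2, aln)
        assert l1 == pytest.approx(l2, abs=1e-3)

    def test_missing_taxa_errors(self):
        with pytest.raises(ValueError):
            tk.fit_branch_lengths(
                tk.read_newick("(x:1,z:1);"), {"x": "ACGT", "y": "ACGT"}
            )

    def test_hky_pmat_matches_expm(self):
        from scipy.linalg import expm

        model = tk.HKYModel(kappa=3.0, freqs=(0.1, 0.2, 0.3, 0.4))
        Q = np.zeros((4, 4))
        f = np.array([0.1, 0.2, 0.3, 0.4])
        for i in range(4):
            for j in range(4):
                if i != j:
                    Q[i, j] = f[j] * (3.0 if (i, j) in ((0, 2), (2, 0), (1, 3), (3, 1)) else 1.0)
        Q[np.diag_indices(4)] = -Q.sum(axis=1)
        Q /= -np.dot(f, np.diag(Q))
        for t in (0.01, 0.3, 2.0):
            assert np.allclose(model.pmat(t), expm(Q * t), atol=1e-10)
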