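import itertools

import numpy as np
import pytest

from polyphylo import discord as dc
from polyphylo import orthodata as od
from polyphylo import simdata as sd
from polyphylo import treekit as tk


def rooted(newick):
    t = tk.read_newick(newick)
    t.is_rooted = True
    return t


# ---------------------------------------------------------------------------
# Concordance pies
# ---------------------------------------------------------------------------


class TestConcordance:
    def test_identical_gene_trees_all_concordant(self):
        sp = rooted("((((A,B),C),D),O);")
        gts = [rooted("((((A,B),C),D),O);") for _ in range(3)]
        for nc in dc.concordance_summary(sp, gts, collapse_threshold=None):
            assert (nc.concordant, nc.dominant_alt, nc.other_conflict, nc.uninformative) == (3, 0, 0, 0)

    def test_mixed_set_hand_derivation(self):
        sp = rooted("((((A,B),C),D),O);")
        g1 = rooted("((((A,B),C),D),O);")
        g2 = rooted("((((A,C),B),D),O);")
        g3 = rooted("(((A,B,C),D),O);")  # polytomy
        res = dc.concordance_summary(sp, [g1, g2, g3], collapse_threshold=None)
        node_ab = next(nc for nc in res if nc.clade == frozenset({"A", "B"}))
        assert node_ab.concordant == 1
        assert node_ab.dominant_alt == 1
        assert node_ab.dominant_alt_clade == frozenset({"A", "C"})
        assert node_ab.other_conflict == 0
        assert node_ab.uninformative == 1

    def test_missing_taxon_uninformative(self):
        sp = rooted("((((A,B),C),D),O);")
        g = rooted("(((A,C),D),O);")  # no B
        res = dc.concordance_summary(sp, [g], collapse_threshold=None)
        node_ab = next(nc for nc in res if nc.clade == frozenset({"A", "B"}))
        assert node_ab.uninformative == 1 and node_ab.concordant == 0

    def test_collapse_applied_before_scoring(self):
        sp = rooted("((((A,B),C),D),O);")
        g = rooted("((((A,C)10,B),D),O);")  # conflicting clade, support 10 < 33
        res = dc.concordance_summary(sp, [g], collapse_threshold=33)
        node_ab = next(nc for nc in res if nc.clade == frozenset({"A", "B"}))
        assert node_ab.uninformative == 1 and node_ab.dominant_alt == 0

    def _oracle(self, sp, gts):
        """Independent exhaustive-compatibility oracle (no dominant logic)."""
        ROOT = "\x01R"
        below_sp = tk._leafset_below(sp)
        sp_taxa = frozenset(l.taxon.label for l in sp.leaf_node_iter())
        out = {}
        for nd in sp.preorder_internal_node_iter():
            clade = below_sp[nd]
            if not (2 <= len(clade) < len(sp_taxa)):
                continue
            conc = confl = uninf = 0
            for gt in gts:
                gt_taxa = frozenset(l.taxon.label for l in gt.leaf_node_iter())
                r = clade & gt_taxa
                if len(r) < 2 or not (gt_taxa - clade):
                    uninf += 1
                    continue
                gclades = set()
                below_gt = tk._leafset_below(gt)
                for gnd in gt.preorder_internal_node_iter():
                    s = below_gt[gnd]
                    if 2 <= len(s) < len(gt_taxa):
                        gclades.add(frozenset(s))
                if any(g & gt_taxa == r for g in gclades):
                    conc += 1
                    continue
                found = False
                # explicit split-pair compatibility with a virtual root taxon
                s1, s2 = r, (gt_taxa - r) | {ROOT}
                for g in gclades:
                    t1, t2 = g, (gt_taxa - g) | {ROOT}
                    if all([s1 & t1, s1 & t2, s2 & t1, s2 & t2]):
                        found = True
                        break
                if found:
                    confl += 1
                else:
                    uninf += 1
            out[clade] = (conc, confl, uninf)
        return out

    def test_matches_exhaustive_oracle_on_random_sets(self, rng):
        labels = [f"t{i}" for i in range(5)] + ["O"]
        for _ in range(10):
            sp = self._random_rooted(rng, labels)
            gts = []
            for _ in range(8):
                keep = [l for l in labels if rng.random() > 0.25]
                if len(keep) < 3:
                    keep = labels[:3]
                gt = self._random_rooted(rng, keep)
                # random polytomies
                for nd in list(gt.preorder_internal_node_iter()):
                    if nd is not gt.seed_node and rng.random() < 0.3:
                        nd.edge.collapse()
                gts.append(gt)
            res = dc.concordance_summary(sp, gts, collapse_threshold=None)
            oracle = self._oracle(sp, gts)
            for nc in res:
                conc, confl, uninf = oracle[nc.clade]
                assert nc.concordant == conc
                assert nc.dominant_alt + nc.other_conflict == confl
                assert nc.uninformative == uninf

    @staticmethod
    def _random_rooted(rng, labels):
        from conftest import random_tree

        t = random_tree(rng, list(labels))
        t = tk.root_by_outgroup(t, [labels[-1]])
        return t


# ---------------------------------------------------------------------------
# Quartet sampling score algebra
# ---------------------------------------------------------------------------


class TestQuartetScoreAlgebra:
    def test_equal_counts_qc_zero(self):
        b = dc.BranchQuartetScore(split=None, t0=5, t1=5, t2=5)
        assert b.qc == pytest.approx(0.0, abs=1e-12)

    def test_all_concordant_full_support(self):
        b = dc.BranchQuartetScore(split=None, t0=9, t1=0, t2=0)
        assert b.qc == 1.0
        assert b.qd is None
        assert b.qi == 1.0
        assert dc.label_string(b) == "1/-/1"

    def test_no_informative_replicates(self):
        b = dc.BranchQuartetScore(split=None, u=10)
        assert b.qi == 0.0
        assert b.qc is None and b.qd is None
        assert dc.label_string(b) == "-/-/0"

    def test_qc_sign_follows_dominance(self):
        assert dc.BranchQuartetScore(split=None, t0=8, t1=2, t2=1).qc > 0
        assert dc.BranchQuartetScore(split=None, t0=2, t1=8, t2=1).qc < 0
        assert dc.BranchQuartetScore(split=None, t0=5, t1=5, t2=1).qc == 0.0

    def test_qd_boundaries(self):
        assert dc.BranchQuartetScore(split=None, t0=1, t1=4, t2=4).qd == 1.0
        assert dc.BranchQuartetScore(split=None, t0=1, t1=4, t2=0).qd == 0.0

    def test_counts_sum_to_replicates(self):
        b = dc.BranchQuartetScore(split=None, t0=3, t1=2, t2=1, u=4)
        assert b.replicates == 10
        assert b.qi == pytest.approx(0.6)


class TestQuartetSampling:
    def test_full_support_no_ils(self, rng):
        spec = "backbone = (((A:2,B:2):4,(C:3,D:3):3):4,O:10);\noutgroups = O\n"
        m = sd.build_network(spec)
        cfg = sd.SimulationConfig(
            n_loci=20, locus_length=400, g=1e-6, clock_rate=0.01, seed=4
        )
        trees = sd.simulate_gene_trees(m, cfg)
        alns = {
            f"OG{i}": sd.evolve_alignment(t, cfg, rng=rng)
            for i, t in enumerate(trees)
        }
        sm = od.concatenate(alns, ["A", "B", "C", "D", "O"])
        sp = rooted("(((A:2,B:2):4,(C:3,D:3):3):4,O:10);")
        qs = dc.quartet_sampling(sp, sm.rows, n_reps=25, seed=1)
        assert len(qs.branches) == 2
        for b in qs.branches:
            assert dc.label_string(b) == "1/-/1"
        assert all(v == 1.0 for v in qs.qf.values())

    def test_branch_without_data_skipped_and_reported(self):
        sp = rooted("(((A,B),C),(D,E));")
        aln = {t: "ACGTACGT" for t in ("A", "B", "C")}  # D,E have no data
        qs = dc.quartet_sampling(sp, aln, n_reps=2, seed=0)
        assert qs.branches == []
        assert len(qs.skipped_branches) == 2

    def test_no_data_at_all_errors(self):
        sp = rooted("((A,B),(C,D));")
        with pytest.raises(ValueError):
            dc.quartet_sampling(sp, {"X": "ACGT"}, n_reps=2, seed=0)

    def test_seeded_reproducibility(self, rng):
        aln = {
            "A": "ACGTACGTAAAA",
            "B": "ACGTACGTAAAA",
            "C": "ACGTACGTGGGG",
            "D": "ACGTACGTGGGG",
            "E": "ACGTACGTGGGG",
        }
        sp = rooted("(((A,B),C),(D,E));")
        q1 = dc.quartet_sampling(sp, aln, n_reps=10, seed=5)
        q2 = dc.quartet_sampling(sp, aln, n_reps=10, seed=5)
        assert q1.branch_report() == q2.branch_report()


# ---------------------------------------------------------------------------
# Triplet skew test
# ---------------------------------------------------------------------------


class TestTripletSkew:
    def test_perfect_symmetry(self):
        r = dc.triplet_skew_test(
            {frozenset("ab"): 30, frozenset("ac"): 15, frozenset("bc"): 15},
            ("a", "b", "c"),
            g=1.0,
        )
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_skewed_counts(self):
        r = dc.triplet_skew_test(
            {frozenset("ab"): 30, frozenset("ac"): 20, frozenset("bc"): 10},
            ("a", "b", "c"),
            g=1.0,
        )
        assert r.statistic == pytest.approx(10 / 3, rel=1e-9)
        assert r.p_value == pytest.approx(0.06789, abs=1e-4)

    def test_internal_branch_estimate(self):
        # minor fraction 30/60 -> t_hat = -g ln(1.5 * 0.5) = -ln(0.75)
        r = dc.triplet_skew_test(
            {frozenset("ab"): 30, frozenset("ac"): 20, frozenset("bc"): 10},
            ("a", "b", "c"),
            g=2.0,
        )
        assert r.t_hat == pytest.approx(-2.0 * np.log(0.75))

    def test_no_minor_topologies_undefined(self):
        r = dc.triplet_skew_test(
            {frozenset("ab"): 40, frozenset("ac"): 0, frozenset("bc"): 0},
            ("a", "b", "c"),
            g=1.0,
        )
        assert not r.defined

    def test_too_few_trees_errors(self):
        with pytest.raises(ValueError):
            dc.triplet_skew_test(
                {frozenset("ab"): 3, frozenset("ac"): 2, frozenset("bc"): 1},
                ("a", "b", "c"),
                g=1.0,
            )

    def test_counting_from_gene_trees(self):
        gts = [rooted("((a,b),c);")] * 3 + [rooted("((a,c),b);")] * 2 + [
            rooted("((b,c),a);")
        ]
        counts = dc.count_triplet_topologies(gts, ("a", "b", "c"))
        assert counts[frozenset("ab")] == 3
        assert counts[frozenset("ac")] == 2
        assert counts[frozenset("bc")] == 1


# ---------------------------------------------------------------------------
# Cytonuclear conflicts
# ---------------------------------------------------------------------------


class TestCytonuclear:
    def test_identical_trees_empty(self):
        nt = rooted("((A,B),(C,D));")
        pt = rooted("((A,B),(C,D));")
        rep = dc.cytonuclear_conflicts(nt, pt)
        assert not rep.has_conflict
        assert rep.conflicting_taxa() == set()

    def test_swapped_pair(self):
        nt = rooted("((A,B),(C,D));")
        pt = rooted("((A,C),(B,D));")
        rep = dc.cytonuclear_conflicts(nt, pt)
        assert len(rep.nuclear_only_conflicting) == 1
        assert len(rep.plastid_only_conflicting) == 1
        assert rep.sister_of["A"] == (frozenset({"B"}), frozenset({"C"}))

    def test_too_few_shared_taxa(self):
        nt = rooted("((A,B),C);")
        pt = rooted("((A,B),C);")
        with pytest.raises(ValueError):
            dc.cytonuclear_conflicts(nt, pt)

    def test_organelle_capture_always_detected_no_ils(self):
        m = sd.load_preset("organelle-capture")
        hits = 0
        runs = 5
        for seed in range(runs):
            cfg = sd.SimulationConfig(
                n_loci=1, locus_length=500, plastid_length=3000, g=1e-9, seed=seed
            )
            _, _, truth = sd.emit_dataset(m, cfg)
            ptree = tk.read_newick(truth.plastid_tree)
            ptree.is_rooted = True
            # nuclear placement follows the parents (undulata side here); the
            # plastid instead travels with the capture lineage glauca
            nt = rooted(
                "(((attenuata,glauca),((undulata,clevelandii),paniculata)),axillaris);"
            )
            rep = dc.cytonuclear_conflicts(nt, ptree, query_taxa=["clevelandii"])
            nsis, psis = rep.sister_of["clevelandii"]
            if nsis != psis and psis == frozenset({"glauca"}):
                hits += 1
        assert hits == runs
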