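import numpy as np
import pytest

from polyphylo import treekit as tk
from polyphylo.orthodata import OrthogroupTable, SequenceRecord, TaxonInfo


def random_tree(rng, labels, min_bl=0.1, max_bl=2.0):
    """Random binary unrooted-shaped tree with uniform branch lengths,
    built by sequential random attachment."""
    import dendropy

    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)

    def leaf(name):
        nd = dendropy.Node()
        nd.taxon = tns.require_taxon(label=name)
        nd.edge.length = float(rng.uniform(min_bl, max_bl))
        return nd

    seed = tree.seed_node
    for name in labels[:3]:
        seed.add_child(leaf(name))
    edges = [ch for ch in seed.child_nodes()]
    for name in labels[3:]:
        target = edges[rng.integers(len(edges))]
        import dendropy as dp

        parent = target.parent_node
        mid = dp.Node()
        old_len = target.edge.length
        split = float(rng.uniform(0.2, 0.8))
        parent.remove_child(target)
        parent.add_child(mid)
        mid.edge.length = old_len * split
        mid.add_child(target)
        target.edge.length = old_len * (1 - split)
        new = leaf(name)
        mid.add_child(new)
        edges.extend([mid, new])
    tree.is_rooted = False
    return tree


def tree_depths(tree):
    depth = {tree.seed_node: 0.0}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None:
            depth[nd] = depth[nd.parent_node] + (nd.edge.length or 0.0)
    return depth


def assert_ultrametric(tree, rel_tol=1e-9):
    depth = tree_depths(tree)
    tips = [depth[lf] for lf in tree.leaf_node_iter()]
    height = max(tips)
    assert max(tips) - min(tips) <= rel_tol * max(height, 1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20230728)


@pytest.fixture
def toy_filter_table():
    """Five orthogroups exercising each low-copy filter criterion.

    Taxa: four diploids T1-T4 and one tetraploid P1 (no outgroup).
    OG1 all taxa, one 400 bp copy each (kept); OG2 P1 with five copies
    (copy cap); OG3 T1 with three copies (diploid cap); OG4 only T1, T2
    present (coverage 40%); OG5 as OG1 but T1's single copy is 250 bp
    (dropped, coverage then 80%, kept).
    """
    meta = [TaxonInfo(f"T{i}", "diploid") for i in range(1, 5)] + [
        TaxonInfo("P1", "tetraploid")
    ]
    taxa = [t.name for t in meta]
    table = OrthogroupTable(meta)
    seq400 = "ACGT" * 100
    seq250 = "ACGT" * 62 + "AC"

    def rec(og, taxon, k, seq=seq400):
        return SequenceRecord(f"{taxon}|{og}g{k}|c{k}", taxon, seq)

    table.add_group("OG1", [rec("OG1", t, 1) for t in taxa])
    table.add_group(
        "OG2",
        [rec("OG2", t, 1) for t in taxa] + [rec("OG2", "P1", k) for k in range(2, 6)],
    )
    table.add_group(
        "OG3",
        [rec("OG3", t, 1) for t in taxa] + [rec("OG3", "T1", k) for k in (2, 3)],
    )
    table.add_group("OG4", [rec("OG4", "T1", 1), rec("OG4", "T2", 1)])
    table.add_group(
        "OG5",
        [rec("OG5", "T1", 1, seq250)] + [rec("OG5", t, 1) for t in taxa[1:]],
    )
    return table
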