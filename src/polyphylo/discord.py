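"""Gene-tree/species-tree conflict accounting.

Four diagnostics of phylogenomic discordance:

* per-node concordance "pies" (concordant / dominant alternative / other
  conflict / uninformative gene-tree counts for every species-tree clade),
* quartet-sampling branch support (QC/QD/QI per branch, QF per tip) from
  repeated likelihood comparison of resampled four-taxon subproblems,
* a rooted-triplet skew test separating incomplete lineage sorting (whose
  two minor topologies are equally frequent) from introgression,
* nuclear-plastid conflict detection (incompatible splits and per-taxon
  sister shifts between two trees).

Gene trees are scored rooted; because rooted-clade conflict on k taxa is
unrooted-split conflict on k+1, a virtual root taxon is appended before the
four-quadrant compatibility test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.stats import chi2

from . import treekit
from .treekit import _leafset_below  # shared clade tabulation

__all__ = [
    "NodeConcordance",
    "concordance_summary",
    "QuartetScores",
    "quartet_sampling",
    "TripletTestResult",
    "count_triplet_topologies",
    "triplet_skew_test",
    "CytonuclearReport",
    "cytonuclear_conflicts",
]

_ROOT = "\x00root"  # virtual taxon standing for the root side of a clade


# ---------------------------------------------------------------------------
# phyparts-style per-node concordance
# ---------------------------------------------------------------------------


@dataclass
class NodeConcordance:
    """Conflict pie for one species-tree clade."""

    clade: frozenset
    concordant: int = 0
    dominant_alt: int = 0
    dominant_alt_clade: frozenset | None = None
    other_conflict: int = 0
    uninformative: int = 0

    @property
    def total(self) -> int:
        return (
            self.concordant + self.dominant_alt + self.other_conflict + self.uninformative
        )

    def row(self) -> str:
        alt = "+".join(sorted(self.dominant_alt_clade)) if self.dominant_alt_clade else "-"
        return "\t".join(
            [
                "+".join(sorted(self.clade)),
                str(self.concordant),
                str(self.dominant_alt),
                alt,
                str(self.other_conflict),
                str(self.uninformative),
            ]
        )


def _conflicts_rooted(clade: frozenset, gt_clade: frozenset, gt_taxa: frozenset) -> bool:
    """Four-quadrant test with a virtual root taxon appended to both
    complements (rooted trees: the root counts as an observed outgroup)."""
    s, s2 = clade, (gt_taxa - clade) | {_ROOT}
    t, t2 = gt_clade, (gt_taxa - gt_clade) | {_ROOT}
    return bool(s & t) and bool(s & t2) and bool(s2 & t) and bool(s2 & t2)


def concordance_summary(
    species_tree: dendropy.Tree,
    gene_trees,
    collapse_threshold: float = 33.0,
) -> list[NodeConcordance]:
    """Score every internal species-tree clade against each rooted gene tree.

    Per gene tree the clade is concordant if its restriction to the gene
    tree's taxa is present as a clade; conflicting if some gene-tree clade is
    incompatible with it (four-quadrant test including the root); otherwise
    uninformative (missing taxa or polytomy).  The dominant alternative is
    the most frequent conflicting clade, counting each conflicting gene
    tree's smallest conflicting clade (ties: lexicographically smallest).
    Gene trees sharing no taxa with a clade contribute to its uninformative
    count.
    """
    sp_below = _leafset_below(species_tree)
    sp_taxa = frozenset(lf.taxon.label for lf in species_tree.leaf_node_iter())
    nodes = []
    for nd in species_tree.preorder_internal_node_iter():
        s = sp_below[nd]
        if 2 <= len(s) < len(sp_taxa):
            nodes.append(s)
    prepared = []
    for gt in gene_trees:
        if collapse_threshold is not None:
            gt = treekit.collapse_low_support(gt, collapse_threshold)
        gt_taxa = frozenset(lf.taxon.label for lf in gt.leaf_node_iter())
        prepared.append((gt_taxa, treekit.clades(gt) | _rooted_extra_clades(gt)))
    out = []
    for clade in sorted(nodes, key=lambda c: (len(c), tuple(sorted(c)))):
        nc = NodeConcordance(clade=clade)
        alt_counts: dict[frozenset, int] = {}
        for gt_taxa, gt_clades in prepared:
            restricted = clade & gt_taxa
            outside = gt_taxa - clade
            if len(restricted) < 2 or len(outside) < 1:
                nc.uninformative += 1
                continue
            if any((c & gt_taxa) == restricted for c in gt_clades):
                nc.concordant += 1
                continue
            conflicting = sorted(
                (
                    c
                    for c in gt_clades
                    if _conflicts_rooted(restricted, c, gt_taxa)
                ),
                key=lambda c: (len(c), tuple(sorted(c))),
            )
            if conflicting:
                alt = conflicting[0]
                alt_counts[alt] = alt_counts.get(alt, 0) + 1
            else:
                nc.uninformative += 1
        if alt_counts:
            best = sorted(
                alt_counts.items(), key=lambda kv: (-kv[1], tuple(sorted(kv[0])))
            )[0]
            nc.dominant_alt_clade = best[0]
            nc.dominant_alt = best[1]
            nc.other_conflict = sum(alt_counts.values()) - best[1]
        out.append(nc)
    return out


def _rooted_extra_clades(gt: dendropy.Tree) -> set:
    """Clades of the root's children even when they span all-but-one taxon
    (informative in rooted comparison)."""
    below = _leafset_below(gt)
    taxa = frozenset(lf.taxon.label for lf in gt.leaf_node_iter())
    out = set()
    for ch in gt.seed_node.child_nodes():
        s = below[ch]
        if 2 <= len(s) < len(taxa):
            out.add(s)
    return out


def concordance_report(summaries: list[NodeConcordance]) -> str:
    header = "clade\tconcordant\tdominant_alt\tdominant_alt_clade\tother_conflict\tuninformative"
    return "\n".join([header] + [nc.row() for nc in summaries]) + "\n"


# ---------------------------------------------------------------------------
# Quartet sampling
# ---------------------------------------------------------------------------


@dataclass
class BranchQuartetScore:
    split: frozenset  # the species-tree bipartition this branch induces
    t0: int = 0  # concordant
    t1: int = 0
    t2: int = 0
    u: int = 0  # uninformative (below likelihood cutoff)

    @property
    def replicates(self) -> int:
        return self.t0 + self.t1 + self.t2 + self.u

    @property
    def qi(self) -> float:
        n = self.replicates
        return (self.t0 + self.t1 + self.t2) / n if n else 0.0

    @property
    def qc(self) -> float | None:
        """Quartet concordance: entropy-weighted skew of topology counts
        (log base 3), signed by whether the concordant topology dominates;
        None when no informative replicates."""
        tot = self.t0 + self.t1 + self.t2
        if tot == 0:
            return None
        ps = [t / tot for t in (self.t0, self.t1, self.t2) if t > 0]
        ent = 1.0 + sum(p * np.log(p) / np.log(3.0) for p in ps)
        sign = np.sign(self.t0 - max(self.t1, self.t2))
        return float(sign * ent)

    @property
    def qd(self) -> float | None:
        """Quartet differential: balance of the two discordant counts,
        1 - |t1-t2|/(t1+t2); None when no discordant topology was sampled."""
        d = self.t1 + self.t2
        if d == 0:
            return None
        return 1.0 - abs(self.t1 - self.t2) / d


@dataclass
class QuartetScores:
    branches: list[BranchQuartetScore]
    qf: dict[str, float | None]  # per tip
    skipped_branches: list[frozenset] = field(default_factory=list)

    def branch_report(self) -> str:
        def fmt(v):
            return "-" if v is None else f"{v:.3f}"

        lines = ["split\tQC\tQD\tQI\tt0\tt1\tt2\tu"]
        for b in self.branches:
            side = min(
                (tuple(sorted(s)) for s in b.split), key=lambda s: (len(s), s)
            )
            lines.append(
                f"{'+'.join(side)}\t{fmt(b.qc)}\t{fmt(b.qd)}\t{b.qi:.3f}"
                f"\t{b.t0}\t{b.t1}\t{b.t2}\t{b.u}"
            )
        return "\n".join(lines) + "\n"

    def tip_report(self) -> str:
        lines = ["tip\tQF"]
        for t in sorted(self.qf):
            v = self.qf[t]
            lines.append(f"{t}\t" + ("-" if v is None else f"{v:.3f}"))
        return "\n".join(lines) + "\n"


def label_string(b: BranchQuartetScore) -> str:
    """The compact QC/QD/QI annotation, '-' for undefined scores."""

    def fmt(v):
        if v is None:
            return "-"
        if v == int(v):
            return str(int(v))
        return f"{v:.2g}"

    return f"{fmt(b.qc)}/{fmt(b.qd)}/{fmt(b.qi)}"


def quartet_sampling(
    species_tree: dendropy.Tree,
    alignment: dict[str, str],
    n_reps: int = 1000,
    lnl_cutoff: float = 2.0,
    model="JC",
    seed: int | None = None,
) -> QuartetScores:
    """Quartet-sampling branch support.

    For each internal branch and replicate, one tip is drawn from each of
    the four subtrees incident to the branch; the three possible quartet
    topologies are fitted by ML (branch lengths only) on the alignment
    columns where all four tips have data, and the replicate counts toward
    its best topology iff the best log-likelihood exceeds the second best by
    ``lnl_cutoff``.  QF for a tip is the fraction of its informative
    replicates that were concordant.
    """
    rng = np.random.default_rng(seed)
    t = species_tree.clone(depth=1)
    t.deroot()
    below = _leafset_below(t)
    all_taxa = frozenset(lf.taxon.label for lf in t.leaf_node_iter())
    with_data = all_taxa & set(alignment)
    if not with_data:
        raise ValueError("no species-tree tip has an alignment row")
    enc_taxa, enc = treekit.encode_alignment({k: alignment[k] for k in sorted(alignment)})
    enc_row = {k: i for i, k in enumerate(enc_taxa)}
    has_data = {k: (enc[enc_row[k]] < 4) for k in enc_taxa}

    branches = []
    skipped = []
    qf_conc: dict[str, int] = {x: 0 for x in all_taxa}
    qf_tot: dict[str, int] = {x: 0 for x in all_taxa}
    internal = []
    for nd in t.preorder_internal_node_iter():
        if nd is t.seed_node:
            continue
        side = below[nd]
        if 2 <= len(side) <= len(all_taxa) - 2:
            internal.append(nd)
    internal.sort(key=lambda nd: tuple(sorted(below[nd])))
    for nd in internal:
        kids = nd.child_nodes()
        parent = nd.parent_node
        sub1, sub2 = (frozenset(below[k]) for k in kids[:2])
        if len(kids) != 2:
            skipped.append(treekit.make_split(below[nd], all_taxa - below[nd]))
            continue
        rest = [c for c in parent.child_nodes() if c is not nd]
        if parent is t.seed_node:
            if len(rest) != 2:
                skipped.append(treekit.make_split(below[nd], all_taxa - below[nd]))
                continue
            sub3, sub4 = (frozenset(below[c]) for c in rest)
        else:
            if len(rest) != 1:
                skipped.append(treekit.make_split(below[nd], all_taxa - below[nd]))
                continue
            sub3 = frozenset(below[rest[0]])
            sub4 = all_taxa - below[parent]
        # a subtree without any sequence data makes the branch unscorable
        quads = [sorted(s & with_data) for s in (sub1, sub2, sub3, sub4)]
        if any(len(q) == 0 for q in quads):
            skipped.append(treekit.make_split(below[nd], all_taxa - below[nd]))
            continue
        score = BranchQuartetScore(
            split=treekit.make_split(below[nd], all_taxa - below[nd])
        )
        if isinstance(model, str):
            model_obj = treekit.JC if model.upper() == "JC" else None
            if model_obj is None:
                raise ValueError(f"unknown model {model!r}")
        else:
            model_obj = model
        for _ in range(n_reps):
            a, b, c, d = (q[rng.integers(len(q))] for q in quads)
            cols = has_data[a] & has_data[b] & has_data[c] & has_data[d]
            if not np.any(cols):
                score.u += 1
                continue
            # compress the four rows to site patterns once (base-4 hash)
            rows = [np.minimum(enc[enc_row[x]][cols], 4).astype(np.int64) for x in (a, b, c, d)]
            ids = ((rows[0] * 5 + rows[1]) * 5 + rows[2]) * 5 + rows[3]
            binc = np.bincount(ids, minlength=625)
            uniq = np.flatnonzero(binc)
            counts = binc[uniq].astype(float)
            digits = [(uniq // 125) % 5, (uniq // 25) % 5, (uniq // 5) % 5, uniq % 5]
            leaf_partials = {
                x: treekit._EYE5[digits[i]] for i, x in enumerate((a, b, c, d))
            }
            lnls = []
            for topo in (
                f"(({a}:0.1,{b}:0.1):0.1,{c}:0.1,{d}:0.1);",
                f"(({a}:0.1,{c}:0.1):0.1,{b}:0.1,{d}:0.1);",
                f"(({a}:0.1,{d}:0.1):0.1,{b}:0.1,{c}:0.1);",
            ):
                tp = treekit.read_newick(topo)
                lnl = treekit._fit_core(
                    tp, model_obj, counts, leaf_partials,
                    tol=1e-4, max_passes=20, xatol=1e-7,
                )
                lnls.append(lnl)
            order = np.argsort(lnls)[::-1]
            if lnls[order[0]] - lnls[order[1]] < lnl_cutoff:
                score.u += 1
                continue
            best = int(order[0])
            if best == 0:
                score.t0 += 1
            elif best == 1:
                score.t1 += 1
            else:
                score.t2 += 1
            for x in (a, b, c, d):
                qf_tot[x] += 1
                if best == 0:
                    qf_conc[x] += 1
        branches.append(score)
    qf = {
        x: (qf_conc[x] / qf_tot[x] if qf_tot[x] else None) for x in sorted(all_taxa)
    }
    return QuartetScores(branches=branches, qf=qf, skipped_branches=skipped)


# ---------------------------------------------------------------------------
# Triplet skew test (ILS vs introgression)
# ---------------------------------------------------------------------------


@dataclass
class TripletTestResult:
    triple: tuple[str, str, str]
    major_pair: frozenset
    counts: dict  # cherry pair (frozenset) -> count
    major: int
    minor1: int
    minor2: int
    statistic: float | None
    p_value: float | None
    t_hat: float | None  # implied internal branch duration (Ma)

    @property
    def defined(self) -> bool:
        return self.statistic is not None


def count_triplet_topologies(gene_trees, triple) -> dict[frozenset, int]:
    """Rooted triplet topology counts over gene trees containing all three
    taxa: the cherry is the pair whose MRCA excludes the third taxon."""
    a, b, c = triple
    counts = {
        frozenset((a, b)): 0,
        frozenset((a, c)): 0,
        frozenset((b, c)): 0,
    }
    for gt in gene_trees:
        labels = {lf.taxon.label for lf in gt.leaf_node_iter()}
        if not {a, b, c} <= labels:
            continue
        below = _leafset_below(gt)
        best = None
        for nd in gt.postorder_internal_node_iter():
            s = below[nd] & {a, b, c}
            if len(s) == 2:
                best = frozenset(s)
                break
        if best is not None:
            counts[best] += 1
    return counts


def triplet_skew_test(
    gene_trees_or_counts,
    triple: tuple[str, str, str],
    g: float,
    min_trees: int = 20,
) -> TripletTestResult:
    """Chi-square (df=1) symmetry test of the two minor rooted-triplet
    topologies.

    Under pure incomplete lineage sorting both minor topologies have equal
    expected frequency (each (1/3)exp(-t/g)); a significant skew flags
    introgression as the preferred explanation.  Also reports the implied
    internal branch duration t_hat = -g ln(1.5 * minor_fraction_total).
    """
    if isinstance(gene_trees_or_counts, dict):
        counts = dict(gene_trees_or_counts)
    else:
        counts = count_triplet_topologies(gene_trees_or_counts, triple)
    total = sum(counts.values())
    if total < min_trees:
        raise ValueError(
            f"need >= {min_trees} gene trees containing the triple, got {total}"
        )
    ranked = sorted(
        counts.items(), key=lambda kv: (-kv[1], tuple(sorted(kv[0])))
    )
    major_pair, major = ranked[0]
    minor1, minor2 = ranked[1][1], ranked[2][1]
    if minor1 + minor2 == 0:
        stat = p = t_hat = None
    else:
        stat = (minor1 - minor2) ** 2 / (minor1 + minor2)
        p = float(chi2.sf(stat, df=1))
        t_hat = float(-g * np.log(1.5 * (minor1 + minor2) / total))
    return TripletTestResult(
        triple=tuple(triple),
        major_pair=major_pair,
        counts=counts,
        major=major,
        minor1=minor1,
        minor2=minor2,
        statistic=stat,
        p_value=p,
        t_hat=t_hat,
    )


# ---------------------------------------------------------------------------
# Cytonuclear conflict
# ---------------------------------------------------------------------------


@dataclass
class CytonuclearReport:
    shared_taxa: frozenset
    nuclear_only_conflicting: list  # splits in nuclear tree conflicting with plastid
    plastid_only_conflicting: list
    sister_of: dict  # taxon -> (nuclear sister set, plastid sister set)

    @property
    def has_conflict(self) -> bool:
        return bool(self.nuclear_only_conflicting or self.plastid_only_conflicting)

    def conflicting_taxa(self) -> set:
        """Taxa whose sister group differs between the two trees."""
        return {
            t
            for t, (ns, ps) in self.sister_of.items()
            if ns is not None and ps is not None and ns != ps
        }

    def to_tsv(self) -> str:
        lines = ["taxon\tnuclear_sister\tplastid_sister\tdiffers"]
        for t in sorted(self.sister_of):
            ns, ps = self.sister_of[t]
            lines.append(
                "\t".join(
                    [
                        t,
                        "+".join(sorted(ns)) if ns else "-",
                        "+".join(sorted(ps)) if ps else "-",
                        str(int(ns != ps)),
                    ]
                )
            )
        return "\n".join(lines) + "\n"


def _sister_set(tree: dendropy.Tree, taxon: str, shared: frozenset) -> frozenset | None:
    """Leaf set (restricted to shared taxa) of the smallest clade joining
    ``taxon`` with anything else."""
    below = _leafset_below(tree)
    node = None
    for lf in tree.leaf_node_iter():
        if lf.taxon.label == taxon:
            node = lf
            break
    if node is None:
        return None
    nd = node.parent_node
    while nd is not None:
        s = (below[nd] - {taxon}) & shared
        if s:
            return frozenset(s)
        nd = nd.parent_node
    return None


def cytonuclear_conflicts(
    nuclear_tree: dendropy.Tree,
    plastid_tree: dendropy.Tree,
    query_taxa=None,
) -> CytonuclearReport:
    """Detect nuclear-plastid discordance: splits unique to one tree and
    incompatible with the other, plus per-taxon sister-group shifts (the
    tanglegram signal used to call hybrid origins and organelle capture)."""
    n_taxa = frozenset(lf.taxon.label for lf in nuclear_tree.leaf_node_iter())
    p_taxa = frozenset(lf.taxon.label for lf in plastid_tree.leaf_node_iter())
    shared = n_taxa & p_taxa
    if len(shared) < 4:
        raise ValueError(f"need >= 4 shared taxa, got {len(shared)}")
    bn = treekit.bipartitions(nuclear_tree, shared)
    bp = treekit.bipartitions(plastid_tree, shared)
    n_only = sorted(
        (s for s in bn - bp if any(not treekit.splits_compatible(s, o) for o in bp)),
        key=_split_key,
    )
    p_only = sorted(
        (s for s in bp - bn if any(not treekit.splits_compatible(s, o) for o in bn)),
        key=_split_key,
    )
    if query_taxa is None:
        query_taxa = sorted(shared)
    sisters = {
        t: (_sister_set(nuclear_tree, t, shared), _sister_set(plastid_tree, t, shared))
        for t in query_taxa
    }
    return CytonuclearReport(
        shared_taxa=shared,
        nuclear_only_conflicting=n_only,
        plastid_only_conflicting=p_only,
        sister_of=sisters,
    )


def _split_key(s):
    return tuple(sorted(tuple(sorted(x)) for x in s))
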