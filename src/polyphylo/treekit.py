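"""Tree data structures and algorithms shared by every pipeline stage.

Trees are :class:`dendropy.Tree` objects throughout; branch support is stored
as internal-node labels on the 0-100 scale (bootstrap percent).  ASTRAL-style
posterior labels in [0, 1] are rescaled to 0-100 on input.  All tie-breaking
is lexicographic on taxon names.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "read_newick",
    "write_newick",
    "leaf_names",
    "root_by_outgroup",
    "mad_root",
    "collapse_low_support",
    "bipartitions",
    "clades",
    "splits_compatible",
    "rf_distance",
    "DistanceMatrix",
    "k2p_distance_matrix",
    "neighbor_joining",
    "nj_k2p_tree",
    "bootstrap_support",
    "HKYModel",
    "JC",
    "fit_branch_lengths",
]

# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------


def read_newick(text: str, support_scale: str = "auto") -> dendropy.Tree:
    """Parse a newick string with internal-node labels read as support values.

    ``support_scale="auto"`` rescales posterior-style labels (all numeric
    internal labels <= 1) to the 0-100 bootstrap convention.
    """
    # cheap balance pre-check so the error carries a character offset
    depth = 0
    for pos, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ValueError(f"unbalanced ')' at offset {pos}")
    if depth != 0:
        raise ValueError(
            f"unbalanced '(': {depth} unclosed at offset {len(text)}"
        )
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise ValueError(f"newick parse error: {exc}") from exc
    if support_scale == "auto":
        vals = []
        for nd in tree.preorder_internal_node_iter():
            v = _parse_support(nd.label)
            if v is not None:
                vals.append(v)
        if vals and max(vals) <= 1.0:
            for nd in tree.preorder_internal_node_iter():
                v = _parse_support(nd.label)
                if v is not None:
                    nd.label = _fmt_num(v * 100.0)
    return tree


def _parse_support(label) -> float | None:
    if label is None:
        return None
    try:
        return float(label)
    except (TypeError, ValueError):
        return None


def _fmt_num(x: float) -> str:
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    # 10 significant digits: accurate far beyond biological meaning while
    # absorbing last-ulp summation-order noise in upstream algorithms
    return f"{x:.10g}"


def _needs_quote(name: str) -> bool:
    return any(c in name for c in "(),:;[]' \t\n")


def _label_str(name: str) -> str:
    if _needs_quote(name):
        return "'" + name.replace("'", "''") + "'"
    return name


def write_newick(tree: dendropy.Tree, canonical: bool = True) -> str:
    """Serialize a tree to newick.

    ``canonical=True`` orders children by their lexicographically smallest
    descendant leaf, so equal trees serialize identically.
    """

    def _length_suffix(node) -> str:
        if node.edge.length is None:
            return ""
        return ":" + _fmt_num(float(node.edge.length))

    def subtree(node) -> tuple[str, str]:
        # returns (min descendant leaf, newick string w/o length suffix)
        if node.is_leaf():
            name = node.taxon.label if node.taxon else (node.label or "")
            return name, _label_str(name)
        items = []
        for ch in node.child_nodes():
            key, s = subtree(ch)
            items.append((key, s + _length_suffix(ch)))
        if canonical:
            items.sort(key=lambda p: p[0])
        inner = ",".join(s for _, s in items)
        label = node.label if node.label is not None else ""
        return items[0][0], f"({inner}){_label_str(label) if label else ''}"

    root = tree.seed_node
    return subtree(root)[1] + ";"


def leaf_names(tree: dendropy.Tree) -> list[str]:
    return sorted(lf.taxon.label for lf in tree.leaf_node_iter())


# ---------------------------------------------------------------------------
# Rooting
# ---------------------------------------------------------------------------


def _leafset_below(tree) -> dict:
    below = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            below[nd] = frozenset([nd.taxon.label])
        else:
            s = frozenset()
            for ch in nd.child_nodes():
                s |= below[ch]
            below[nd] = s
    return below


def _support_by_split(tree: dendropy.Tree) -> dict:
    """Support labels keyed by unrooted bipartition (rerooting-safe)."""
    all_taxa = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    below = _leafset_below(tree)
    out = {}
    for nd in tree.preorder_internal_node_iter():
        if nd is tree.seed_node or nd.label is None:
            continue
        side = below[nd]
        other = all_taxa - side
        if len(side) >= 2 and len(other) >= 2:
            out[make_split(side, other)] = nd.label
    return out


def _reapply_support(tree: dendropy.Tree, smap: dict) -> None:
    """Re-attach edge supports to nodes after a topology-preserving
    rerooting; labels whose split vanished (root edge) are dropped."""
    all_taxa = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    below = _leafset_below(tree)
    for nd in tree.preorder_internal_node_iter():
        if nd is tree.seed_node:
            continue
        side = below[nd]
        other = all_taxa - side
        key = make_split(side, other) if len(side) >= 2 and len(other) >= 2 else None
        nd.label = smap.get(key) if key is not None else None


def root_by_outgroup(tree: dendropy.Tree, outgroup_taxa: Iterable[str]) -> dendropy.Tree:
    """Root the tree on the edge separating ``outgroup_taxa`` from the rest."""
    og = frozenset(outgroup_taxa)
    t = tree.clone(depth=1)
    all_taxa = frozenset(lf.taxon.label for lf in t.leaf_node_iter())
    if not og:
        raise ValueError("empty outgroup")
    missing = og - all_taxa
    if missing:
        raise ValueError(f"outgroup taxa absent from tree: {sorted(missing)}")
    if og == all_taxa:
        raise ValueError("outgroup cannot be the full taxon set")
    smap = _support_by_split(t)
    t.deroot()
    below = _leafset_below(t)
    target = None
    for nd in t.preorder_node_iter():
        if nd is t.seed_node:
            continue
        s = below[nd]
        if s == og or (all_taxa - s) == og:
            target = nd
            break
    if target is None:
        raise ValueError(
            f"outgroup {sorted(og)} is not monophyletic under any rooting"
        )
    edge = target.edge
    elen = edge.length
    if elen is None:
        t.reroot_at_edge(edge, update_bipartitions=False)
    else:
        t.reroot_at_edge(
            edge, length1=elen / 2.0, length2=elen / 2.0, update_bipartitions=False
        )
    t.is_rooted = True
    _reapply_support(t, smap)
    return t


def _pairwise_leaf_data(tree):
    """Leaf list, leaf-to-leaf distances and per-node leaf distances."""
    leaves = sorted(tree.leaf_node_iter(), key=lambda l: l.taxon.label)
    index = {id(lf): i for i, lf in enumerate(leaves)}
    n = len(leaves)
    # distance from each node to each descendant leaf
    dist_to_leaves = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            dist_to_leaves[nd] = {index[id(nd)]: 0.0}
        else:
            d = {}
            for ch in nd.child_nodes():
                bl = ch.edge.length or 0.0
                for li, dd in dist_to_leaves[ch].items():
                    d[li] = dd + bl
            dist_to_leaves[nd] = d
    D = np.zeros((n, n))
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            continue
        kids = nd.child_nodes()
        for a in range(len(kids)):
            for b in range(a + 1, len(kids)):
                bla = kids[a].edge.length or 0.0
                blb = kids[b].edge.length or 0.0
                for li, da in dist_to_leaves[kids[a]].items():
                    for lj, db in dist_to_leaves[kids[b]].items():
                        D[li, lj] = D[lj, li] = da + bla + db + blb
    return leaves, index, D, dist_to_leaves


def mad_root(tree: dendropy.Tree, return_score: bool = False):
    """Root by Minimal Ancestor Deviation.

    For every branch and root position on it, each tip pair implies an
    ancestor; the relative deviation of a pair is ``|2*d(anc,i)/d(i,j) - 1|``.
    The root is placed where the root-mean-square deviation over all pairs is
    minimal; ties go to the lexicographically smallest bipartition.
    """
    t = tree.clone(depth=1)
    smap = _support_by_split(t)
    t.deroot()
    leaves, index, D, _ = _pairwise_leaf_data(t)
    n = len(leaves)
    if n < 3:
        raise ValueError("MAD rooting needs >= 3 leaves")
    if all((nd.edge.length or 0.0) == 0.0 for nd in t.preorder_node_iter() if nd is not t.seed_node):
        raise ValueError("MAD rooting undefined: all branch lengths are zero")
    labels = [lf.taxon.label for lf in leaves]
    below = _leafset_below(t)
    all_set = frozenset(labels)

    # distance from every leaf to every node (via distances to child node of
    # each edge): d(leaf, node) computed from leaf depths wrt seed.
    depth = {}
    for nd in t.preorder_node_iter():
        if nd is t.seed_node:
            depth[nd] = 0.0
        else:
            depth[nd] = depth[nd.parent_node] + (nd.edge.length or 0.0)
    # leaf-to-node distances via LCA on the seed-rooted view
    # d(leaf, node): walk not needed -- use d(i,node) = depth_i + depth_node - 2*depth_lca
    # we get depth_lca from leafsets: lca of leaf and node is node if leaf below it,
    # else lca of the two in the seed-rooted tree.
    anc_chain = {}
    for lf in leaves:
        chain = []
        nd = lf
        while nd is not None:
            chain.append(nd)
            nd = nd.parent_node
        anc_chain[id(lf)] = chain

    def leaf_node_dist(li, node):
        lf = leaves[li]
        if labels[li] in below[node]:
            return depth[lf] - depth[node]
        # ascend from node until it contains the leaf
        nd = node
        while labels[li] not in below[nd]:
            nd = nd.parent_node
        return depth[lf] - 2 * depth[nd] + depth[node]

    pair_idx = [(i, j) for i in range(n) for j in range(i + 1, n)]
    best = None  # (score, split_key, node, rho_abs)
    for nd in t.preorder_node_iter():
        if nd is t.seed_node:
            continue
        L = nd.edge.length or 0.0
        bset = below[nd]
        aset = all_set - bset
        bidx = [i for i in range(n) if labels[i] in bset]
        aidx = [i for i in range(n) if labels[i] in aset]
        parent = nd.parent_node
        d_b = np.array([leaf_node_dist(i, nd) for i in bidx])
        d_a = np.array([leaf_node_dist(i, parent) for i in aidx])
        # cross pairs
        Dba = d_b[:, None] + L + d_a[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            num = np.sum(1.0 / Dba) - np.sum(2.0 * d_b[:, None] / Dba**2)
            den = 2.0 * np.sum(1.0 / Dba**2)
        x = 0.0 if den == 0 else num / den
        x = min(max(x, 0.0), L)
        dev_cross = 2.0 * (d_b[:, None] + x) / Dba - 1.0
        ss = float(np.sum(dev_cross**2))
        # same-side pairs: ancestor is the median node of (i, j, edge)
        for side in (bidx, aidx):
            ref = nd if side is bidx else parent
            for ii in range(len(side)):
                for jj in range(ii + 1, len(side)):
                    i, j = side[ii], side[jj]
                    dij = D[i, j]
                    if dij == 0:
                        continue
                    dim = 0.5 * (dij + leaf_node_dist(i, ref) - leaf_node_dist(j, ref))
                    ss += (2.0 * dim / dij - 1.0) ** 2
        score = math.sqrt(ss / len(pair_idx))
        split_key = tuple(sorted([tuple(sorted(bset)), tuple(sorted(aset))]))
        cand = (score, split_key, nd, x)
        if best is None or score < best[0] - 1e-12 or (
            abs(score - best[0]) <= 1e-12 and split_key < best[1]
        ):
            best = cand
    _, _, node, x = best
    L = node.edge.length or 0.0
    if L > 0:
        # dendropy: length1 = tail(parent)-side piece, length2 = head(child)-side
        t.reroot_at_edge(
            node.edge, length1=L - x, length2=x, update_bipartitions=False
        )
    else:
        t.reroot_at_edge(node.edge, update_bipartitions=False)
    t.is_rooted = True
    _reapply_support(t, smap)
    if return_score:
        return t, best[0]
    return t


# ---------------------------------------------------------------------------
# Support collapsing
# ---------------------------------------------------------------------------


def collapse_low_support(tree: dendropy.Tree, threshold: float = 33.0) -> dendropy.Tree:
    """Contract internal edges with support strictly below ``threshold``.

    Edges lacking a numeric support label are retained.
    """
    t = tree.clone(depth=1)
    to_collapse = []
    for nd in t.preorder_internal_node_iter():
        if nd is t.seed_node:
            continue
        v = _parse_support(nd.label)
        if v is not None and v < threshold:
            to_collapse.append(nd)
    for nd in to_collapse:
        nd.edge.collapse()
    return t


# ---------------------------------------------------------------------------
# Bipartitions, clades, RF
# ---------------------------------------------------------------------------

Split = frozenset  # frozenset({frozenset(sideA), frozenset(sideB)})


def make_split(side_a: Iterable[str], side_b: Iterable[str]) -> Split:
    return frozenset({frozenset(side_a), frozenset(side_b)})


def bipartitions(tree: dendropy.Tree, taxa: Iterable[str] | None = None) -> set:
    """Nontrivial unrooted bipartitions, optionally restricted to ``taxa``."""
    if taxa is None:
        taxa = [lf.taxon.label for lf in tree.leaf_node_iter()]
    taxa = frozenset(taxa)
    below = _leafset_below(tree)
    out = set()
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node:
            continue
        side = below[nd] & taxa
        other = taxa - side
        if len(side) >= 2 and len(other) >= 2:
            out.add(make_split(side, other))
    return out


def clades(tree: dendropy.Tree, taxa: Iterable[str] | None = None) -> set:
    """Leaf sets of internal nodes of a rooted tree (restricted, size >= 2)."""
    if taxa is None:
        taxa = [lf.taxon.label for lf in tree.leaf_node_iter()]
    taxa = frozenset(taxa)
    below = _leafset_below(tree)
    out = set()
    for nd in tree.preorder_internal_node_iter():
        s = below[nd] & taxa
        if 2 <= len(s) < len(taxa):
            out.add(s)
    return out


def splits_compatible(s1: Split, s2: Split) -> bool:
    """Two splits on the same taxon set are compatible iff some pair of sides
    is disjoint (equivalently, not all four intersections are nonempty)."""
    a1, b1 = tuple(s1)
    a2, b2 = tuple(s2)
    for x in (a1, b1):
        for y in (a2, b2):
            if not (x & y):
                return True
    return False


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Robinson-Foulds distance on the shared taxon set."""
    s1 = frozenset(lf.taxon.label for lf in t1.leaf_node_iter())
    s2 = frozenset(lf.taxon.label for lf in t2.leaf_node_iter())
    shared = s1 & s2
    if len(shared) < 4:
        raise ValueError(f"need >= 4 shared taxa, got {len(shared)}")
    b1 = bipartitions(t1, shared)
    b2 = bipartitions(t2, shared)
    return len(b1 ^ b2)


# ---------------------------------------------------------------------------
# Distances / NJ
# ---------------------------------------------------------------------------

_NUC_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _NUC_CODE[ord(_c)] = _i
    _NUC_CODE[ord(_c.lower())] = _i


def encode_alignment(alignment: dict[str, str]) -> tuple[list[str], np.ndarray]:
    """Encode an alignment to a (taxa, uint8 matrix) pair.

    A,C,G,T -> 0..3; every other character (gap, N, ambiguity) -> 255.
    Row order is the dict insertion order.
    """
    taxa = list(alignment)
    if not taxa:
        raise ValueError("empty alignment")
    L = len(alignment[taxa[0]])
    for t in taxa:
        if len(alignment[t]) != L:
            raise ValueError("alignment is not rectangular")
    mat = np.vstack(
        [_NUC_CODE[np.frombuffer(alignment[t].encode(), dtype=np.uint8)] for t in taxa]
    )
    return taxa, mat


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with saturation flags."""

    taxa: list[str]
    values: np.ndarray
    saturated: np.ndarray = None  # bool matrix

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.saturated is None:
            self.saturated = np.zeros_like(self.values, dtype=bool)
        if self.values.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxon list")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("nonzero diagonal")

    def to_tsv(self) -> str:
        lines = ["\t".join([""] + self.taxa)]
        for i, t in enumerate(self.taxa):
            lines.append(
                "\t".join([t] + [_fmt_num(round(v, 10)) for v in self.values[i]])
            )
        return "\n".join(lines) + "\n"


def _k2p_from_counts(nvalid, ntrans, ntransv):
    with np.errstate(divide="ignore", invalid="ignore"):
        P = np.where(nvalid > 0, ntrans / np.maximum(nvalid, 1), 0.0)
        Q = np.where(nvalid > 0, ntransv / np.maximum(nvalid, 1), 0.0)
        w1 = 1.0 - 2.0 * P - Q
        w2 = 1.0 - 2.0 * Q
        sat = (w1 <= 0.0) | (w2 <= 0.0) | (nvalid == 0)
        d = np.where(sat, np.nan, -0.5 * np.log(np.where(sat, 1.0, w1) * np.sqrt(np.where(sat, 1.0, w2))))
    return d, sat


def k2p_distance_matrix(alignment: dict[str, str]) -> DistanceMatrix:
    """Kimura two-parameter distances with pairwise deletion of gap/N sites.

    d = -1/2 ln((1-2P-Q) sqrt(1-2Q)); pairs whose log argument is
    non-positive are flagged saturated (distance NaN).
    """
    taxa, mat = encode_alignment(alignment)
    n = len(taxa)
    d = np.zeros((n, n))
    sat = np.zeros((n, n), dtype=bool)
    valid = mat < 4
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            a, b = mat[i][both].astype(int), mat[j][both].astype(int)
            diff = a != b
            trans = diff & (((a - b) % 2) == 0)  # A<->G, C<->T
            transv = diff & ~trans
            dij, sij = _k2p_from_counts(
                np.array(both.sum()), np.array(trans.sum()), np.array(transv.sum())
            )
            d[i, j] = d[j, i] = float(dij)
            sat[i, j] = sat[j, i] = bool(sij)
    return DistanceMatrix(taxa, d, sat)


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining tree (unrooted); exact on additive matrices.

    Negative branch-length estimates are clamped to zero.
    """
    if dm.saturated.any():
        raise ValueError("saturated distances present; cannot build NJ tree")
    if not np.allclose(dm.values, dm.values.T):
        raise ValueError("distance matrix is not symmetric")
    if len(dm.taxa) < 3:
        raise ValueError("need >= 3 taxa")
    buf = io.StringIO()
    buf.write("," + ",".join(dm.taxa) + "\n")
    for i, t in enumerate(dm.taxa):
        buf.write(t + "," + ",".join(repr(float(v)) for v in dm.values[i]) + "\n")
    buf.seek(0)
    tns = dendropy.TaxonNamespace()
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
        src=buf, taxon_namespace=tns, delimiter=","
    )
    tree = pdm.nj_tree()
    tree.deroot()
    for nd in tree.preorder_node_iter():
        if nd.edge.length is not None and nd.edge.length < 0:
            nd.edge.length = 0.0
    tree.is_rooted = False
    return tree


def nj_k2p_tree(alignment: dict[str, str]) -> dendropy.Tree:
    """Convenience builder: NJ on K2P distances."""
    return neighbor_joining(k2p_distance_matrix(alignment))


def bootstrap_support(
    alignment: dict[str, str],
    tree_builder: Callable[[dict[str, str]], dendropy.Tree] | None = None,
    n: int = 1000,
    seed: int | None = None,
) -> dendropy.Tree:
    """Site-resampling bootstrap; support = % replicates containing each
    bipartition of the point-estimate tree.

    ``tree_builder=None`` selects the NJ(K2P) builder with a fast path that
    precomputes per-pair site categories and draws multinomial column weights.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    fast = tree_builder is None
    builder = nj_k2p_tree if fast else tree_builder
    point = builder(alignment)
    splits0 = sorted(
        bipartitions(point),
        key=lambda s: tuple(sorted(tuple(sorted(x)) for x in s)),
    )
    counts = {s: 0 for s in splits0}
    taxa = list(alignment)
    ntax = len(taxa)
    L = len(alignment[taxa[0]])
    if fast:
        _, mat = encode_alignment(alignment)
        valid = mat < 4
        pairs = [(i, j) for i in range(ntax) for j in range(i + 1, ntax)]
        both = np.array([valid[i] & valid[j] for i, j in pairs])
        diff = np.array([(mat[i] != mat[j]) for i, j in pairs]) & both
        a = mat.astype(int)
        trans = np.array([((a[i] - a[j]) % 2 == 0) for i, j in pairs]) & diff
        transv = diff & ~trans
        bothf = both.astype(np.float32)
        transf = trans.astype(np.float32)
        transvf = transv.astype(np.float32)
        for _ in range(n):
            w = rng.multinomial(L, np.full(L, 1.0 / L)).astype(np.float32)
            nv = bothf @ w
            nt = transf @ w
            nq = transvf @ w
            d, sat = _k2p_from_counts(nv, nt, nq)
            if np.any(sat) or np.any(~np.isfinite(d)):
                continue  # saturated replicate carries no countable splits
            m = np.zeros((ntax, ntax))
            for k, (i, j) in enumerate(pairs):
                m[i, j] = m[j, i] = max(d[k], 0.0)
            rep = neighbor_joining(DistanceMatrix(taxa, m))
            rep_splits = bipartitions(rep)
            for s in splits0:
                if s in rep_splits:
                    counts[s] += 1
    else:
        for _ in range(n):
            idx = rng.integers(0, L, size=L)
            raln = {t: "".join(alignment[t][i] for i in idx) for t in taxa}
            rep = builder(raln)
            rep_splits = bipartitions(rep)
            for s in splits0:
                if s in rep_splits:
                    counts[s] += 1
    out = point.clone(depth=1)
    below = _leafset_below(out)
    all_taxa = frozenset(t for t in taxa)
    for nd in out.preorder_internal_node_iter():
        if nd is out.seed_node:
            continue
        side = below[nd]
        other = all_taxa - side
        if len(side) >= 2 and len(other) >= 2:
            s = make_split(side, other)
            if s in counts:
                nd.label = str(int(round(100.0 * counts[s] / n)))
    return out


# ---------------------------------------------------------------------------
# Likelihood engine (JC / HKY branch-length fitting)
# ---------------------------------------------------------------------------


@dataclass
class HKYModel:
    """HKY85 substitution model, rate matrix normalized to one expected
    substitution per site per unit branch length."""

    kappa: float = 2.0
    freqs: Sequence[float] = field(default_factory=lambda: (0.25, 0.25, 0.25, 0.25))

    def __post_init__(self):
        f = np.asarray(self.freqs, dtype=float)
        if f.shape != (4,) or np.any(f <= 0) or abs(f.sum() - 1.0) > 1e-8:
            raise ValueError("freqs must be 4 positive values summing to 1")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        self.freqs = f
        Q = np.zeros((4, 4))
        # state order A,C,G,T; transitions: A<->G (0,2), C<->T (1,3)
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                rate = f[j]
                if (i, j) in ((0, 2), (2, 0), (1, 3), (3, 1)):
                    rate *= self.kappa
                Q[i, j] = rate
        Q[np.diag_indices(4)] = -Q.sum(axis=1)
        mu = -np.dot(f, np.diag(Q))
        Q /= mu
        # symmetric decomposition for numerical stability:
        # S = Pi^(1/2) Q Pi^(-1/2) is symmetric for reversible Q
        sq = np.sqrt(f)
        S = (Q * sq[:, None]) / sq[None, :]
        w, V = np.linalg.eigh((S + S.T) / 2.0)
        self._w = w
        self._left = V / sq[:, None]
        self._right = (V * sq[:, None]).T

    def pmat(self, t: float) -> np.ndarray:
        P = (self._left * np.exp(self._w * max(t, 0.0))) @ self._right
        P = np.clip(P, 1e-300, None)
        return P / P.sum(axis=1, keepdims=True)


JC = HKYModel(kappa=1.0)


def _compress_patterns(taxa_order: list[str], alignment: dict[str, str]):
    _, mat = encode_alignment({t: alignment[t] for t in taxa_order})
    mat = np.where(mat < 4, mat, 4)  # 4 = missing
    patt, counts = np.unique(mat, axis=1, return_counts=True)
    return patt, counts.astype(float)


_EYE5 = np.vstack([np.eye(4), np.ones(4)])  # row 4 = missing datum


def _tree_lnl(tree, model: HKYModel, counts, leaf_partials):
    partial = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            partial[nd] = leaf_partials[nd.taxon.label]
        else:
            p = None
            for ch in nd.child_nodes():
                P = model.pmat(ch.edge.length or 0.0)
                q = partial[ch] @ P.T
                p = q if p is None else p * q
            partial[nd] = p
    site = partial[tree.seed_node] @ model.freqs
    return float(np.sum(counts * np.log(np.maximum(site, 1e-300))))


def fit_branch_lengths(
    topology: dendropy.Tree,
    alignment: dict[str, str],
    model: HKYModel | str = "JC",
    tol: float = 1e-6,
    max_passes: int = 50,
    xatol: float = 1e-10,
) -> tuple[dendropy.Tree, float]:
    """Optimize branch lengths on a fixed topology by coordinate ascent under
    the pruning-algorithm likelihood; returns (tree, total lnL)."""
    if isinstance(model, str):
        if model.upper() == "JC":
            model = JC
        else:
            raise ValueError(f"unknown model {model!r}")
    tree = topology.clone(depth=1)
    tree_taxa = [lf.taxon.label for lf in tree.leaf_node_iter()]
    missing = [t for t in tree_taxa if t not in alignment]
    if missing:
        raise ValueError(f"taxa absent from alignment: {missing}")
    patt, counts = _compress_patterns(tree_taxa, alignment)
    leaf_partials = {t: _EYE5[patt[i]] for i, t in enumerate(tree_taxa)}
    lnl = _fit_core(tree, model, counts, leaf_partials, tol, max_passes, xatol)
    return tree, lnl


def _fit_core(tree, model, counts, leaf_partials, tol, max_passes, xatol):
    """Coordinate-ascent branch-length optimization in place; returns lnL."""
    edges = [nd for nd in tree.preorder_node_iter() if nd is not tree.seed_node]
    for nd in edges:
        if nd.edge.length is None or nd.edge.length < 0:
            nd.edge.length = 0.1
    lnl = _tree_lnl(tree, model, counts, leaf_partials)
    for _ in range(max_passes):
        for nd in edges:
            def neg(b, node=nd):
                node.edge.length = b
                return -_tree_lnl(tree, model, counts, leaf_partials)

            res = minimize_scalar(
                neg, bounds=(0.0, 20.0), method="bounded",
                options={"xatol": xatol},
            )
            nd.edge.length = float(res.x)
        new_lnl = _tree_lnl(tree, model, counts, leaf_partials)
        if new_lnl - lnl < tol:
            lnl = new_lnl
            break
        lnl = new_lnl
    return lnl
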