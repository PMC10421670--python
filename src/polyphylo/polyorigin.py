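"""Parentage inference for allopolyploids from best-hit counting.

Strategy: every polyploid CDS is scored against all diploid sequences of
its orthogroup with a deterministic global-alignment similarity score; the
diploid with the best hit is credited (exact cross-diploid ties credit
nobody).  Aggregated counts concentrate on the lineages closest to the two
progenitors, so the parent pair is read off as the top diploid plus the top
diploid outside its local clade.  The plastid tree (maternal inheritance)
orients the pair; a plastid sister outside the pair is flagged as organelle
capture.  Sequences are then classified maternal/paternal/ambiguous and the
classified pseudo-taxa (``P#maternal``, ``P#paternal``) are placed in a
bootstrap NJ phylogeny alongside the diploids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from Bio import Align

from . import treekit
from .orthodata import OrthogroupTable, concatenate
from .treekit import _leafset_below

__all__ = [
    "similarity_score",
    "BestHit",
    "BestHitMatrix",
    "best_hit_counts",
    "ParentHypothesis",
    "infer_parent_pair",
    "orient_parents",
    "SubgenomeAssignment",
    "assign_subgenomes",
    "build_subgenome_tree",
]

MATERNAL = "maternal"
PATERNAL = "paternal"
AMBIGUOUS = "ambiguous"


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = 1.0
    al.mismatch_score = -1.0
    al.open_gap_score = -2.0
    al.extend_gap_score = -0.5
    return al


_ALIGNER = _aligner()


def similarity_score(a, b) -> float:
    """Deterministic global-alignment similarity (match +1, mismatch -1, gap
    open -2, extend -0.5).  Accepts SequenceRecord or plain strings; gap
    characters are stripped before aligning.  Symmetric in its arguments."""
    sa = (a if isinstance(a, str) else a.residues).replace("-", "")
    sb = (b if isinstance(b, str) else b.residues).replace("-", "")
    if not sa or not sb:
        raise ValueError("cannot score an empty sequence")
    return float(_ALIGNER.score(sa, sb))


@dataclass(frozen=True)
class BestHit:
    og_id: str
    seq_id: str
    polyploid: str
    best_taxon: str | None  # None = tie across diploids
    score: float
    margin: float  # best minus runner-up score (0 for ties)


@dataclass
class BestHitMatrix:
    """Polyploid x diploid best-hit count matrix plus per-sequence detail."""

    counts: pd.DataFrame  # rows polyploids, columns diploids
    ties: dict[str, int]
    unscored: dict[str, int]  # sequences in orthogroups lacking diploids
    skipped_orthogroups: int
    details: list[BestHit] = field(default_factory=list)

    def total_scored(self, polyploid: str) -> int:
        return int(self.counts.loc[polyploid].sum()) + self.ties[polyploid]

    def to_tsv(self) -> str:
        return self.counts.to_csv(sep="\t")


def best_hit_counts(table: OrthogroupTable) -> BestHitMatrix:
    """Count, per polyploid, the diploid holding the best hit of each of its
    sequences within the same orthogroup."""
    diploids = table.diploid_taxa
    polyploids = table.polyploid_taxa
    if not polyploids or len(diploids) < 2:
        raise ValueError("need >= 1 polyploid and >= 2 diploid taxa")
    counts = pd.DataFrame(
        0, index=polyploids, columns=diploids, dtype=int
    )
    ties = {p: 0 for p in polyploids}
    unscored = {p: 0 for p in polyploids}
    details: list[BestHit] = []
    skipped = 0
    for og_id in table.og_ids:
        group = table.groups[og_id]
        dip_seqs = [
            (taxon, rec)
            for taxon in diploids
            for rec in group.get(taxon, ())
        ]
        has_poly = any(group.get(p) for p in polyploids)
        if not dip_seqs:
            if has_poly:
                skipped += 1
                for p in polyploids:
                    unscored[p] += len(group.get(p, ()))
            continue
        for p in polyploids:
            for rec in group.get(p, ()):
                scored = [
                    (similarity_score(rec, drec), taxon)
                    for taxon, drec in dip_seqs
                ]
                best = max(s for s, _ in scored)
                best_taxa = sorted({t for s, t in scored if s == best})
                others = [s for s, _ in scored if s < best]
                margin = best - max(others) if others else 0.0
                if len(best_taxa) == 1:
                    counts.loc[p, best_taxa[0]] += 1
                    details.append(
                        BestHit(og_id, rec.seq_id, p, best_taxa[0], best, margin)
                    )
                else:
                    ties[p] += 1
                    details.append(BestHit(og_id, rec.seq_id, p, None, best, 0.0))
    return BestHitMatrix(
        counts=counts,
        ties=ties,
        unscored=unscored,
        skipped_orthogroups=skipped,
        details=details,
    )


# ---------------------------------------------------------------------------
# Parent-pair hypothesis
# ---------------------------------------------------------------------------


@dataclass
class ParentHypothesis:
    """Putative progenitor pair for one polyploid.

    ``maternal``/``paternal`` are sets of diploid taxa (singleton for a
    species-level parent, larger for a clade-level/ancestral parent).  Until
    orientation, the pair is stored as (first, second) by best-hit mass.
    """

    polyploid: str
    first: frozenset
    second: frozenset
    first_count: int = 0
    second_count: int = 0
    margin: int = 0  # first_count - second_count
    oriented: bool = False
    maternal: frozenset | None = None
    paternal: frozenset | None = None
    plastid_sister: frozenset | None = None
    capture_flag: bool = False  # plastid sister outside both parents
    single_parent_like: bool = False

    def pair(self) -> tuple[frozenset, frozenset]:
        return self.first, self.second


def _clade_of(tree_below, taxon: str, min_size: int = 2) -> frozenset:
    """Smallest clade containing ``taxon`` with >= min_size members."""
    best = None
    for s in tree_below.values():
        if taxon in s and len(s) >= min_size:
            if best is None or len(s) < len(best):
                best = s
    return frozenset(best) if best else frozenset({taxon})


def infer_parent_pair(
    counts_row: pd.Series,
    diploid_species_tree: dendropy.Tree,
    clade_radius: int = 2,
    single_parent_frac: float = 0.05,
) -> ParentHypothesis:
    """Unoriented parent pair from a best-hit count row.

    First candidate = argmax diploid; second = argmax over diploids outside
    the first's local clade (smallest clade of >= ``clade_radius`` taxa
    containing it, i.e. its sister-pair clade by default).  If every other
    diploid's count is <= ``single_parent_frac`` of the maximum the
    hypothesis is flagged autopolyploid-like.
    """
    counts_row = counts_row.astype(int)
    if counts_row.sum() == 0:
        raise ValueError("all-zero best-hit row")
    if counts_row.nunique() == 1:
        raise ValueError(
            "all best-hit counts equal; parent pair is ambiguous - manual "
            "review required"
        )
    below = {
        nd: frozenset(s)
        for nd, s in _leafset_below(diploid_species_tree).items()
    }
    order = sorted(counts_row.index)
    first = max(order, key=lambda t: (counts_row[t], t))
    first_clade = _clade_of(below, first, clade_radius)
    outside = [t for t in order if t not in first_clade and t in counts_row.index]
    if not outside:
        raise ValueError("no diploids outside the first parent's clade")
    second = max(outside, key=lambda t: (counts_row[t], t))
    others = counts_row.drop(first)
    single_like = bool((others <= single_parent_frac * counts_row[first]).all())
    return ParentHypothesis(
        polyploid=str(counts_row.name) if counts_row.name else "",
        first=frozenset({first}),
        second=frozenset({second}),
        first_count=int(counts_row[first]),
        second_count=int(counts_row[second]),
        margin=int(counts_row[first] - counts_row[second]),
        single_parent_like=single_like,
    )


def orient_parents(
    hypothesis: ParentHypothesis,
    plastid_tree: dendropy.Tree,
    polyploid: str | None = None,
) -> ParentHypothesis:
    """Assign maternal/paternal orientation from the (maternally inherited)
    plastid tree.

    The maternal parent is the pair member whose taxa contain, or are
    contained in, the polyploid's sister group in the plastid tree.  If
    neither member qualifies the orientation is left undetermined and the
    observed plastid sister is reported (organelle-capture flag).
    """
    poly = polyploid or hypothesis.polyploid
    tips = {lf.taxon.label for lf in plastid_tree.leaf_node_iter()}
    if poly not in tips:
        raise ValueError(f"polyploid {poly!r} absent from plastid tree")
    sister = _plastid_sister(plastid_tree, poly)
    hypothesis.plastid_sister = sister

    def qualifies(member: frozenset) -> bool:
        return bool(sister and (sister <= member or member <= sister))

    q1, q2 = qualifies(hypothesis.first), qualifies(hypothesis.second)
    if q1 == q2:  # both or neither: undetermined
        hypothesis.oriented = False
        hypothesis.capture_flag = not q1
        hypothesis.maternal = hypothesis.paternal = None
    else:
        hypothesis.oriented = True
        hypothesis.capture_flag = False
        if q1:
            hypothesis.maternal, hypothesis.paternal = (
                hypothesis.first,
                hypothesis.second,
            )
        else:
            hypothesis.maternal, hypothesis.paternal = (
                hypothesis.second,
                hypothesis.first,
            )
    return hypothesis


def _plastid_sister(tree: dendropy.Tree, taxon: str) -> frozenset:
    below = _leafset_below(tree)
    leaf = next(
        lf for lf in tree.leaf_node_iter() if lf.taxon.label == taxon
    )
    nd = leaf.parent_node
    while nd is not None:
        s = below[nd] - {taxon}
        if s:
            return frozenset(s)
        nd = nd.parent_node
    return frozenset()


# ---------------------------------------------------------------------------
# Subgenome assignment
# ---------------------------------------------------------------------------


@dataclass
class SubgenomeAssignment:
    """Per-sequence maternal/paternal/ambiguous labels for one polyploid."""

    polyploid: str
    labels: dict[str, str]  # seq_id -> label
    best_hits: dict[str, str | None]
    margins: dict[str, float]
    by_orthogroup: dict[str, dict[str, str]]  # og_id -> seq_id -> label

    def count(self, label: str) -> int:
        return sum(1 for v in self.labels.values() if v == label)

    def to_tsv(self) -> str:
        lines = ["og_id\tseq_id\tlabel\tbest_hit\tmargin"]
        for og_id in sorted(self.by_orthogroup):
            for seq_id in sorted(self.by_orthogroup[og_id]):
                lines.append(
                    "\t".join(
                        [
                            og_id,
                            seq_id,
                            self.labels[seq_id],
                            self.best_hits[seq_id] or "-",
                            f"{self.margins[seq_id]:g}",
                        ]
                    )
                )
        return "\n".join(lines) + "\n"


def assign_subgenomes(
    table: OrthogroupTable,
    hypothesis: ParentHypothesis,
    best_hits: BestHitMatrix | None = None,
    maternal_clade: frozenset | None = None,
    paternal_clade: frozenset | None = None,
) -> SubgenomeAssignment:
    """Label each sequence of the hypothesis' polyploid maternal, paternal
    or ambiguous by the lineage of its best-hit diploid.

    Clade overrides widen a parent to a set of diploids (counts pooled).
    Within an orthogroup, if two copies map to the same lineage only the
    higher-scoring one keeps the label (the other becomes ambiguous);
    ambiguous sequences are discarded downstream.
    """
    if not hypothesis.oriented:
        raise ValueError(
            "hypothesis must be oriented (or overridden) before assignment"
        )
    poly = hypothesis.polyploid
    mat = frozenset(maternal_clade or hypothesis.maternal)
    pat = frozenset(paternal_clade or hypothesis.paternal)
    if mat & pat:
        raise ValueError("maternal and paternal clades overlap")
    if best_hits is None:
        best_hits = best_hit_counts(table)
    labels: dict[str, str] = {}
    hit_of: dict[str, str | None] = {}
    margin_of: dict[str, float] = {}
    score_of: dict[str, float] = {}
    by_og: dict[str, dict[str, str]] = {}
    for bh in best_hits.details:
        if bh.polyploid != poly:
            continue
        if bh.best_taxon in mat:
            lab = MATERNAL
        elif bh.best_taxon in pat:
            lab = PATERNAL
        else:
            lab = AMBIGUOUS
        labels[bh.seq_id] = lab
        hit_of[bh.seq_id] = bh.best_taxon
        margin_of[bh.seq_id] = bh.margin
        score_of[bh.seq_id] = bh.score
        by_og.setdefault(bh.og_id, {})[bh.seq_id] = lab
    # demote same-lineage doubletons: keep the higher-scoring copy
    for og_id, seqs in by_og.items():
        for lab in (MATERNAL, PATERNAL):
            same = [s for s, l in seqs.items() if l == lab]
            if len(same) > 1:
                same.sort(key=lambda s: (-score_of[s], s))
                for s in same[1:]:
                    seqs[s] = AMBIGUOUS
                    labels[s] = AMBIGUOUS
    return SubgenomeAssignment(
        polyploid=poly,
        labels=labels,
        best_hits=hit_of,
        margins=margin_of,
        by_orthogroup=by_og,
    )


# ---------------------------------------------------------------------------
# Subgenome phylogeny
# ---------------------------------------------------------------------------


def build_subgenome_tree(
    table: OrthogroupTable,
    assignments: list[SubgenomeAssignment],
    diploids: list[str] | None = None,
    min_loci: int = 10,
    bootstrap: int = 1000,
    seed: int | None = None,
) -> tuple[dendropy.Tree, list[str]]:
    """Bootstrap NJ(K2P) phylogeny of diploids plus classified subgenome
    pseudo-taxa (``P#maternal`` / ``P#paternal``).

    Pseudo-taxa with fewer than ``min_loci`` classified loci are excluded
    (returned in the warnings list).  Returns (tree with % support,
    warnings).
    """
    if diploids is None:
        diploids = table.diploid_taxa
    loci: dict[str, dict[str, str]] = {}
    for og_id in table.og_ids:
        aln = {}
        for taxon in diploids:
            recs = table.groups[og_id].get(taxon, ())
            if len(recs) == 1:
                aln[taxon] = recs[0].residues
        loci[og_id] = aln
    pseudo_counts: dict[str, int] = {}
    for asn in assignments:
        rec_by_id = {
            rec.seq_id: rec
            for og_id in table.og_ids
            for rec in table.groups[og_id].get(asn.polyploid, ())
        }
        for og_id, seqs in asn.by_orthogroup.items():
            for seq_id, lab in seqs.items():
                if lab == AMBIGUOUS:
                    continue
                pseudo = f"{asn.polyploid}#{lab}"
                if pseudo in loci[og_id]:
                    continue  # one classified copy per locus
                loci[og_id][pseudo] = rec_by_id[seq_id].residues
                pseudo_counts[pseudo] = pseudo_counts.get(pseudo, 0) + 1
    warnings = []
    drop = set()
    for asn in assignments:
        for lab in (MATERNAL, PATERNAL):
            pseudo = f"{asn.polyploid}#{lab}"
            n = pseudo_counts.get(pseudo, 0)
            if n < min_loci:
                warnings.append(
                    f"pseudo-taxon {pseudo} has {n} classified loci "
                    f"(< {min_loci}); excluded"
                )
                drop.add(pseudo)
    if pseudo_counts and set(pseudo_counts) <= drop and any(
        a.labels for a in assignments
    ):
        pass  # plain diploid tree still returned
    if assignments and not pseudo_counts:
        raise ValueError("assignments contain no classified (non-ambiguous) sequences")
    rows = [t for t in diploids] + sorted(set(pseudo_counts) - drop)
    loci = {
        og: {t: s for t, s in aln.items() if t in rows}
        for og, aln in loci.items()
    }
    sm = concatenate(loci, rows)
    tree = treekit.bootstrap_support(sm.rows, n=bootstrap, seed=seed)
    return tree, warnings
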