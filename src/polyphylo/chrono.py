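"""Strict-clock dating by constrained least squares, and per-subgenome
hybridization dates.

Given a rooted tree with branch lengths in substitutions/site and one
secondary calibration (a node age in Ma), node heights x_v (in substitution
units) are fitted to minimize the sum over branches of
``(observed length - (x_parent - x_child))^2`` subject to tips at 0 and
parent >= child; the clock rate is then r = x_cal / age_cal and ages are
x / r.  On exactly clocklike input the fit is exact (RSS 0) and the result
is plain proportional scaling.  The hybridization date of a subgenome is
the age of the MRCA of its pseudo-taxon and its extant parent lineage - an
upper bound on the hybridization time, because the parent sampled today
diverged from the true donor population no later than the hybridization.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.optimize import lsq_linear, minimize

from . import treekit
from .treekit import _leafset_below

__all__ = [
    "Chronogram",
    "strict_clock_chronogram",
    "HybridizationDate",
    "hybridization_dates",
]


@dataclass
class Chronogram:
    """Ultrametric tree with node ages in Ma, fitted clock rate and RSS."""

    tree: dendropy.Tree  # branch lengths = age differences (Ma)
    ages: dict  # node -> age (Ma)
    rate: float  # substitutions/site/Ma
    calibration_clade: frozenset
    calibration_age: float
    rss: float

    def age_of(self, taxa) -> float:
        """Age of the MRCA of a set of tip labels."""
        taxa = frozenset(taxa) if not isinstance(taxa, str) else frozenset({taxa})
        below = _leafset_below(self.tree)
        best = None
        for nd, s in below.items():
            if taxa <= s and (best is None or len(s) < len(below[best])):
                best = nd
        if best is None:
            raise ValueError(f"taxa {sorted(taxa)} not in chronogram")
        return self.ages[best]

    def node_age_table(self) -> str:
        below = _leafset_below(self.tree)
        lines = ["clade\tage_ma"]
        for nd in self.tree.preorder_internal_node_iter():
            lines.append(
                "+".join(sorted(below[nd])) + f"\t{self.ages[nd]:.6f}"
            )
        return "\n".join(lines) + "\n"


def strict_clock_chronogram(
    rooted_tree: dendropy.Tree,
    calibration_taxa,
    calibration_age: float,
) -> Chronogram:
    """Date a rooted tree under a strict clock with one fixed node age.

    ``calibration_taxa`` identifies the calibrated node as the MRCA of the
    given tip labels (use all tips to calibrate the root).  Raises if the
    calibration falls on a tip or the tree has zero total length.
    """
    if calibration_age <= 0:
        raise ValueError("calibration age must be positive")
    tree = rooted_tree.clone(depth=1)
    nodes = list(tree.preorder_node_iter())
    total_len = sum(nd.edge.length or 0.0 for nd in nodes if nd.parent_node)
    if total_len <= 0:
        raise ValueError("zero total tree length; clock rate undefined")
    internal = [nd for nd in nodes if not nd.is_leaf()]
    index = {id(nd): i for i, nd in enumerate(internal)}
    below = _leafset_below(tree)
    cal_taxa = frozenset(calibration_taxa)
    cal_node = None
    for nd in internal:
        if below[nd] == (below[nd] | cal_taxa) and cal_taxa <= below[nd]:
            if cal_node is None or len(below[nd]) < len(below[cal_node]):
                cal_node = nd
    if len(cal_taxa) == 1:
        raise ValueError("calibration cannot be placed on a tip")
    if cal_node is None or not cal_taxa <= below[cal_node]:
        raise ValueError("calibration taxa not found in tree")

    # least squares for x (heights in substitution units) over internal nodes
    n = len(internal)
    rows_A, rhs = [], []
    constraints = []  # (parent index, child index) meaning x_p >= x_c
    root = tree.seed_node
    root_kids = root.child_nodes()
    merge_root_edges = len(root_kids) == 2
    for nd in nodes:
        if nd.parent_node is None:
            continue
        if merge_root_edges and nd.parent_node is root:
            # the two root-child branches are one unrooted edge whose split
            # by the rooting is arbitrary; only their sum is an observation
            if nd is root_kids[0]:
                b = sum(k.edge.length or 0.0 for k in root_kids)
                row = np.zeros(n)
                row[index[id(root)]] = 2.0
                for k in root_kids:
                    if not k.is_leaf():
                        row[index[id(k)]] -= 1.0
                rows_A.append(row)
                rhs.append(b)
            for k in (nd,):
                if not k.is_leaf():
                    constraints.append((index[id(root)], index[id(k)]))
            continue
        b = nd.edge.length or 0.0
        row = np.zeros(n)
        row[index[id(nd.parent_node)]] = 1.0
        if not nd.is_leaf():
            row[index[id(nd)]] = -1.0
            constraints.append((index[id(nd.parent_node)], index[id(nd)]))
        rows_A.append(row)
        rhs.append(b)
    A = np.vstack(rows_A)
    b = np.asarray(rhs)
    res = lsq_linear(A, b, bounds=(0.0, np.inf))
    x = res.x
    # enforce parent >= child ordering if the box-constrained solution
    # violates it (rare: strongly anticlocklike inputs)
    if any(x[p] < x[c] - 1e-12 for p, c in constraints):
        cons = [
            {
                "type": "ineq",
                "fun": (lambda v, p=p, c=c: v[p] - v[c]),
            }
            for p, c in constraints
        ] + [{"type": "ineq", "fun": lambda v: v}]
        opt = minimize(
            lambda v: float(np.sum((A @ v - b) ** 2)),
            x0=np.maximum(x, 0.0),
            jac=lambda v: 2.0 * A.T @ (A @ v - b),
            constraints=cons,
            method="SLSQP",
            options={"maxiter": 500, "ftol": 1e-14},
        )
        x = opt.x
        for p, c in constraints:  # numerical cleanup
            if x[p] < x[c]:
                x[p] = x[c]
    rss = float(np.sum((A @ x - b) ** 2))
    x_cal = x[index[id(cal_node)]]
    if x_cal <= 0:
        raise ValueError(
            "calibration node has zero height; rate undefined"
        )
    rate = x_cal / calibration_age
    ages = {}
    for nd in nodes:
        ages[nd] = 0.0 if nd.is_leaf() else float(x[index[id(nd)]] / rate)
    ages[cal_node] = float(calibration_age)  # exact by construction
    for nd in nodes:
        if nd.parent_node is not None:
            nd.edge.length = max(ages[nd.parent_node] - ages[nd], 0.0)
    return Chronogram(
        tree=tree,
        ages=ages,
        rate=rate,
        calibration_clade=frozenset(below[cal_node]),
        calibration_age=float(calibration_age),
        rss=rss,
    )


@dataclass(frozen=True)
class HybridizationDate:
    polyploid: str
    subgenome: str  # "maternal" | "paternal"
    parent: frozenset
    age_ma: float
    lo: float | None = None
    hi: float | None = None

    def row(self) -> str:
        return "\t".join(
            [
                self.polyploid,
                self.subgenome,
                "+".join(sorted(self.parent)),
                f"{self.age_ma:.6f}",
                "-" if self.lo is None else f"{self.lo:.6f}",
                "-" if self.hi is None else f"{self.hi:.6f}",
            ]
        )


def hybridization_dates(
    chronogram: Chronogram,
    hypotheses,
) -> list[HybridizationDate]:
    """Per-subgenome hybridization dates: the age of MRCA(pseudo-taxon,
    parent lineage) for each oriented parent hypothesis.

    ``hypotheses`` is an iterable of objects with ``polyploid``, ``maternal``
    and ``paternal`` attributes (sets of diploid taxa).  Maternal and
    paternal dates are independent numbers: the two parents were sampled in
    extant relatives that diverged from the actual donors at different
    times.
    """
    tips = {lf.taxon.label for lf in chronogram.tree.leaf_node_iter()}
    out = []
    for hyp in hypotheses:
        for sub in ("maternal", "paternal"):
            parent = getattr(hyp, sub)
            if parent is None:
                continue
            parent = frozenset(parent)
            pseudo = f"{hyp.polyploid}#{sub}"
            if pseudo not in tips:
                raise ValueError(f"pseudo-taxon {pseudo!r} absent from chronogram")
            missing = parent - tips
            if missing:
                raise ValueError(
                    f"parent taxa {sorted(missing)} absent from chronogram"
                )
            age = chronogram.age_of(parent | {pseudo})
            out.append(
                HybridizationDate(
                    polyploid=hyp.polyploid,
                    subgenome=sub,
                    parent=parent,
                    age_ma=age,
                )
            )
    return out


def dates_report(dates) -> str:
    header = "polyploid\tsubgenome\tparent\tage_ma\tlo\thi"
    return "\n".join([header] + [d.row() for d in dates]) + "\n"
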