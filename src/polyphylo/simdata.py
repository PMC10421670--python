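"""Coalescent simulation of multilocus allopolyploid transcriptome datasets.

The generative model is a multispecies coalescent on a time-calibrated,
rooted species tree (ages in Ma) carrying allopolyploid hybrid events: each
allotetraploid contributes two homeologous haplotypes per nuclear locus, one
entering its maternal parent branch and one its paternal parent branch at
the hybridization time T_h.  Within every branch, lineages coalesce at rate
``pairs / g`` where ``g`` is the expected within-lineage pairwise
coalescence time (Ma).  Sequences then evolve along each gene tree under a
strict clock (rate ``r`` substitutions/site/Ma) with an HKY(kappa, pi)
substitution model and optional gamma rate heterogeneity across sites.  A
single maternally inherited plastid locus is simulated with a halved
coalescent intensity (organellar effective size); an explicit
``plastid_donor`` on an event emulates organelle capture (plastid lineage
from a non-parent).

The coalescent engine is msprime (one population per species-tree branch,
``ploidy=1`` with ``population_size=g`` so the expected pairwise coalescence
time within a branch is exactly ``g``).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import dendropy
import msprime
import numpy as np

from . import treekit
from .orthodata import OrthogroupTable, SequenceRecord, TaxonInfo, write_fasta, write_metadata

__all__ = [
    "HybridEvent",
    "SpeciesNetworkModel",
    "SimulationConfig",
    "TruthRecord",
    "build_network",
    "preset_spec",
    "load_preset",
    "PRESETS",
    "simulate_gene_trees",
    "simulate_triplet_counts",
    "evolve_alignment",
    "emit_dataset",
]


# ---------------------------------------------------------------------------
# Network model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HybridEvent:
    """One allopolyploid origin: polyploid taxon, parent branches (taxon name
    or 'A+B' for the branch subtending MRCA(A,B)), hybridization time (Ma),
    inheritance probability gamma (provenance only), and the branch donating
    the plastid (defaults to the maternal branch; differing from it encodes
    organelle capture)."""

    polyploid: str
    maternal: str
    paternal: str
    t_h: float
    gamma: float = 0.5
    plastid_donor: str | None = None

    @property
    def effective_plastid_donor(self) -> str:
        return self.plastid_donor if self.plastid_donor is not None else self.maternal


class SpeciesNetworkModel:
    """Time-calibrated species tree plus allopolyploid hybrid events."""

    def __init__(
        self,
        backbone: dendropy.Tree,
        taxa: Sequence[TaxonInfo],
        events: Sequence[HybridEvent] = (),
    ):
        self.backbone = backbone
        self.taxa = list(taxa)
        self.events = list(events)
        self.metadata = {t.name: t for t in self.taxa}
        self._ages = self._compute_ages()
        self._validate()

    # -- derived ----------------------------------------------------------
    def _compute_ages(self) -> dict:
        depth = {}
        for nd in self.backbone.preorder_node_iter():
            if nd.parent_node is None:
                depth[nd] = 0.0
            else:
                if nd.edge.length is None or nd.edge.length < 0:
                    raise ValueError("backbone branches need nonnegative lengths")
                depth[nd] = depth[nd.parent_node] + nd.edge.length
        leaf_depths = [depth[lf] for lf in self.backbone.leaf_node_iter()]
        height = max(leaf_depths)
        if max(leaf_depths) - min(leaf_depths) > 1e-6 * max(height, 1.0):
            raise ValueError("backbone must be ultrametric (tip ages 0)")
        return {nd: height - depth[nd] for nd in depth}

    def age(self, node) -> float:
        return self._ages[node]

    @property
    def root_age(self) -> float:
        return self._ages[self.backbone.seed_node]

    @property
    def backbone_taxa(self) -> list[str]:
        return sorted(lf.taxon.label for lf in self.backbone.leaf_node_iter())

    @property
    def diploids(self) -> list[str]:
        return [t.name for t in self.taxa if t.ploidy == "diploid"]

    @property
    def polyploids(self) -> list[str]:
        return [t.name for t in self.taxa if t.ploidy == "tetraploid"]

    @property
    def outgroups(self) -> list[str]:
        return [t.name for t in self.taxa if t.outgroup]

    def resolve_branch(self, spec: str):
        """Backbone node whose subtending branch a spec like 'A' or 'A+B'
        names (MRCA for multi-taxon specs)."""
        names = spec.split("+")
        leaves = {lf.taxon.label: lf for lf in self.backbone.leaf_node_iter()}
        for n in names:
            if n not in leaves:
                raise ValueError(f"unknown taxon {n!r} in branch spec {spec!r}")
        if len(names) == 1:
            return leaves[names[0]]
        node = self.backbone.mrca(taxa=[leaves[n].taxon for n in names])
        return node

    # -- validation -------------------------------------------------------
    def _validate(self):
        backbone_set = set(self.backbone_taxa)
        meta_names = set(self.metadata)
        if len(self.metadata) != len(self.taxa):
            raise ValueError("duplicate taxon names in metadata")
        poly = set(self.polyploids)
        if backbone_set - meta_names:
            raise ValueError(
                f"backbone taxa missing metadata: {sorted(backbone_set - meta_names)}"
            )
        if (meta_names - poly) != backbone_set:
            raise ValueError(
                "every non-polyploid taxon must be a backbone tip and vice versa"
            )
        seen = set()
        for ev in self.events:
            if ev.polyploid not in poly:
                raise ValueError(f"event polyploid {ev.polyploid!r} not a tetraploid taxon")
            if ev.polyploid in seen:
                raise ValueError(f"polyploid {ev.polyploid!r} has multiple events")
            seen.add(ev.polyploid)
            if not (0.0 < ev.gamma < 1.0):
                raise ValueError("gamma must lie in (0, 1)")
            if ev.t_h <= 0:
                raise ValueError("hybridization time must be positive")
            if ev.maternal == ev.paternal:
                raise ValueError("maternal and paternal branches must differ")
            for spec in {ev.maternal, ev.paternal, ev.effective_plastid_donor}:
                node = self.resolve_branch(spec)
                lo = self.age(node)
                parent = node.parent_node
                hi = self.age(parent) if parent is not None else math.inf
                if not (lo <= ev.t_h < hi):
                    raise ValueError(
                        f"event time {ev.t_h} Ma for {ev.polyploid!r} lies outside "
                        f"branch {spec!r} (exists {lo:g}-{hi:g} Ma); it must be "
                        "younger than the parents' divergence"
                    )
        if poly - seen:
            raise ValueError(
                f"polyploid taxa without a hybrid event: {sorted(poly - seen)}"
            )


# ---------------------------------------------------------------------------
# Network spec parsing and presets
# ---------------------------------------------------------------------------


def build_network(spec_text: str) -> SpeciesNetworkModel:
    """Parse a network spec: key=value lines (``backbone`` newick,
    ``outgroups`` comma list) plus an ``[events]`` TSV block with columns
    polyploid, maternal, paternal, t_h, gamma [, plastid_donor]."""
    backbone_nwk = None
    outgroups: set[str] = set()
    events: list[HybridEvent] = []
    lines = spec_text.splitlines()
    in_events = False
    header: list[str] | None = None
    for raw in lines:
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.lower() == "[events]":
            in_events = True
            continue
        if not in_events:
            if "=" not in line:
                raise ValueError(f"cannot parse spec line {line!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            if key == "backbone":
                backbone_nwk = val
            elif key == "outgroups":
                outgroups = {s.strip() for s in val.split(",") if s.strip()}
            else:
                raise ValueError(f"unknown spec key {key!r}")
        else:
            cols = line.split("\t") if "\t" in line else line.split()
            if header is None:
                header = cols
                continue
            row = dict(zip(header, cols))
            events.append(
                HybridEvent(
                    polyploid=row["polyploid"],
                    maternal=row["maternal"],
                    paternal=row["paternal"],
                    t_h=float(row["t_h"]),
                    gamma=float(row.get("gamma", 0.5)),
                    plastid_donor=row.get("plastid_donor") or None,
                )
            )
    if backbone_nwk is None:
        raise ValueError("spec lacks a 'backbone' newick line")
    backbone = treekit.read_newick(backbone_nwk)
    backbone.is_rooted = True
    tips = sorted(lf.taxon.label for lf in backbone.leaf_node_iter())
    taxa = [TaxonInfo(t, "diploid", outgroup=(t in outgroups)) for t in tips]
    taxa += [TaxonInfo(ev.polyploid, "tetraploid") for ev in events]
    return SpeciesNetworkModel(backbone, taxa, events)


_NICOTIANA_BACKBONE = (
    "((((obtusifolia:6.5,tomentosiformis:6.5):1.0,"
    "(undulata:6.0,(paniculata:2.5,knightiana:2.5):3.5):1.5):1.74,"
    "(sylvestris:8.0,(attenuata:5.5,glauca:5.5):2.5):1.24):21.16,"
    "axillaris:30.4);"
)

PRESETS: dict[str, str] = {
    # two-tetraploid network echoing the study system: a young tetraploid
    # (sylvestris x tomentosiformis) and an older one (attenuata x undulata)
    "nicotiana-like": f"""\
backbone = {_NICOTIANA_BACKBONE}
outgroups = axillaris
[events]
polyploid\tmaternal\tpaternal\tt_h\tgamma
tabacum\tsylvestris\ttomentosiformis\t0.5\t0.5
clevelandii\tattenuata\tundulata\t3.7\t0.5
""",
    # single tetraploid from the western-North-America-like section
    "polydicliae-like": """\
backbone = (((attenuata:5.5,glauca:5.5):3.74,(undulata:6.0,paniculata:6.0):3.24):21.16,axillaris:30.4);
outgroups = axillaris
[events]
polyploid\tmaternal\tpaternal\tt_h\tgamma
clevelandii\tattenuata\tundulata\t3.7\t0.5
""",
    # maternal parent is an ancestral (clade-level) lineage
    "rusticae-like": """\
backbone = (((paniculata:1.2,knightiana:1.2):4.8,undulata:6.0):24.4,axillaris:30.4);
outgroups = axillaris
[events]
polyploid\tmaternal\tpaternal\tt_h\tgamma
rustica\tpaniculata+knightiana\tundulata\t1.52\t0.59
""",
    # plastid donated by a lineage that is neither nuclear parent
    "organelle-capture": """\
backbone = (((attenuata:5.5,glauca:5.5):3.74,(undulata:6.0,paniculata:6.0):3.24):21.16,axillaris:30.4);
outgroups = axillaris
[events]
polyploid\tmaternal\tpaternal\tt_h\tgamma\tplastid_donor
clevelandii\tattenuata\tundulata\t3.7\t0.5\tglauca
""",
}


def preset_spec(name: str) -> str:
    try:
        return PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; have {sorted(PRESETS)}") from None


def load_preset(name: str) -> SpeciesNetworkModel:
    return build_network(preset_spec(name))


# ---------------------------------------------------------------------------
# Simulation configuration
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Knobs of the generative model.

    g is the expected within-lineage pairwise coalescence time in Ma (larger
    g = more incomplete lineage sorting); clock_rate is substitutions per
    site per Ma; gamma_shape=None disables among-site rate heterogeneity
    (the alpha -> infinity limit).
    """

    n_loci: int = 100
    locus_length: int = 500
    g: float = 0.5
    clock_rate: float = 0.005
    kappa: float = 2.0
    base_freqs: tuple = (0.25, 0.25, 0.25, 0.25)
    gamma_shape: float | None = None
    loss_prob: float = 0.0
    dup_prob: float = 0.0
    plastid_length: int = 10000
    plastid_g_factor: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.g <= 0:
            raise ValueError("g must be positive")
        if self.n_loci <= 0 or self.locus_length < 1:
            raise ValueError("n_loci and locus_length must be positive")
        if self.clock_rate < 0 or self.kappa <= 0:
            raise ValueError("rates must be nonnegative, kappa positive")
        f = np.asarray(self.base_freqs, dtype=float)
        if f.shape != (4,) or np.any(f <= 0) or abs(f.sum() - 1.0) > 1e-8:
            raise ValueError("base_freqs must be 4 positive values summing to 1")
        for p in (self.loss_prob, self.dup_prob):
            if not (0.0 <= p < 1.0):
                raise ValueError("loss_prob and dup_prob must lie in [0, 1)")
        if self.gamma_shape is not None and not (
            self.gamma_shape > 0 or math.isinf(self.gamma_shape)
        ):
            raise ValueError("gamma_shape must be positive (or None)")


# ---------------------------------------------------------------------------
# msprime demography
# ---------------------------------------------------------------------------


def _pop_name(tag: str) -> str:
    return "p_" + "".join(c if c.isalnum() else "_" for c in tag)


def _build_demography(
    model: SpeciesNetworkModel, g: float, plastid: bool = False
) -> tuple[msprime.Demography, list[tuple[str, str]]]:
    """Demography with one population per backbone branch plus hybrid
    populations; returns (demography, [(sample label, population name)]).

    Nuclear mode: every polyploid contributes two homeolog populations
    merging into its maternal / paternal branch at T_h.  Plastid mode: one
    population per polyploid merging into the plastid-donor branch.
    """
    dem = msprime.Demography()
    node_pop = {}
    counter = 0
    for nd in model.backbone.postorder_node_iter():
        if nd.is_leaf():
            name = _pop_name(nd.taxon.label)
        else:
            name = f"anc_{counter}"
            counter += 1
        node_pop[nd] = name
        dem.add_population(name=name, initial_size=g)
    for nd in model.backbone.postorder_node_iter():
        if nd.is_leaf():
            continue
        dem.add_population_split(
            time=model.age(nd),
            derived=[node_pop[ch] for ch in nd.child_nodes()],
            ancestral=node_pop[nd],
        )
    samples: list[tuple[str, str]] = []
    for t in model.taxa:
        if t.ploidy == "diploid":
            lf = model.resolve_branch(t.name)
            samples.append((t.name, node_pop[lf]))
    for ev in model.events:
        if plastid:
            pname = _pop_name(ev.polyploid + "_pt")
            dem.add_population(name=pname, initial_size=g)
            donor = model.resolve_branch(ev.effective_plastid_donor)
            # mass migration (not a population split): the donor branch must
            # stay active for its own sampled lineage
            dem.add_mass_migration(
                time=ev.t_h, source=pname, dest=node_pop[donor], proportion=1.0
            )
            samples.append((ev.polyploid, pname))
        else:
            for tag, branch in (("m", ev.maternal), ("p", ev.paternal)):
                pname = _pop_name(f"{ev.polyploid}_{tag}")
                dem.add_population(name=pname, initial_size=g)
                node = model.resolve_branch(branch)
                dem.add_mass_migration(
                    time=ev.t_h, source=pname, dest=node_pop[node], proportion=1.0
                )
                samples.append((f"{ev.polyploid}|{tag}", pname))
    dem.sort_events()
    return dem, samples


def _ts_to_dendropy(ts, labels: list[str], tns: dendropy.TaxonNamespace) -> dendropy.Tree:
    t = ts.first()
    tree = dendropy.Tree(taxon_namespace=tns)
    times = ts.tables.nodes.time

    def build(u):
        node = dendropy.Node()
        kids = t.children(u)
        if not kids:
            node.taxon = tns.require_taxon(label=labels[u])
        for c in kids:
            ch = build(c)
            ch.edge.length = float(times[t.parent(c)] - times[c])
            node.add_child(ch)
        return node

    roots = t.roots
    if len(roots) != 1:
        raise RuntimeError("expected a single gene-tree root")
    tree.seed_node = build(roots[0])
    tree.is_rooted = True
    return tree


def _locus_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31 - 2)) + 1 for c in ss.spawn(n)]


def simulate_gene_trees(
    model: SpeciesNetworkModel,
    config: SimulationConfig,
    n_loci: int | None = None,
    tns: dendropy.TaxonNamespace | None = None,
) -> list[dendropy.Tree]:
    """Simulate gene trees (branch lengths in Ma) under the multispecies
    coalescent on the network.

    One haplotype is sampled per diploid tip; each polyploid contributes two
    homeolog haplotypes labelled ``taxon|m`` and ``taxon|p``.  Per-locus
    random substreams are derived deterministically from ``config.seed`` so
    any locus is individually reproducible.
    """
    n = config.n_loci if n_loci is None else n_loci
    dem, samples = _build_demography(model, config.g)
    labels = [s[0] for s in samples]
    sample_sets = [msprime.SampleSet(1, population=p, time=0, ploidy=1) for _, p in samples]
    if tns is None:
        tns = dendropy.TaxonNamespace()
    seeds = _locus_seeds(config.seed, n)
    trees = []
    for sd in seeds:
        ts = msprime.sim_ancestry(
            samples=sample_sets, demography=dem, ploidy=1, random_seed=sd
        )
        trees.append(_ts_to_dendropy(ts, labels, tns))
    return trees


def simulate_triplet_counts(
    model: SpeciesNetworkModel,
    config: SimulationConfig,
    triple: tuple[str, str, str],
    n_loci: int | None = None,
    seed: int | None = None,
) -> dict[frozenset, int]:
    """Fast rooted-triplet topology counts (cherry pair -> count) over
    simulated loci, bypassing tree object construction."""
    n = config.n_loci if n_loci is None else n_loci
    dem, samples = _build_demography(model, config.g)
    labels = [s[0] for s in samples]
    idx = {lab: i for i, lab in enumerate(labels)}
    for t in triple:
        if t not in idx:
            raise ValueError(f"taxon {t!r} not among sampled lineages {labels}")
    ids = [idx[t] for t in triple]
    sample_sets = [msprime.SampleSet(1, population=p, time=0, ploidy=1) for _, p in samples]
    counts = {
        frozenset((triple[0], triple[1])): 0,
        frozenset((triple[0], triple[2])): 0,
        frozenset((triple[1], triple[2])): 0,
    }
    reps = msprime.sim_ancestry(
        samples=sample_sets,
        demography=dem,
        ploidy=1,
        num_replicates=n,
        random_seed=(seed if seed is not None else config.seed) % (2**31 - 2) + 1,
    )
    pairs = [(0, 1), (0, 2), (1, 2)]
    for ts in reps:
        t = ts.first()
        tm = [t.tmrca(ids[a], ids[b]) for a, b in pairs]
        k = int(np.argmin(tm))
        a, b = pairs[k]
        counts[frozenset((triple[a], triple[b]))] += 1
    return counts


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------


def evolve_alignment(
    gene_tree: dendropy.Tree,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, str]:
    """Evolve a gap-free alignment along a gene tree (branch durations in Ma)
    under strict-clock HKY with optional gamma site rates."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    L = config.locus_length
    hky = treekit.HKYModel(config.kappa, tuple(config.base_freqs))
    w, left, right = hky._w, hky._left, hky._right
    freqs = hky.freqs
    if config.gamma_shape is None or math.isinf(config.gamma_shape):
        rates = np.ones(L)
    else:
        a = config.gamma_shape
        rates = rng.gamma(a, 1.0 / a, size=L)
    r = config.clock_rate
    root_state = rng.choice(4, size=L, p=freqs)
    states = {gene_tree.seed_node: root_state}
    out = {}
    for nd in gene_tree.preorder_node_iter():
        if nd is not gene_tree.seed_node:
            parent_state = states[nd.parent_node]
            bl = (nd.edge.length or 0.0) * r
            if bl <= 0:
                child = parent_state.copy()
            else:
                t_site = bl * rates
                child = np.empty(L, dtype=np.int64)
                for a_state in range(4):
                    m = parent_state == a_state
                    if not np.any(m):
                        continue
                    E = np.exp(np.outer(t_site[m], w))
                    probs = (E * left[a_state]) @ right
                    probs = np.clip(probs, 0.0, None)
                    probs /= probs.sum(axis=1, keepdims=True)
                    u = rng.random((probs.shape[0], 1))
                    child[m] = (probs.cumsum(axis=1) < u).sum(axis=1)
            states[nd] = child
        if nd.is_leaf():
            out[nd.taxon.label] = "".join("ACGT"[s] for s in states[nd])
    return out


# ---------------------------------------------------------------------------
# Dataset emission
# ---------------------------------------------------------------------------


@dataclass
class TruthRecord:
    """Everything needed to check downstream inference without rerunning the
    simulator: true gene trees, parent pairs with orientation, copy labels,
    hybridization times, plastid donors, and the full config echo."""

    seed: int
    config: dict
    taxa: list[dict]
    events: list[dict]
    copy_origin: dict  # polyploid -> {"maternal": copy label, "paternal": ...}
    gene_trees: list[str]
    plastid_tree: str

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "TruthRecord":
        return cls(**json.loads(text))

    def parent_pair(self, polyploid: str) -> tuple[str, str]:
        for ev in self.events:
            if ev["polyploid"] == polyploid:
                return ev["maternal"], ev["paternal"]
        raise KeyError(polyploid)


def _graft_duplicate(tree, leaf, dup_label, delta, tns):
    """Attach a duplicate tip diverging ``delta`` Ma ago on a terminal branch."""
    bl = leaf.edge.length or 0.0
    h = min(delta, 0.99 * bl)
    parent = leaf.parent_node
    mid = dendropy.Node()
    parent.remove_child(leaf)
    parent.add_child(mid)
    mid.edge.length = bl - h
    mid.add_child(leaf)
    leaf.edge.length = h
    dup = dendropy.Node()
    dup.taxon = tns.require_taxon(label=dup_label)
    dup.edge.length = h
    mid.add_child(dup)


def emit_dataset(
    model: SpeciesNetworkModel,
    config: SimulationConfig,
    out_dir=None,
) -> tuple[OrthogroupTable, dict[str, str], TruthRecord]:
    """Simulate and (optionally) write a full dataset: one FASTA per
    orthogroup (headers ``taxon|seqid|copy``), a plastid alignment whose
    polyploid lineages enter their plastid-donor branches, the taxon
    metadata table, and the truth record.

    Loss drops a taxon from a locus; duplication adds a second copy with
    extra within-branch divergence (exponential, mean 0.1*g Ma).  Returns
    the in-memory table, plastid alignment and truth record.
    """
    master = np.random.SeedSequence(config.seed)
    children = master.spawn(config.n_loci + 2)
    ss_loci = children[: config.n_loci]
    rng_assign = np.random.default_rng(children[config.n_loci])
    ss_plastid = children[config.n_loci + 1]

    dem, samples = _build_demography(model, config.g)
    labels = [s[0] for s in samples]
    sample_sets = [msprime.SampleSet(1, population=p, time=0, ploidy=1) for _, p in samples]
    tns = dendropy.TaxonNamespace()

    copy_origin = {}
    for ev in model.events:
        flip = bool(rng_assign.integers(2))
        copy_origin[ev.polyploid] = (
            {"maternal": "h2", "paternal": "h1"}
            if flip
            else {"maternal": "h1", "paternal": "h2"}
        )

    table = OrthogroupTable(model.taxa)
    gene_tree_newicks = []
    og_alignments = {}
    for i, child_ss in enumerate(ss_loci):
        og_id = f"OG{i:04d}"
        rng = np.random.default_rng(child_ss)
        tree_seed = int(rng.integers(1, 2**31 - 2))
        ts = msprime.sim_ancestry(
            samples=sample_sets, demography=dem, ploidy=1, random_seed=tree_seed
        )
        tree = _ts_to_dendropy(ts, labels, tns)
        # duplication: per retained taxon per locus
        dup_leaves = []
        for t in model.taxa:
            if rng.random() < config.dup_prob:
                cand = [
                    lf
                    for lf in tree.leaf_node_iter()
                    if lf.taxon.label.split("|")[0] == t.name
                ]
                lf = cand[int(rng.integers(len(cand)))]
                dup_label = lf.taxon.label + "|dup"
                delta = rng.exponential(0.1 * config.g)
                _graft_duplicate(tree, lf, dup_label, delta, tns)
                dup_leaves.append(dup_label)
        gene_tree_newicks.append(treekit.write_newick(tree))
        aln = evolve_alignment(tree, config, rng=rng)
        # loss: drop a taxon (all its copies) from this locus
        lost = {t.name for t in model.taxa if rng.random() < config.loss_prob}
        records = []
        k = 0
        for leaf_label in sorted(aln):
            taxon = leaf_label.split("|")[0]
            if taxon in lost:
                continue
            parts = leaf_label.split("|")
            if model.metadata[taxon].ploidy == "tetraploid":
                hom = "maternal" if parts[1] == "m" else "paternal"
                copy = copy_origin[taxon][hom]
                if leaf_label.endswith("|dup"):
                    copy += "d"
            else:
                copy = "c2" if leaf_label.endswith("|dup") else "c1"
            k += 1
            seq_id = f"{og_id}g{k}"
            records.append(
                SequenceRecord(
                    f"{taxon}|{seq_id}|{copy}", taxon, aln[leaf_label]
                )
            )
        table.add_group(og_id, records)
        og_alignments[og_id] = {
            rec.seq_id: rec.residues for rec in records
        }

    # plastid locus: maternally inherited (or captured) single alignment
    pdem, psamples = _build_demography(
        model, config.g * config.plastid_g_factor, plastid=True
    )
    plabels = [s[0] for s in psamples]
    psets = [msprime.SampleSet(1, population=p, time=0, ploidy=1) for _, p in psamples]
    prng = np.random.default_rng(ss_plastid)
    pseed = int(prng.integers(1, 2**31 - 2))
    pts = msprime.sim_ancestry(
        samples=psets, demography=pdem, ploidy=1, random_seed=pseed
    )
    ptree = _ts_to_dendropy(pts, plabels, dendropy.TaxonNamespace())
    pconfig_len = config.plastid_length
    pcfg = SimulationConfig(
        n_loci=1,
        locus_length=pconfig_len,
        g=config.g * config.plastid_g_factor,
        clock_rate=config.clock_rate,
        kappa=config.kappa,
        base_freqs=config.base_freqs,
        gamma_shape=config.gamma_shape,
        seed=config.seed,
    )
    plastid_aln = evolve_alignment(ptree, pcfg, rng=prng)

    cfg = asdict(config)
    cfg["base_freqs"] = list(cfg["base_freqs"])
    truth = TruthRecord(
        seed=config.seed,
        config=cfg,
        taxa=[asdict(t) for t in model.taxa],
        events=[
            {
                "polyploid": ev.polyploid,
                "maternal": ev.maternal,
                "paternal": ev.paternal,
                "t_h": ev.t_h,
                "gamma": ev.gamma,
                "plastid_donor": ev.effective_plastid_donor,
            }
            for ev in model.events
        ],
        copy_origin=copy_origin,
        gene_trees=gene_tree_newicks,
        plastid_tree=treekit.write_newick(ptree),
    )

    if out_dir is not None:
        out = Path(out_dir)
        (out / "orthogroups").mkdir(parents=True, exist_ok=True)
        for og_id in sorted(og_alignments):
            write_fasta(og_alignments[og_id], out / "orthogroups" / f"{og_id}.fasta")
        (out / "plastid").mkdir(exist_ok=True)
        write_fasta(
            {f"{t}|plastid|c1": s for t, s in sorted(plastid_aln.items())},
            out / "plastid" / "plastid.fasta",
        )
        write_metadata(table.metadata, out / "metadata.tsv")
        (out / "truth.json").write_text(truth.to_json() + "\n")
    return table, plastid_aln, truth
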