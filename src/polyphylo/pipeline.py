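"""Pipeline orchestration: configuration, stage execution and reporting.

Stages (in order): simulate -> filter -> stats -> tree -> genetrees ->
concord -> qs -> plastid -> triplet -> parentage -> date.  Every stage
writes its artifacts (TSV tables with a config-echo comment header, plain
newick trees, FASTA) into the output directory; later stages reload
artifacts from disk, so any contiguous or disjoint subset of stages can be
run across invocations.  All randomness flows from the single config seed,
and reruns with identical config are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, fields
from pathlib import Path

import numpy as np

from . import __version__, chrono, discord, orthodata, polyorigin, simdata, treekit

__all__ = [
    "PipelineConfig",
    "parse_config_file",
    "bundled_config_path",
    "run_pipeline",
    "STAGES",
]


def bundled_config_path(name: str = "runall-small.cfg") -> Path:
    """Path of a config file shipped with the package."""
    from importlib.resources import files

    return Path(str(files("polyphylo") / "presets" / name))

STAGES = [
    "simulate",
    "filter",
    "stats",
    "tree",
    "genetrees",
    "concord",
    "qs",
    "plastid",
    "triplet",
    "parentage",
    "date",
]


@dataclass
class PipelineConfig:
    """All thresholds and scales of a pipeline run.

    Defaults are the analysis constants used throughout: low-copy filter
    caps (<5 copies per taxon, <3 per diploid, >300 bp, >=50% coverage), the
    33% gene-tree collapse threshold, the separate 30% threshold for trees
    entering the introgression (triplet) test, 1000-replicate quartet
    sampling with log-likelihood cutoff 2, 1000 bootstrap replicates, and
    the 30.4 Ma secondary root calibration.
    """

    # filtering
    max_copies: int = 5
    max_diploid_copies: int = 3
    min_len: int = 300
    min_coverage: float = 0.5
    # conflict accounting
    collapse_threshold: float = 33.0
    network_bs_threshold: float = 30.0
    qs_replicates: int = 1000
    qs_lnl_cutoff: float = 2.0
    # tree building
    bootstrap_replicates: int = 1000
    gene_bootstrap_replicates: int = 100
    min_gene_taxa: int = 4
    # dating
    root_calibration: float = 30.4
    # parentage
    min_subgenome_loci: int = 10
    # simulation (used by the simulate stage)
    preset: str = "nicotiana-like"
    n_loci: int = 100
    locus_length: int = 500
    g: float = 0.5
    clock_rate: float = 0.005
    kappa: float = 2.0
    gamma_shape: float = 0.0  # 0 = no site-rate heterogeneity
    loss_prob: float = 0.0
    dup_prob: float = 0.0
    plastid_length: int = 10000
    # triplet test: comma-joined focal,parent1,parent2 ('' = skip stage)
    triplet: str = "sylvestris,attenuata,glauca"
    seed: int = 1

    def __post_init__(self):
        if not (0 < self.min_coverage <= 1):
            raise ValueError("min_coverage must be in (0, 1]")
        for name in ("collapse_threshold", "network_bs_threshold"):
            v = getattr(self, name)
            if not (0 <= v <= 100):
                raise ValueError(f"{name} must be in [0, 100]")
        if self.qs_replicates <= 0 or self.bootstrap_replicates <= 0:
            raise ValueError("replicate counts must be positive")
        if self.root_calibration <= 0:
            raise ValueError("root calibration must be positive")

    def echo(self) -> str:
        d = asdict(self)
        return "; ".join(f"{k}={d[k]}" for k in sorted(d))

    def sim_config(self) -> simdata.SimulationConfig:
        return simdata.SimulationConfig(
            n_loci=self.n_loci,
            locus_length=self.locus_length,
            g=self.g,
            clock_rate=self.clock_rate,
            kappa=self.kappa,
            gamma_shape=self.gamma_shape if self.gamma_shape > 0 else None,
            loss_prob=self.loss_prob,
            dup_prob=self.dup_prob,
            plastid_length=self.plastid_length,
            seed=self.seed,
        )


def parse_config_file(path) -> PipelineConfig:
    """Flat ``key = value`` config file; '#' starts a comment."""
    values = {}
    valid = {f.name: f.type for f in fields(PipelineConfig)}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, val = (s.strip() for s in line.split("=", 1))
        if key not in valid:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        current = getattr(PipelineConfig, "__dataclass_fields__")[key].default
        if isinstance(current, bool):
            values[key] = val.lower() in ("1", "true", "yes")
        elif isinstance(current, int):
            values[key] = int(val)
        elif isinstance(current, float):
            values[key] = float(val)
        else:
            values[key] = val
    return PipelineConfig(**values)


# ---------------------------------------------------------------------------
# Artifact helpers
# ---------------------------------------------------------------------------


def _header(config: PipelineConfig) -> str:
    return (
        f"# polyphylo {__version__}\n"
        f"# seed: {config.seed}\n"
        f"# config: {config.echo()}\n"
    )


def _write_tsv(path: Path, body: str, config: PipelineConfig) -> None:
    path.write_text(_header(config) + body)


def _write_tree(path: Path, tree) -> None:
    path.write_text(treekit.write_newick(tree) + "\n")


def _read_tree(path: Path):
    t = treekit.read_newick(path.read_text().strip())
    t.is_rooted = True
    return t


def _stage_seed(config: PipelineConfig, stage: str) -> int:
    """Independent, deterministic substream per stage."""
    ss = np.random.SeedSequence([config.seed, STAGES.index(stage)])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------


class PipelineRun:
    """Executes stages against an output directory, reloading earlier
    artifacts from disk when a stage is run in a fresh invocation."""

    def __init__(self, config: PipelineConfig, out_dir):
        self.config = config
        self.out = Path(out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self._cache: dict = {}

    # -- cached inputs ----------------------------------------------------
    def _data_dir(self) -> Path:
        d = self.out / "data"
        if not d.exists():
            raise StageError("filter", f"no input data at {d}; run 'simulate' first")
        return d

    def metadata(self):
        if "metadata" not in self._cache:
            self._cache["metadata"] = orthodata.read_metadata(
                self._data_dir() / "metadata.tsv"
            )
        return self._cache["metadata"]

    def raw_table(self):
        if "raw_table" not in self._cache:
            self._cache["raw_table"] = orthodata.load_orthogroups(
                self._data_dir() / "orthogroups", self.metadata()
            )
        return self._cache["raw_table"]

    def filtered_table(self):
        if "filtered_table" not in self._cache:
            d = self.out / "filtered"
            if not d.exists():
                raise StageError("stats", "no filtered orthogroups; run 'filter' first")
            self._cache["filtered_table"] = orthodata.load_orthogroups(
                d, self.metadata()
            )
        return self._cache["filtered_table"]

    def diploid_supermatrix(self):
        if "supermatrix" not in self._cache:
            path = self.out / "supermatrix.fasta"
            if not path.exists():
                raise StageError("tree", "no supermatrix; run 'stats' first")
            rows = orthodata.read_fasta(path)
            parts = []
            for line in (self.out / "supermatrix_partitions.txt").read_text().splitlines():
                og, rng = line.split(" = ")
                s, e = rng.split("-")
                parts.append((og, int(s), int(e)))
            self._cache["supermatrix"] = orthodata.Supermatrix(rows, parts)
        return self._cache["supermatrix"]

    def species_tree(self):
        path = self.out / "diploid_tree.nwk"
        if not path.exists():
            raise StageError("concord", "no species tree; run 'tree' first")
        return _read_tree(path)

    def gene_trees(self):
        path = self.out / "gene_trees.nwk"
        if not path.exists():
            raise StageError("concord", "no gene trees; run 'genetrees' first")
        trees = []
        for line in path.read_text().splitlines():
            if line.strip():
                t = treekit.read_newick(line)
                t.is_rooted = True
                trees.append(t)
        return trees

    def plastid_tree(self):
        path = self.out / "plastid_tree.nwk"
        if not path.exists():
            raise StageError("parentage", "no plastid tree; run 'plastid' first")
        return _read_tree(path)

    def outgroups(self) -> list[str]:
        return [t.name for t in self.metadata().values() if t.outgroup]

    # -- stages -----------------------------------------------------------
    def stage_simulate(self):
        model = simdata.load_preset(self.config.preset)
        table, plastid_aln, truth = simdata.emit_dataset(
            model, self.config.sim_config(), out_dir=self.out / "data"
        )
        self._cache["metadata"] = table.metadata
        self._cache["raw_table"] = table
        self._summary("simulate", {
            "preset": self.config.preset,
            "n_loci": self.config.n_loci,
            "taxa": sorted(table.metadata),
        })

    def stage_filter(self):
        table = self.raw_table()
        filtered, report = orthodata.filter_orthogroups(
            table,
            max_copies=self.config.max_copies,
            max_diploid_copies=self.config.max_diploid_copies,
            min_len=self.config.min_len,
            min_coverage=self.config.min_coverage,
        )
        self._cache["filtered_table"] = filtered
        fdir = self.out / "filtered"
        fdir.mkdir(exist_ok=True)
        for og_id in filtered.og_ids:
            orthodata.write_fasta(
                {r.seq_id: r.residues for r in filtered.sequences(og_id)},
                fdir / f"{og_id}.fasta",
            )
        _write_tsv(self.out / "filter_report.tsv", report.to_tsv(), self.config)
        pm = orthodata.presence_matrix(filtered)
        _write_tsv(
            self.out / "presence_matrix.tsv",
            pm.to_csv(sep="\t"),
            self.config,
        )
        self._summary("filter", {
            "input": report.input_count,
            "retained": len(report.retained),
            "rejected": list(report.rejection_counts),
            "dropped_sequences": report.dropped_sequences,
        })

    def _diploid_loci(self, table):
        """Single-copy diploid (+outgroup) alignments per orthogroup."""
        loci = {}
        diploids = table.diploid_taxa
        for og_id in table.og_ids:
            aln = {}
            for taxon in diploids:
                recs = table.groups[og_id].get(taxon, ())
                if len(recs) == 1:
                    aln[taxon] = recs[0].residues
            if len(aln) >= 2:
                loci[og_id] = orthodata.trim_alignment(aln, 0.5)
        return loci

    def stage_stats(self):
        table = self.filtered_table()
        loci = self._diploid_loci(table)
        if not loci:
            raise StageError("stats", "no single-copy diploid loci after filtering")
        sm = orthodata.concatenate(loci, table.diploid_taxa)
        orthodata.write_fasta(sm.rows, self.out / "supermatrix.fasta")
        (self.out / "supermatrix_partitions.txt").write_text(sm.partition_text())
        stats = orthodata.supermatrix_stats(sm)
        _write_tsv(self.out / "supermatrix_stats.tsv", stats.to_tsv(), self.config)
        self._cache["supermatrix"] = sm
        self._summary("stats", {
            "loci": len(sm.partitions),
            "length": stats.total_length,
            "variable_pct": stats.variable_pct,
            "pi_pct": stats.parsimony_informative_pct,
            "missing_pct": stats.missing_pct,
        })

    def stage_tree(self):
        sm = self.diploid_supermatrix()
        tree = treekit.bootstrap_support(
            sm.rows,
            n=self.config.bootstrap_replicates,
            seed=_stage_seed(self.config, "tree"),
        )
        og = self.outgroups()
        if og:
            tree = treekit.root_by_outgroup(tree, og)
        _write_tree(self.out / "diploid_tree.nwk", tree)
        self._summary("tree", {"newick": treekit.write_newick(tree)})

    def stage_genetrees(self):
        table = self.filtered_table()
        loci = self._diploid_loci(table)
        og_names = self.outgroups()
        out_lines = []
        seed0 = _stage_seed(self.config, "genetrees")
        for i, og_id in enumerate(sorted(loci)):
            aln = loci[og_id]
            if len(aln) < self.config.min_gene_taxa:
                continue
            try:
                gt = treekit.bootstrap_support(
                    aln,
                    n=self.config.gene_bootstrap_replicates,
                    seed=(seed0 + i) % (2**31 - 1),
                )
            except ValueError:
                continue  # saturated / degenerate locus
            present_og = [t for t in og_names if t in aln]
            try:
                if present_og:
                    gt = treekit.root_by_outgroup(gt, present_og)
                else:
                    gt = treekit.mad_root(gt)
            except ValueError:
                continue
            gt = treekit.collapse_low_support(gt, self.config.collapse_threshold)
            out_lines.append(treekit.write_newick(gt))
        (self.out / "gene_trees.nwk").write_text("\n".join(out_lines) + "\n")
        self._summary("genetrees", {"n_trees": len(out_lines)})

    def stage_concord(self):
        sp = self.species_tree()
        gts = self.gene_trees()
        res = discord.concordance_summary(sp, gts, collapse_threshold=None)
        _write_tsv(
            self.out / "concordance.tsv",
            discord.concordance_report(res),
            self.config,
        )
        self._summary("concord", {
            "nodes": len(res),
            "mean_concordant_fraction": (
                round(
                    float(
                        np.mean(
                            [nc.concordant / nc.total for nc in res if nc.total]
                        )
                    ),
                    4,
                )
                if res
                else None
            ),
        })

    def stage_qs(self):
        sp = self.species_tree()
        sm = self.diploid_supermatrix()
        qs = discord.quartet_sampling(
            sp,
            sm.rows,
            n_reps=self.config.qs_replicates,
            lnl_cutoff=self.config.qs_lnl_cutoff,
            seed=_stage_seed(self.config, "qs"),
        )
        _write_tsv(self.out / "qs_branches.tsv", qs.branch_report(), self.config)
        _write_tsv(self.out / "qs_tips.tsv", qs.tip_report(), self.config)
        self._summary("qs", {
            "branches": len(qs.branches),
            "labels": [discord.label_string(b) for b in qs.branches],
        })

    def stage_plastid(self):
        d = self._data_dir() / "plastid" / "plastid.fasta"
        if not d.exists():
            raise StageError("plastid", f"missing plastid alignment {d}")
        aln = {
            name.split("|")[0]: seq for name, seq in orthodata.read_fasta(d).items()
        }
        tree = treekit.bootstrap_support(
            aln,
            n=self.config.bootstrap_replicates,
            seed=_stage_seed(self.config, "plastid"),
        )
        og = self.outgroups()
        if og:
            tree = treekit.root_by_outgroup(tree, [t for t in og if t in aln])
        _write_tree(self.out / "plastid_tree.nwk", tree)
        try:
            sp = self.species_tree()
        except StageError:
            sp = None
        if sp is not None:
            rep = discord.cytonuclear_conflicts(sp, tree)
            _write_tsv(self.out / "cytonuclear.tsv", rep.to_tsv(), self.config)
            self._summary("plastid", {
                "conflicting_taxa": sorted(rep.conflicting_taxa()),
            })
        else:
            self._summary("plastid", {"conflicting_taxa": None})

    def stage_triplet(self):
        if not self.config.triplet:
            self._summary("triplet", {"skipped": True})
            return
        triple = tuple(s.strip() for s in self.config.triplet.split(","))
        if len(triple) != 3:
            raise StageError("triplet", f"bad triple spec {self.config.triplet!r}")
        gts = [
            treekit.collapse_low_support(t, self.config.network_bs_threshold)
            for t in self.gene_trees()
        ]
        try:
            res = discord.triplet_skew_test(gts, triple, g=self.config.g)
        except ValueError as exc:
            raise StageError("triplet", str(exc)) from exc
        body = (
            "key\tvalue\n"
            f"triple\t{','.join(triple)}\n"
            f"major_pair\t{'+'.join(sorted(res.major_pair))}\n"
            f"major\t{res.major}\n"
            f"minor1\t{res.minor1}\n"
            f"minor2\t{res.minor2}\n"
            f"chi2\t{'-' if res.statistic is None else f'{res.statistic:.6f}'}\n"
            f"p_value\t{'-' if res.p_value is None else f'{res.p_value:.6f}'}\n"
            f"t_hat_ma\t{'-' if res.t_hat is None else f'{res.t_hat:.6f}'}\n"
        )
        _write_tsv(self.out / "triplet.tsv", body, self.config)
        self._summary("triplet", {
            "chi2": res.statistic,
            "p": res.p_value,
        })

    def stage_parentage(self):
        table = self.filtered_table()
        if not table.polyploid_taxa:
            raise StageError("parentage", "no polyploid taxa in metadata")
        bh = polyorigin.best_hit_counts(table)
        _write_tsv(self.out / "besthit_matrix.tsv", bh.to_tsv(), self.config)
        sp = self.species_tree()
        ptree = self.plastid_tree()
        rows = ["polyploid\tfirst\tsecond\tmaternal\tpaternal\tcapture\tplastid_sister"]
        hyps = []
        assignments = []
        for poly in table.polyploid_taxa:
            hyp = polyorigin.infer_parent_pair(bh.counts.loc[poly], sp)
            hyp.polyploid = poly
            hyp = polyorigin.orient_parents(hyp, ptree)
            hyps.append(hyp)
            rows.append(
                "\t".join(
                    [
                        poly,
                        "+".join(sorted(hyp.first)),
                        "+".join(sorted(hyp.second)),
                        "+".join(sorted(hyp.maternal)) if hyp.maternal else "-",
                        "+".join(sorted(hyp.paternal)) if hyp.paternal else "-",
                        str(int(hyp.capture_flag)),
                        "+".join(sorted(hyp.plastid_sister or [])) or "-",
                    ]
                )
            )
            if hyp.oriented:
                asn = polyorigin.assign_subgenomes(table, hyp, best_hits=bh)
                assignments.append(asn)
                _write_tsv(
                    self.out / f"assignments_{poly}.tsv", asn.to_tsv(), self.config
                )
        _write_tsv(self.out / "parentage.tsv", "\n".join(rows) + "\n", self.config)
        oriented = [h for h in hyps if h.oriented]
        if assignments:
            tree, warns = polyorigin.build_subgenome_tree(
                table,
                assignments,
                min_loci=self.config.min_subgenome_loci,
                bootstrap=self.config.bootstrap_replicates,
                seed=_stage_seed(self.config, "parentage"),
            )
            og = [t for t in self.outgroups() if t in table.diploid_taxa]
            if og:
                tree = treekit.root_by_outgroup(tree, og)
            _write_tree(self.out / "subgenome_tree.nwk", tree)
        else:
            warns = ["no oriented hypotheses; subgenome tree skipped"]
        self._summary("parentage", {
            "hypotheses": [
                {
                    "polyploid": h.polyploid,
                    "maternal": sorted(h.maternal) if h.maternal else None,
                    "paternal": sorted(h.paternal) if h.paternal else None,
                    "capture": h.capture_flag,
                }
                for h in hyps
            ],
            "warnings": warns,
            "oriented": len(oriented),
        })

    def stage_date(self):
        path = self.out / "subgenome_tree.nwk"
        if not path.exists():
            raise StageError("date", "no subgenome tree; run 'parentage' first")
        tree = _read_tree(path)
        tips = [lf.taxon.label for lf in tree.leaf_node_iter()]
        cg = chrono.strict_clock_chronogram(
            tree, tips, self.config.root_calibration
        )
        _write_tree(self.out / "chronogram.nwk", cg.tree)
        _write_tsv(self.out / "node_ages.tsv", cg.node_age_table(), self.config)
        # reconstruct oriented hypotheses from the parentage table
        hyps = []
        ppath = self.out / "parentage.tsv"
        if not ppath.exists():
            raise StageError("date", "no parentage table; run 'parentage' first")
        for line in ppath.read_text().splitlines():
            if line.startswith("#") or line.startswith("polyploid\t"):
                continue
            poly, _first, _second, mat, pat, *_ = line.split("\t")
            if mat == "-" or pat == "-":
                continue
            hyps.append(
                polyorigin.ParentHypothesis(
                    polyploid=poly,
                    first=frozenset(mat.split("+")),
                    second=frozenset(pat.split("+")),
                    oriented=True,
                    maternal=frozenset(mat.split("+")),
                    paternal=frozenset(pat.split("+")),
                )
            )
        dates = chrono.hybridization_dates(cg, hyps)
        _write_tsv(
            self.out / "hybridization_dates.tsv",
            chrono.dates_report(dates),
            self.config,
        )
        self._summary("date", {
            "rate": cg.rate,
            "rss": cg.rss,
            "dates": [
                {
                    "polyploid": d.polyploid,
                    "subgenome": d.subgenome,
                    "age_ma": round(d.age_ma, 6),
                }
                for d in dates
            ],
        })

    # -- driver -----------------------------------------------------------
    def _summary(self, stage: str, payload: dict) -> None:
        data = {
            "stage": stage,
            "version": __version__,
            "seed": self.config.seed,
            "config": self.config.echo(),
            "result": payload,
        }
        (self.out / f"summary_{stage}.json").write_text(
            json.dumps(data, sort_keys=True, indent=1, default=str) + "\n"
        )

    def run(self, stages=None) -> None:
        stages = list(STAGES) if stages is None else list(stages)
        unknown = [s for s in stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")
        for stage in STAGES:
            if stage in stages:
                getattr(self, f"stage_{stage}")()


def run_pipeline(config: PipelineConfig, out_dir, stages=None) -> Path:
    run = PipelineRun(config, out_dir)
    run.run(stages)
    return run.out
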