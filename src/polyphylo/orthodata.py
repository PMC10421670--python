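"""Orthogroup I/O, low-copy filtering, trimming, concatenation and summary
statistics.

The central container is :class:`OrthogroupTable`: orthogroup -> taxon ->
list of :class:`SequenceRecord`, plus per-taxon metadata (ploidy, outgroup
flag).  Filtering implements the four low-copy criteria used to select
orthogroups for phylogenomic analysis of a mixed diploid/allotetraploid
sample: a per-taxon copy-number cap, a stricter per-diploid cap, a minimum
coding length, and a minimum ingroup taxon coverage.
"""

from __future__ import annotations


import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "TaxonInfo",
    "SequenceRecord",
    "OrthogroupTable",
    "FilterReport",
    "load_orthogroups",
    "filter_orthogroups",
    "presence_matrix",
    "trim_alignment",
    "Supermatrix",
    "concatenate",
    "deconcatenate",
    "SupermatrixStats",
    "supermatrix_stats",
    "read_fasta",
    "write_fasta",
    "read_metadata",
    "write_metadata",
]

_ALPHABET = set("ACGTN-")


@dataclass(frozen=True)
class TaxonInfo:
    name: str
    ploidy: str  # "diploid" | "tetraploid"
    outgroup: bool = False

    def __post_init__(self):
        if self.ploidy not in ("diploid", "tetraploid"):
            raise ValueError(f"unknown ploidy {self.ploidy!r} for {self.name}")


@dataclass(frozen=True)
class SequenceRecord:
    seq_id: str
    taxon: str
    residues: str

    def __post_init__(self):
        if not self.residues:
            raise ValueError(f"empty sequence for {self.seq_id}")
        bad = set(self.residues.upper()) - _ALPHABET
        if bad:
            raise ValueError(
                f"illegal characters {sorted(bad)} in sequence {self.seq_id}"
            )
        object.__setattr__(self, "residues", self.residues.upper())

    @property
    def ungapped_length(self) -> int:
        return len(self.residues) - self.residues.count("-")


class OrthogroupTable:
    """og_id -> taxon -> list of SequenceRecord, with taxon metadata."""

    def __init__(self, metadata: Sequence[TaxonInfo] | Mapping[str, TaxonInfo]):
        if isinstance(metadata, Mapping):
            metadata = list(metadata.values())
        self.metadata: dict[str, TaxonInfo] = {t.name: t for t in metadata}
        self.groups: dict[str, dict[str, list[SequenceRecord]]] = {}

    # -- construction -----------------------------------------------------
    def add(self, og_id: str, record: SequenceRecord) -> None:
        if record.taxon not in self.metadata:
            raise ValueError(
                f"taxon {record.taxon!r} (orthogroup {og_id}) not in metadata"
            )
        self.groups.setdefault(og_id, {}).setdefault(record.taxon, []).append(record)

    def add_group(self, og_id: str, records: Iterable[SequenceRecord]) -> None:
        if og_id in self.groups:
            raise ValueError(f"duplicate orthogroup id {og_id!r}")
        self.groups[og_id] = {}
        for rec in records:
            self.add(og_id, rec)

    # -- views ------------------------------------------------------------
    @property
    def og_ids(self) -> list[str]:
        return sorted(self.groups)

    @property
    def taxa(self) -> list[str]:
        return list(self.metadata)

    @property
    def ingroup_taxa(self) -> list[str]:
        return [t for t, m in self.metadata.items() if not m.outgroup]

    @property
    def diploid_taxa(self) -> list[str]:
        return [t for t, m in self.metadata.items() if m.ploidy == "diploid"]

    @property
    def polyploid_taxa(self) -> list[str]:
        return [t for t, m in self.metadata.items() if m.ploidy == "tetraploid"]

    def sequences(self, og_id: str) -> list[SequenceRecord]:
        out = []
        for taxon in self.metadata:
            out.extend(self.groups.get(og_id, {}).get(taxon, []))
        return out

    def alignment(self, og_id: str) -> dict[str, str]:
        """Per-taxon alignment rows for single-copy taxa of one orthogroup.

        Taxa with more than one copy are skipped (rows would be ambiguous).
        """
        out = {}
        for taxon, recs in self.groups[og_id].items():
            if len(recs) == 1:
                out[taxon] = recs[0].residues
        return out

    def __len__(self) -> int:
        return len(self.groups)


# ---------------------------------------------------------------------------
# FASTA / metadata I/O
# ---------------------------------------------------------------------------


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path, wrap: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), wrap):
                fh.write(seq[i : i + wrap] + "\n")


def write_metadata(metadata: Mapping[str, TaxonInfo], path) -> None:
    with open(path, "w") as fh:
        fh.write("taxon\tploidy\toutgroup\n")
        for t in metadata.values():
            fh.write(f"{t.name}\t{t.ploidy}\t{int(t.outgroup)}\n")


def read_metadata(path) -> dict[str, TaxonInfo]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = {}
    for _, row in df.iterrows():
        out[row["taxon"]] = TaxonInfo(
            row["taxon"], row["ploidy"], bool(int(row["outgroup"]))
        )
    return out


def load_orthogroups(
    paths, metadata: Sequence[TaxonInfo] | Mapping[str, TaxonInfo]
) -> OrthogroupTable:
    """Load orthogroup FASTAs (one file per orthogroup, ``taxon|seqid[|copy]``
    headers); the file stem is the orthogroup id."""
    if isinstance(paths, (str, os.PathLike)):
        root = Path(paths)
        paths = sorted(root.glob("*.fasta")) + sorted(root.glob("*.fa"))
    table = OrthogroupTable(metadata)
    for path in paths:
        path = Path(path)
        og_id = path.stem
        if og_id in table.groups:
            raise ValueError(f"duplicate orthogroup id {og_id!r} from {path}")
        records = []
        with open(path) as fh:
            lineno = 0
            header = None
            chunks: list[str] = []

            def flush():
                if header is None:
                    return
                if "|" not in header:
                    raise ValueError(
                        f"{path}:{header_line}: header {header!r} lacks the "
                        "'taxon|seqid' delimiter"
                    )
                parts = header.split("|")
                taxon = parts[0]
                seq_id = header
                records.append(SequenceRecord(seq_id, taxon, "".join(chunks)))

            for raw in fh:
                lineno += 1
                line = raw.strip()
                if not line:
                    continue
                if line.startswith(">"):
                    flush()
                    header = line[1:].split()[0]
                    header_line = lineno
                    chunks = []
                else:
                    chunks.append(line)
            flush()
        table.add_group(og_id, records)
    return table


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------


@dataclass
class FilterReport:
    """Per-criterion rejection accounting; criteria are evaluated in order
    (copy cap, diploid copy cap, length drop, coverage) and a rejected
    orthogroup is attributed to the first criterion it fails."""

    input_count: int = 0
    retained: list[str] = field(default_factory=list)
    rejected_max_copies: int = 0
    rejected_max_diploid_copies: int = 0
    rejected_min_coverage: int = 0
    dropped_sequences: int = 0

    @property
    def rejection_counts(self) -> tuple[int, int, int]:
        return (
            self.rejected_max_copies,
            self.rejected_max_diploid_copies,
            self.rejected_min_coverage,
        )

    def to_tsv(self) -> str:
        lines = [
            "key\tvalue",
            f"input_orthogroups\t{self.input_count}",
            f"retained\t{len(self.retained)}",
            f"rejected_max_copies\t{self.rejected_max_copies}",
            f"rejected_max_diploid_copies\t{self.rejected_max_diploid_copies}",
            f"rejected_min_coverage\t{self.rejected_min_coverage}",
            f"dropped_short_sequences\t{self.dropped_sequences}",
        ]
        return "\n".join(lines) + "\n"


def filter_orthogroups(
    table: OrthogroupTable,
    max_copies: int = 5,
    max_diploid_copies: int = 3,
    min_len: int = 300,
    min_coverage: float = 0.5,
) -> tuple[OrthogroupTable, FilterReport]:
    """Low-copy orthogroup filter.

    Retains an orthogroup iff (1) every taxon has fewer than ``max_copies``
    sequences, (2) every diploid taxon fewer than ``max_diploid_copies``,
    (3) after dropping sequences of ungapped length <= ``min_len`` (strict
    "> min_len" retention), (4) the fraction of ingroup taxa still present is
    >= ``min_coverage``.  Criterion 3 drops offending sequences rather than
    whole orthogroups; coverage is then re-evaluated.
    """
    if not (0.0 < min_coverage <= 1.0):
        raise ValueError("min_coverage must be in (0, 1]")
    if max_copies <= 0 or max_diploid_copies <= 0 or min_len <= 0:
        raise ValueError("thresholds must be positive")
    diploids = set(table.diploid_taxa)
    ingroup = table.ingroup_taxa
    report = FilterReport(input_count=len(table))
    out = OrthogroupTable(table.metadata)
    for og_id in table.og_ids:
        group = table.groups[og_id]
        if any(len(recs) >= max_copies for recs in group.values()):
            report.rejected_max_copies += 1
            continue
        if any(
            len(recs) >= max_diploid_copies
            for taxon, recs in group.items()
            if taxon in diploids
        ):
            report.rejected_max_diploid_copies += 1
            continue
        kept: dict[str, list[SequenceRecord]] = {}
        for taxon, recs in group.items():
            keep = [r for r in recs if r.ungapped_length > min_len]
            report.dropped_sequences += len(recs) - len(keep)
            if keep:
                kept[taxon] = keep
        present = sum(1 for t in ingroup if t in kept)
        if ingroup and present / len(ingroup) < min_coverage:
            report.rejected_min_coverage += 1
            continue
        out.groups[og_id] = kept
        report.retained.append(og_id)
    return out, report


def presence_matrix(table: OrthogroupTable) -> pd.DataFrame:
    """Taxon x orthogroup copy-count matrix (rows in metadata order, columns
    in lexicographic orthogroup order)."""
    ogs = table.og_ids
    data = np.zeros((len(table.taxa), len(ogs)), dtype=int)
    for j, og in enumerate(ogs):
        for i, taxon in enumerate(table.taxa):
            data[i, j] = len(table.groups[og].get(taxon, ()))
    return pd.DataFrame(data, index=table.taxa, columns=ogs)


# ---------------------------------------------------------------------------
# Trimming / concatenation / statistics
# ---------------------------------------------------------------------------


def trim_alignment(
    alignment: Mapping[str, str], max_gap_fraction: float = 0.5
) -> dict[str, str]:
    """Remove columns whose gap+N fraction exceeds ``max_gap_fraction``."""
    if not alignment:
        raise ValueError("empty alignment")
    rows = list(alignment.values())
    L = len(rows[0])
    if any(len(r) != L for r in rows):
        raise ValueError("alignment is not rectangular")
    if L == 0:
        raise ValueError("zero-length alignment")
    arr = np.array([list(r) for r in rows])
    frac = np.mean((arr == "-") | (arr == "N"), axis=0)
    keep = frac <= max_gap_fraction
    return {
        name: "".join(np.array(list(seq))[keep]) for name, seq in alignment.items()
    }


@dataclass
class Supermatrix:
    """Concatenated alignment with 1-based inclusive partition coordinates."""

    rows: dict[str, str]
    partitions: list[tuple[str, int, int]]

    def __post_init__(self):
        lens = {len(s) for s in self.rows.values()}
        if len(lens) > 1:
            raise ValueError("rows of unequal length")
        total = next(iter(lens)) if lens else 0
        pos = 1
        for og, start, end in self.partitions:
            if start != pos or end < start:
                raise ValueError("partitions do not tile the matrix")
            pos = end + 1
        if self.partitions and pos - 1 != total:
            raise ValueError("partitions do not cover the matrix")

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def partition_text(self) -> str:
        return "".join(f"{og} = {s}-{e}\n" for og, s, e in self.partitions)


def concatenate(loci, taxa: Sequence[str]) -> Supermatrix:
    """Concatenate loci into a supermatrix over a fixed row order.

    ``loci`` is a mapping og_id -> alignment dict, or an iterable of
    ``(og_id, alignment)`` pairs.  Taxa absent from a locus are padded with
    gaps across that partition.
    """
    if isinstance(loci, Mapping):
        loci = sorted(loci.items())
    taxa = list(taxa)
    if len(set(taxa)) != len(taxa):
        dup = sorted({t for t in taxa if taxa.count(t) > 1})
        raise ValueError(f"taxon name collision: {dup}")
    chunks: dict[str, list[str]] = {t: [] for t in taxa}
    partitions = []
    pos = 1
    for og_id, aln in loci:
        if not aln:
            continue
        L = len(next(iter(aln.values())))
        if any(len(s) != L for s in aln.values()):
            raise ValueError(f"locus {og_id} is not rectangular")
        for t in taxa:
            chunks[t].append(aln.get(t, "-" * L))
        partitions.append((og_id, pos, pos + L - 1))
        pos += L
    return Supermatrix({t: "".join(chunks[t]) for t in taxa}, partitions)


def deconcatenate(sm: Supermatrix) -> dict[str, dict[str, str]]:
    """Recover per-locus alignments (all-gap rows removed)."""
    out = {}
    for og, start, end in sm.partitions:
        aln = {}
        for t, row in sm.rows.items():
            piece = row[start - 1 : end]
            if piece != "-" * len(piece):
                aln[t] = piece
        out[og] = aln
    return out


@dataclass
class SupermatrixStats:
    total_length: int
    variable_sites: int
    parsimony_informative: int
    missing_cells: int
    total_cells: int

    @property
    def variable_pct(self) -> float:
        return round(100.0 * self.variable_sites / self.total_length, 2)

    @property
    def parsimony_informative_pct(self) -> float:
        return round(100.0 * self.parsimony_informative / self.total_length, 2)

    @property
    def missing_pct(self) -> float:
        return round(100.0 * self.missing_cells / self.total_cells, 2)

    def to_tsv(self) -> str:
        return (
            "key\tvalue\n"
            f"total_length\t{self.total_length}\n"
            f"variable_sites\t{self.variable_sites}\n"
            f"variable_pct\t{self.variable_pct}\n"
            f"parsimony_informative\t{self.parsimony_informative}\n"
            f"parsimony_informative_pct\t{self.parsimony_informative_pct}\n"
            f"missing_cells\t{self.missing_cells}\n"
            f"missing_pct\t{self.missing_pct}\n"
        )


def supermatrix_stats(sm: Supermatrix) -> SupermatrixStats:
    """Variable / parsimony-informative / missing site accounting.

    A column is variable if it holds >= 2 distinct non-gap, non-N states;
    parsimony-informative if >= 2 states each occur in >= 2 rows; missing
    counts gap and N cells over all cells.
    """
    if not sm.rows or sm.length == 0:
        raise ValueError("empty supermatrix")
    arr = np.array([list(s) for s in sm.rows.values()])
    missing_mask = (arr == "-") | (arr == "N")
    var = 0
    pi = 0
    for j in range(arr.shape[1]):
        col = arr[~missing_mask[:, j], j]
        if col.size == 0:
            continue
        states, counts = np.unique(col, return_counts=True)
        if len(states) >= 2:
            var += 1
            if np.sum(counts >= 2) >= 2:
                pi += 1
    return SupermatrixStats(
        total_length=sm.length,
        variable_sites=var,
        parsimony_informative=pi,
        missing_cells=int(missing_mask.sum()),
        total_cells=int(arr.size),
    )
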