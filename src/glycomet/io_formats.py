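"""Readers and writers for every external file the pipeline touches.

All tabular formats are plain TSV; coordinates are 0-based half-open
(BEDGraph convention) throughout. Readers validate strictly and report
1-based line numbers on malformed input rather than coercing silently.

Formats owned by this module:

* alignment hits — BLAST outfmt-6-like TSV (configurable column order),
* per-base depth tracks — 4-column BEDGraph (``genomecov -bga`` style),
* NCBI-style taxdump ``nodes.dmp`` / ``names.dmp``,
* genome manifest (genome_id, length_bp),
* gene annotation table (gene_id, parent_id, ordinal, length_bp, labels),
* transcript counts (gene_id, count),
* glycan microarray long-format signal table.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "FormatError",
    "AlignmentHit",
    "GeneRecord",
    "DepthInterval",
    "DEFAULT_HIT_COLUMNS",
    "read_alignment_hits",
    "write_alignment_hits",
    "read_depth_track",
    "write_depth_track",
    "read_taxdump",
    "write_taxdump",
    "read_genome_manifest",
    "write_genome_manifest",
    "read_gene_annotations",
    "write_gene_annotations",
    "read_transcript_counts",
    "write_transcript_counts",
    "read_microarray_signals",
    "write_microarray_signals",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class AlignmentHit:
    """One protein-alignment hit of a predicted gene against a reference.

    ``percent_identity`` and ``query_coverage`` are on the 0–100 scale;
    ``subject_taxid`` is the taxon of the database subject.
    """

    query_gene_id: str
    subject_id: str
    percent_identity: float
    evalue: float
    query_coverage: float
    bitscore: float
    subject_taxid: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(
                f"percent_identity {self.percent_identity} outside [0, 100]"
            )
        if not 0.0 <= self.query_coverage <= 100.0:
            raise ValueError(
                f"query_coverage {self.query_coverage} outside [0, 100]"
            )
        if self.evalue < 0:
            raise ValueError(f"evalue {self.evalue} is negative")


@dataclass(frozen=True)
class GeneRecord:
    """An annotated gene on a parent read or contig.

    ``ordinal`` is the 0-based position index of the gene along its parent;
    ``labels`` holds functional tags (SC-RBP marker names, CAZyme families
    such as ``GH16_3``, ``sulfatase``, ``peptidase``, ``susC``, ``susD``,
    ``TBDT``, ``other``).
    """

    gene_id: str
    parent_id: str
    ordinal: int
    length_bp: int
    labels: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"length_bp must be positive, got {self.length_bp}")
        if self.ordinal < 0:
            raise ValueError(f"ordinal must be >= 0, got {self.ordinal}")
        object.__setattr__(self, "labels", frozenset(self.labels))


@dataclass(frozen=True)
class DepthInterval:
    """A run of constant per-base depth on one genome, 0-based half-open."""

    genome_id: str
    start: int
    end: int
    depth: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"interval [{self.start}, {self.end}) on {self.genome_id} is empty"
            )
        if self.depth < 0:
            raise ValueError(f"depth {self.depth} is negative")

    def __len__(self) -> int:
        return self.end - self.start


# BLAST outfmt 6 with query_coverage (qcovhsp) and subject_taxid (staxids)
# appended; only the named fields are consumed, the rest are passed through.
DEFAULT_HIT_COLUMNS: tuple[str, ...] = (
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
    "qcovhsp",
    "staxids",
)

_HIT_FIELD_TO_COLUMN = {
    "query_gene_id": "qseqid",
    "subject_id": "sseqid",
    "percent_identity": "pident",
    "evalue": "evalue",
    "bitscore": "bitscore",
    "query_coverage": "qcovhsp",
    "subject_taxid": "staxids",
}


def _open_rows(path):
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if row[0].startswith("#"):
                continue
            yield lineno, row


def read_alignment_hits(
    path, dialect: Sequence[str] = DEFAULT_HIT_COLUMNS
) -> list[AlignmentHit]:
    """Read a tab-separated hit table into :class:`AlignmentHit` records.

    ``dialect`` names the columns in file order; it must contain every
    column required by the seven AlignmentHit fields (qseqid, sseqid,
    pident, evalue, bitscore, qcovhsp, staxids).
    """
    dialect = list(dialect)
    index: dict[str, int] = {}
    for fieldname, col in _HIT_FIELD_TO_COLUMN.items():
        try:
            index[fieldname] = dialect.index(col)
        except ValueError:
            raise FormatError(
                f"hit dialect is missing required column {col!r} "
                f"(field {fieldname})"
            ) from None
    n_needed = max(index.values()) + 1

    hits: list[AlignmentHit] = []
    for lineno, row in _open_rows(path):
        if len(row) < n_needed:
            raise FormatError(
                f"{path}:{lineno}: expected >= {n_needed} columns, got {len(row)}"
            )
        try:
            hits.append(
                AlignmentHit(
                    query_gene_id=row[index["query_gene_id"]],
                    subject_id=row[index["subject_id"]],
                    percent_identity=float(row[index["percent_identity"]]),
                    evalue=float(row[index["evalue"]]),
                    query_coverage=float(row[index["query_coverage"]]),
                    bitscore=float(row[index["bitscore"]]),
                    # staxids may be a ;-joined list; take the first
                    subject_taxid=int(str(row[index["subject_taxid"]]).split(";")[0]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{path}:{lineno}: malformed hit row: {exc}") from exc
    return hits


def write_alignment_hits(
    path, hits: Iterable[AlignmentHit], header: str | None = None
) -> None:
    """Write hits in the default 14-column dialect (unused columns zeroed)."""
    with open(path, "w", newline="") as fh:
        if header:
            fh.write(header)
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for h in hits:
            # repr keeps the shortest representation that round-trips
            w.writerow(
                [
                    h.query_gene_id,
                    h.subject_id,
                    repr(h.percent_identity),
                    0,
                    0,
                    0,
                    0,
                    0,
                    0,
                    0,
                    repr(h.evalue),
                    repr(h.bitscore),
                    repr(h.query_coverage),
                    h.subject_taxid,
                ]
            )


def read_depth_track(path) -> dict[str, list[DepthInterval]]:
    """Read a 4-column BEDGraph into per-genome sorted interval lists.

    Intervals are sorted by start; overlapping intervals within one genome
    are a validation error. Gaps are permitted (depth 0 downstream when the
    genome length is known from the manifest).
    """
    by_genome: dict[str, list[DepthInterval]] = {}
    for lineno, row in _open_rows(path):
        if len(row) < 4:
            raise FormatError(f"{path}:{lineno}: BEDGraph needs 4 columns")
        try:
            iv = DepthInterval(
                genome_id=row[0],
                start=int(row[1]),
                end=int(row[2]),
                depth=float(row[3]),
            )
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        by_genome.setdefault(iv.genome_id, []).append(iv)

    for gid, ivs in by_genome.items():
        ivs.sort(key=lambda iv: iv.start)
        for a, b in zip(ivs, ivs[1:]):
            if b.start < a.end:
                raise FormatError(
                    f"{path}: overlapping intervals on {gid}: "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )
    return by_genome


def write_depth_track(
    path, intervals: Mapping[str, Sequence[DepthInterval]], header: str | None = None
) -> None:
    with open(path, "w", newline="") as fh:
        if header:
            fh.write(header)
        for gid in sorted(intervals):
            for iv in sorted(intervals[gid], key=lambda x: x.start):
                fh.write(f"{gid}\t{iv.start}\t{iv.end}\t{iv.depth!r}\n")


def _split_dmp(line: str) -> list[str]:
    # dmp dialect: fields separated by "\t|\t", line terminated by "\t|"
    line = line.rstrip("\n")
    if line.endswith("\t|"):
        line = line[: -len("\t|")]
    return line.split("\t|\t")


def read_taxdump(nodes_path, names_path):
    """Parse NCBI-style ``nodes.dmp`` / ``names.dmp`` into a TaxonomyTree.

    Only scientific names are attached. Orphan nodes (parent absent from
    the file) are a validation error listing the offenders.
    """
    from .taxonomy import TaxonomyTree

    parents: dict[int, int] = {}
    ranks: dict[int, str] = {}
    with open(nodes_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = _split_dmp(line)
            if len(parts) < 3:
                raise FormatError(f"{nodes_path}:{lineno}: need taxid|parent|rank")
            try:
                taxid, parent = int(parts[0]), int(parts[1])
            except ValueError as exc:
                raise FormatError(f"{nodes_path}:{lineno}: {exc}") from exc
            parents[taxid] = parent
            ranks[taxid] = parts[2]

    names: dict[int, str] = {}
    with open(names_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = _split_dmp(line)
            if len(parts) < 2:
                raise FormatError(f"{names_path}:{lineno}: need taxid|name")
            if len(parts) >= 4 and parts[3] != "scientific name":
                continue
            try:
                names[int(parts[0])] = parts[1]
            except ValueError as exc:
                raise FormatError(f"{names_path}:{lineno}: {exc}") from exc

    orphans = sorted(t for t, p in parents.items() if p not in parents)
    if orphans:
        raise FormatError(f"{nodes_path}: orphan taxids (parent absent): {orphans}")

    nodes = {
        t: (parents[t], ranks[t], names.get(t, f"taxid_{t}")) for t in parents
    }
    return TaxonomyTree(nodes)


def write_taxdump(tree, nodes_path, names_path) -> None:
    with open(nodes_path, "w") as fh:
        for taxid in sorted(tree.nodes):
            parent, rank, _ = tree.nodes[taxid]
            fh.write(f"{taxid}\t|\t{parent}\t|\t{rank}\t|\n")
    with open(names_path, "w") as fh:
        for taxid in sorted(tree.nodes):
            _, _, name = tree.nodes[taxid]
            fh.write(f"{taxid}\t|\t{name}\t|\t\t|\tscientific name\t|\n")


def read_genome_manifest(path) -> dict[str, int]:
    """Read the genome manifest TSV (genome_id, length_bp)."""
    out: dict[str, int] = {}
    for lineno, row in _open_rows(path):
        if row[0] == "genome_id":
            continue
        if len(row) < 2:
            raise FormatError(f"{path}:{lineno}: manifest needs 2 columns")
        try:
            length = int(row[1])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        if length <= 0:
            raise FormatError(f"{path}:{lineno}: length_bp must be positive")
        out[row[0]] = length
    return out


def write_genome_manifest(path, lengths: Mapping[str, int], header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        fh.write("genome_id\tlength_bp\n")
        for gid in sorted(lengths):
            fh.write(f"{gid}\t{lengths[gid]}\n")


def read_gene_annotations(path) -> list[GeneRecord]:
    """Read the gene annotation TSV; labels are semicolon-joined tags."""
    genes: list[GeneRecord] = []
    seen: dict[str, set[int]] = {}
    for lineno, row in _open_rows(path):
        if row[0] == "gene_id":
            continue
        if len(row) < 5:
            raise FormatError(f"{path}:{lineno}: annotation needs 5 columns")
        try:
            rec = GeneRecord(
                gene_id=row[0],
                parent_id=row[1],
                ordinal=int(row[2]),
                length_bp=int(row[3]),
                labels=frozenset(t for t in row[4].split(";") if t),
            )
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        used = seen.setdefault(rec.parent_id, set())
        if rec.ordinal in used:
            raise FormatError(
                f"{path}:{lineno}: duplicate ordinal {rec.ordinal} on {rec.parent_id}"
            )
        used.add(rec.ordinal)
        genes.append(rec)
    return genes


def write_gene_annotations(path, genes: Iterable[GeneRecord], header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        fh.write("gene_id\tparent_id\tordinal\tlength_bp\tlabels\n")
        for g in genes:
            fh.write(
                f"{g.gene_id}\t{g.parent_id}\t{g.ordinal}\t{g.length_bp}\t"
                f"{';'.join(sorted(g.labels))}\n"
            )


def read_transcript_counts(path) -> dict[str, int]:
    out: dict[str, int] = {}
    for lineno, row in _open_rows(path):
        if row[0] == "gene_id":
            continue
        if len(row) < 2:
            raise FormatError(f"{path}:{lineno}: counts need 2 columns")
        try:
            n = int(row[1])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        if n < 0:
            raise FormatError(f"{path}:{lineno}: negative count")
        out[row[0]] = n
    return out


def write_transcript_counts(path, counts: Mapping[str, int], header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        fh.write("gene_id\tcount\n")
        for gid in sorted(counts):
            fh.write(f"{gid}\t{counts[gid]}\n")


_MICROARRAY_COLUMNS = [
    "sample",
    "extraction",
    "antibody",
    "replicate",
    "signal",
    "is_control",
]


def read_microarray_signals(path) -> pd.DataFrame:
    """Read the long-format microarray signal TSV into a DataFrame.

    Columns: sample, extraction, antibody, replicate (1–4), signal,
    is_control (0/1 flag for standard-control spots).
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in _MICROARRAY_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing microarray columns {missing}")
    if "is_control" not in df.columns:
        df["is_control"] = 0
    if (df["signal"] < 0).any():
        lineno = int(df.index[df["signal"] < 0][0]) + 2  # header + 1-based
        raise FormatError(f"{path}:{lineno}: negative signal")
    if (df["replicate"] > 4).any() or (df["replicate"] < 1).any():
        raise FormatError(f"{path}: replicate index outside 1–4")
    return df[_MICROARRAY_COLUMNS]


def write_microarray_signals(path, df: pd.DataFrame, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        df.to_csv(fh, sep="\t", index=False, columns=_MICROARRAY_COLUMNS)
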