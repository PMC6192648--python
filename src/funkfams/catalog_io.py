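"""Readers and writers for the external formats the pipeline consumes and emits.

The pipeline touches five kinds of files:

* a protein-family catalog: amino-acid multi-FASTA plus a tab-separated
  membership table mapping each sequence to its family, source taxon and
  start/stop-codon flags;
* a flattened taxonomy lineage table (taxon id -> named ranks);
* one or more annotation databases: FASTA of annotated proteins plus a TSV of
  domain accessions per sequence;
* per-sample read alignments in 12-column BLAST tabular format (outfmt 6,
  a.k.a. "m8");
* a sample-metadata table carrying environment labels, covariates, read
  lengths and genome equivalents.

All TSVs are UTF-8, tab-separated, header-first, unquoted.  Readers validate
strictly and raise :class:`ValidationError` rather than skipping malformed
lines: silent data loss would corrupt every downstream count.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "RANKS",
    "ValidationError",
    "SequenceRecord",
    "LineageRecord",
    "AnnotationRecord",
    "AlignmentHit",
    "SampleRecord",
    "FamilyReport",
    "normalize_aa",
    "read_family_catalog",
    "read_lineage_table",
    "read_annotation_db",
    "read_m8",
    "read_sample_metadata",
    "sample_records",
    "write_catalog_report",
    "read_catalog_report",
]

#: Named taxonomic ranks, most specific first.
RANKS = ("species", "genus", "family", "order", "class", "phylum", "kingdom", "domain")

# IUPAC one-letter amino-acid codes including ambiguity/rare codes.
_AA_LETTERS = frozenset("ACDEFGHIKLMNPQRSTVWYBXZJUO")


class ValidationError(ValueError):
    """An input file violates the format contract."""


def normalize_aa(raw: str) -> str:
    """Normalize an amino-acid sequence: uppercase, strip one trailing ``*``.

    A stop symbol is permitted only as the final character (translation
    artifacts commonly carry it); an internal ``*`` usually indicates a
    pseudogene or frameshift and is rejected.  Normalization is idempotent.
    """
    seq = raw.strip().upper()
    if seq.endswith("*"):
        seq = seq[:-1]
    if not seq:
        raise ValidationError("empty amino-acid sequence")
    if "*" in seq:
        raise ValidationError(f"internal stop symbol '*' in sequence {seq[:30]!r}...")
    bad = set(seq) - _AA_LETTERS
    if bad:
        raise ValidationError(f"non-IUPAC amino-acid letters {sorted(bad)} in sequence")
    return seq


@dataclass(frozen=True)
class SequenceRecord:
    """One catalog protein: sequence plus membership metadata."""

    seq_id: str
    aa_seq: str
    family_id: str
    taxon_id: str
    has_start: bool
    has_stop: bool

    @property
    def truncated(self) -> bool:
        """A member is truncated iff it lacks a start or a stop codon."""
        return not (self.has_start and self.has_stop)


@dataclass(frozen=True)
class LineageRecord:
    """Named taxa at the eight ranks for one source taxon; missing ranks are None."""

    taxon_id: str
    ranks: Mapping[str, str | None]

    def __post_init__(self) -> None:
        extra = set(self.ranks) - set(RANKS)
        if extra:
            raise ValidationError(f"unknown rank names {sorted(extra)}")


@dataclass(frozen=True)
class AnnotationRecord:
    """One annotated protein from an annotation database."""

    db_name: str
    seq_id: str
    aa_seq: str
    domain_accessions: tuple[str, ...]


@dataclass(frozen=True)
class AlignmentHit:
    """One row of a 12-column BLAST tabular alignment report."""

    read_id: str
    subject_id: str
    pct_identity: float
    align_len: int
    evalue: float
    bit_score: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.pct_identity <= 100.0):
            raise ValidationError(f"pct_identity {self.pct_identity} outside [0, 100]")
        if self.align_len < 1:
            raise ValidationError(f"align_len {self.align_len} < 1")
        if not math.isfinite(self.bit_score):
            raise ValidationError("non-finite bit score")


@dataclass(frozen=True)
class SampleRecord:
    """Metadata for one metagenome sample.

    ``genome_equivalents`` (library depth / average genome size, from an
    upstream estimator) is consumed, never computed here.
    """

    sample_id: str
    environment: str
    read_length: int
    genome_equivalents: float
    covariates: Mapping[str, object] = field(default_factory=dict)
    stratum: str = ""

    def __post_init__(self) -> None:
        if self.genome_equivalents <= 0:
            raise ValidationError(f"{self.sample_id}: genome_equivalents must be > 0")
        if self.read_length <= 0:
            raise ValidationError(f"{self.sample_id}: read_length must be > 0")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

_MEMBERSHIP_COLS = ("seq_id", "family_id", "taxon_id", "has_start", "has_stop")


def _parse_bool01(value: str, *, context: str) -> bool:
    if value == "1":
        return True
    if value == "0":
        return False
    raise ValidationError(f"{context}: boolean flag must be 0 or 1, got {value!r}")


def read_family_catalog(
    fasta_path: str | Path, membership_tsv_path: str | Path
) -> dict[str, list[SequenceRecord]]:
    """Read a protein-family catalog (FASTA + membership TSV).

    Returns families keyed by ``family_id`` in lexicographic order; members
    keep FASTA file order.  Every FASTA id must appear in the membership
    table and vice versa; duplicate ids are rejected.
    """
    meta: dict[str, tuple[str, str, bool, bool]] = {}
    with open(membership_tsv_path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or tuple(header) != _MEMBERSHIP_COLS:
            raise ValidationError(
                f"membership table header must be {list(_MEMBERSHIP_COLS)}, got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if len(row) != len(_MEMBERSHIP_COLS):
                raise ValidationError(f"membership line {lineno}: expected 5 columns")
            seq_id, family_id, taxon_id, start_s, stop_s = row
            if seq_id in meta:
                raise ValidationError(f"duplicate seq_id {seq_id!r} in membership table")
            meta[seq_id] = (
                family_id,
                taxon_id,
                _parse_bool01(start_s, context=f"line {lineno} has_start"),
                _parse_bool01(stop_s, context=f"line {lineno} has_stop"),
            )

    families: dict[str, list[SequenceRecord]] = {}
    seen: set[str] = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seen:
            raise ValidationError(f"duplicate seq_id {rec.id!r} in FASTA")
        seen.add(rec.id)
        if rec.id not in meta:
            raise ValidationError(f"FASTA id {rec.id!r} absent from membership table")
        family_id, taxon_id, has_start, has_stop = meta[rec.id]
        families.setdefault(family_id, []).append(
            SequenceRecord(
                seq_id=rec.id,
                aa_seq=normalize_aa(str(rec.seq)),
                family_id=family_id,
                taxon_id=taxon_id,
                has_start=has_start,
                has_stop=has_stop,
            )
        )
    missing = set(meta) - seen
    if missing:
        raise ValidationError(
            f"membership seq_id {sorted(missing)[0]!r} absent from FASTA"
        )
    return dict(sorted(families.items()))


def read_lineage_table(tsv_path: str | Path) -> dict[str, LineageRecord]:
    """Read a flattened lineage table: ``taxon_id`` plus the eight rank columns.

    Blank cells become ``None`` (explicitly unknown), never empty strings.
    """
    lineages: dict[str, LineageRecord] = {}
    with open(tsv_path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or header[0] != "taxon_id":
            raise ValidationError("lineage table must start with a taxon_id column")
        rank_cols = header[1:]
        unknown = set(rank_cols) - set(RANKS)
        if unknown:
            raise ValidationError(f"unknown rank column(s) {sorted(unknown)}")
        if set(rank_cols) != set(RANKS):
            raise ValidationError(
                f"lineage header must name all eight ranks, missing {sorted(set(RANKS) - set(rank_cols))}"
            )
        for lineno, row in enumerate(reader, start=2):
            if len(row) != len(header):
                raise ValidationError(f"lineage line {lineno}: wrong column count")
            taxon_id = row[0]
            if taxon_id in lineages:
                raise ValidationError(f"duplicate taxon_id {taxon_id!r} in lineage table")
            ranks = {
                rank: (cell if cell != "" else None)
                for rank, cell in zip(rank_cols, row[1:])
            }
            lineages[taxon_id] = LineageRecord(taxon_id=taxon_id, ranks=ranks)
    return lineages


def read_annotation_db(
    fasta_path: str | Path, tsv_path: str | Path, db_name: str
) -> list[AnnotationRecord]:
    """Read an annotation database: protein FASTA + TSV of domain accessions.

    The TSV has columns ``seq_id`` and ``domain_accessions`` (comma-separated,
    possibly blank: a database entry with no assigned domains).
    """
    accessions: dict[str, tuple[str, ...]] = {}
    with open(tsv_path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or tuple(header) != ("seq_id", "domain_accessions"):
            raise ValidationError(
                f"annotation table header must be ['seq_id', 'domain_accessions'], got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if len(row) != 2:
                raise ValidationError(f"annotation line {lineno}: expected 2 columns")
            seq_id, acc_s = row
            if seq_id in accessions:
                raise ValidationError(f"duplicate seq_id {seq_id!r} in annotation table")
            accessions[seq_id] = tuple(a for a in acc_s.split(",") if a)

    records: list[AnnotationRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seen:
            raise ValidationError(f"duplicate seq_id {rec.id!r} in annotation FASTA")
        seen.add(rec.id)
        if rec.id not in accessions:
            raise ValidationError(f"annotation FASTA id {rec.id!r} absent from TSV")
        records.append(
            AnnotationRecord(
                db_name=db_name,
                seq_id=rec.id,
                aa_seq=normalize_aa(str(rec.seq)),
                domain_accessions=accessions[rec.id],
            )
        )
    missing = set(accessions) - seen
    if missing:
        raise ValidationError(f"annotation seq_id {sorted(missing)[0]!r} absent from FASTA")
    return records


def read_m8(path: str | Path) -> Iterator[AlignmentHit]:
    """Stream alignment hits from a BLAST tabular (outfmt 6 / m8) file.

    Requires >= 12 tab-separated columns; columns 1, 2, 3, 4, 11, 12 are
    query, subject, percent identity, alignment length, e-value and bit
    score.  Extra columns are ignored.  Malformed rows raise with the line
    number rather than being skipped.
    """
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise ValidationError(f"{path}:{lineno}: expected >=12 columns, got {len(cols)}")
            try:
                hit = AlignmentHit(
                    read_id=cols[0],
                    subject_id=cols[1],
                    pct_identity=float(cols[2]),
                    align_len=int(cols[3]),
                    evalue=float(cols[10]),
                    bit_score=float(cols[11]),
                )
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
            yield hit


_SAMPLE_REQUIRED = ("sample_id", "environment", "read_length", "genome_equivalents")


def read_sample_metadata(tsv_path: str | Path) -> pd.DataFrame:
    """Read sample metadata into a DataFrame indexed by ``sample_id``.

    Required columns: sample_id, environment, read_length,
    genome_equivalents.  Any remaining columns are covariates or stratum
    labels and are passed through untouched (numeric columns coerced).
    """
    df = pd.read_csv(tsv_path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in _SAMPLE_REQUIRED if c not in df.columns]
    if missing:
        raise ValidationError(f"sample metadata missing column(s) {missing}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValidationError(f"duplicate sample_id {dup!r}")
    if (df["genome_equivalents"] <= 0).any():
        raise ValidationError("genome_equivalents must be > 0 for every sample")
    if (df["read_length"] <= 0).any():
        raise ValidationError("read_length must be > 0 for every sample")
    return df.set_index("sample_id")


def sample_records(metadata: pd.DataFrame, stratum_var: str = "environment") -> list[SampleRecord]:
    """Materialize :class:`SampleRecord` objects from a metadata frame."""
    extra = [c for c in metadata.columns if c not in _SAMPLE_REQUIRED]
    out = []
    for sample_id, row in metadata.iterrows():
        out.append(
            SampleRecord(
                sample_id=str(sample_id),
                environment=str(row["environment"]),
                read_length=int(row["read_length"]),
                genome_equivalents=float(row["genome_equivalents"]),
                covariates={c: row[c] for c in extra},
                stratum=str(row[stratum_var]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# catalog report
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FamilyReport:
    """One catalog-report row: filter outcome, annotation status and breadth."""

    family_id: str
    n_members: int
    n_unique: int
    pass_filter: bool
    annotated: bool
    breadth: Mapping[str, int] | None
    is_funkfam: bool


_RANK_PLURAL = {
    "species": "species",
    "genus": "genera",
    "family": "families",
    "order": "orders",
    "class": "classes",
    "phylum": "phyla",
    "kingdom": "kingdoms",
    "domain": "domains",
}

_REPORT_COLS = (
    "family_id",
    "n_members",
    "n_unique",
    "pass_filter",
    "annotated",
    *[f"n_{_RANK_PLURAL[r]}" for r in RANKS],
    "is_funkfam",
)


def write_catalog_report(records: Sequence[FamilyReport], path: str | Path) -> None:
    """Write the per-family summary table (one row per family).

    Re-reading with :func:`read_catalog_report` reproduces the records.
    Records must carry a breadth profile; a missing one is an upstream bug,
    not a value to silently zero-fill.
    """
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_REPORT_COLS)
        for rec in records:
            if rec.breadth is None:
                raise ValidationError(f"family {rec.family_id}: missing breadth profile")
            missing = set(RANKS) - set(rec.breadth)
            if missing:
                raise ValidationError(
                    f"family {rec.family_id}: breadth profile missing ranks {sorted(missing)}"
                )
            writer.writerow(
                [
                    rec.family_id,
                    rec.n_members,
                    rec.n_unique,
                    int(rec.pass_filter),
                    int(rec.annotated),
                    *[rec.breadth[r] for r in RANKS],
                    int(rec.is_funkfam),
                ]
            )


def read_catalog_report(path: str | Path) -> list[FamilyReport]:
    """Inverse of :func:`write_catalog_report` on its column set."""
    records: list[FamilyReport] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or tuple(header) != _REPORT_COLS:
            raise ValidationError(f"unexpected catalog report header {header}")
        for row in reader:
            records.append(
                FamilyReport(
                    family_id=row[0],
                    n_members=int(row[1]),
                    n_unique=int(row[2]),
                    pass_filter=bool(int(row[3])),
                    annotated=bool(int(row[4])),
                    breadth={r: int(v) for r, v in zip(RANKS, row[5:13])},
                    is_funkfam=bool(int(row[13])),
                )
            )
    return records
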