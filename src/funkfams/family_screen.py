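"""Family quality filters and exact-match annotation screening.

A family enters downstream analysis only if it looks like a *bona fide*
full-length protein family: at least ``min_unique`` distinct member
sequences (default 3) and at most half of its members truncated (missing a
start or stop codon; the truncated fraction must not exceed 50%, strictly).

Annotation status is decided by exact full-length sequence identity against
one or more annotation databases.  Because catalog families derive from
reference genomes whose proteomes have already been processed into those
databases, a family member that carries any curated domain will be present
*verbatim*; a 100%-identity full-length match is therefore realized as a
hash lookup on the normalized sequence, which is bit-exact and needs no
external aligner.  Searching for non-exact homologs is a different problem
and is deliberately not supported here.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .catalog_io import AnnotationRecord, SequenceRecord

__all__ = [
    "ConfigurationError",
    "FilterReason",
    "FilterDecision",
    "AnnotationIndex",
    "AnnotationStatus",
    "count_unique",
    "filter_family",
    "build_annotation_index",
    "annotation_status",
]


class ConfigurationError(ValueError):
    """A threshold or mode parameter is outside its documented range."""


class FilterReason(str, Enum):
    TOO_FEW_UNIQUE = "TOO_FEW_UNIQUE"
    TOO_MANY_TRUNCATED = "TOO_MANY_TRUNCATED"


@dataclass(frozen=True)
class FilterDecision:
    family_id: str
    n_members: int
    n_unique: int
    frac_truncated: float
    passed: bool
    reasons: tuple[FilterReason, ...]


@dataclass(frozen=True)
class AnnotationIndex:
    """Exact-lookup index: normalized amino-acid sequence -> database records."""

    db_name: str
    lookup: Mapping[str, tuple[AnnotationRecord, ...]]

    def __len__(self) -> int:
        return len(self.lookup)


@dataclass(frozen=True)
class AnnotationStatus:
    """Exact-match hits per database and the derived annotated flag.

    ``annotated`` is true iff at least one hit carries a non-empty domain
    accession list.  A hit whose database entry has *no* domains (e.g. a
    protein deposited only as "hypothetical") is recorded for transparency
    but does not count as annotation.
    """

    family_id: str
    hits: Mapping[str, tuple[tuple[str, str, tuple[str, ...]], ...]]
    annotated: bool


def count_unique(members: Sequence[SequenceRecord]) -> int:
    """Number of distinct normalized member sequences."""
    if not members:
        raise ValueError("count_unique: empty member list")
    return len({m.aa_seq for m in members})


def filter_family(
    members: Sequence[SequenceRecord],
    min_unique: int = 3,
    max_truncated_frac: float = 0.5,
) -> FilterDecision:
    """Apply the two family-quality filters.

    Fails with ``TOO_FEW_UNIQUE`` if the family has fewer than ``min_unique``
    distinct sequences, and with ``TOO_MANY_TRUNCATED`` if *more than*
    ``max_truncated_frac`` of members lack a start or stop codon (strict
    inequality: a family with exactly half its members truncated passes).
    """
    if min_unique < 1:
        raise ConfigurationError(f"min_unique must be >= 1, got {min_unique}")
    if not (0.0 <= max_truncated_frac <= 1.0):
        raise ConfigurationError(
            f"max_truncated_frac must be in [0, 1], got {max_truncated_frac}"
        )
    if not members:
        raise ValueError("filter_family: empty member list")

    n_members = len(members)
    n_unique = count_unique(members)
    frac_truncated = sum(m.truncated for m in members) / n_members

    reasons: list[FilterReason] = []
    if n_unique < min_unique:
        reasons.append(FilterReason.TOO_FEW_UNIQUE)
    if frac_truncated > max_truncated_frac:
        reasons.append(FilterReason.TOO_MANY_TRUNCATED)

    return FilterDecision(
        family_id=members[0].family_id,
        n_members=n_members,
        n_unique=n_unique,
        frac_truncated=frac_truncated,
        passed=not reasons,
        reasons=tuple(reasons),
    )


def build_annotation_index(records: Iterable[AnnotationRecord]) -> AnnotationIndex:
    """Index annotation records by exact normalized sequence.

    Distinct database entries sharing one sequence are kept as a list under
    the shared key.  All records must come from a single database.
    """
    records = list(records)
    db_names = {r.db_name for r in records}
    if len(db_names) > 1:
        raise ValueError(f"mixed db_name in one index: {sorted(db_names)}")
    db_name = db_names.pop() if db_names else ""
    lookup: dict[str, list[AnnotationRecord]] = {}
    for rec in records:
        lookup.setdefault(rec.aa_seq, []).append(rec)
    return AnnotationIndex(
        db_name=db_name, lookup={k: tuple(v) for k, v in lookup.items()}
    )


def annotation_status(
    members: Sequence[SequenceRecord], indexes: Sequence[AnnotationIndex]
) -> AnnotationStatus:
    """Determine whether any family member has any annotated domain.

    A member matches a database entry iff their normalized sequences are
    byte-identical (100% identity over the full length).  The family is
    annotated iff any match carries at least one domain accession.
    """
    if not members:
        raise ValueError("annotation_status: empty member list")
    hits: dict[str, list[tuple[str, str, tuple[str, ...]]]] = {}
    annotated = False
    for index in indexes:
        for member in members:
            for rec in index.lookup.get(member.aa_seq, ()):
                hits.setdefault(index.db_name, []).append(
                    (member.seq_id, rec.seq_id, rec.domain_accessions)
                )
                if rec.domain_accessions:
                    annotated = True
    return AnnotationStatus(
        family_id=members[0].family_id,
        hits={k: tuple(v) for k, v in hits.items()},
        annotated=annotated,
    )
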