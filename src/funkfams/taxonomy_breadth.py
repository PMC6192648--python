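"""Phylogenetic breadth of protein families and FUnkFam selection.

Each family member carries the taxonomy of the genome it derives from.  A
family's breadth at a rank is the number of *distinct named taxa* among its
members at that rank: two genomes sharing a class name count once, and a
member whose lineage is unknown (or null at a rank) contributes nothing.
With complete lineages the counts are non-increasing from species up to
domain.

A FUnkFam (Function Unknown Family) is a family that passed the quality
filters, has no exact-match domain annotation, and spans at least
``min_distinct`` taxa (default 2) at the selection rank (default class).
Selected families are ranked by breadth — lexicographically on (distinct
domains, phyla, classes, number of unique sequences), descending — to put
the most phylogenetically widespread unknowns at the top of the list.  The
ranking score is this package's own convention and is labeled as such in
output headers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .catalog_io import RANKS, LineageRecord, SequenceRecord
from .family_screen import AnnotationStatus, ConfigurationError, FilterDecision

__all__ = [
    "BreadthProfile",
    "FamilySummary",
    "FunkFamSelection",
    "breadth_profile",
    "select_funkfams",
    "breadth_histogram",
]


@dataclass(frozen=True)
class BreadthProfile:
    family_id: str
    distinct: Mapping[str, int]
    n_members_with_lineage: int


@dataclass(frozen=True)
class FamilySummary:
    """Per-family bundle of screen outputs, the input unit for selection."""

    family_id: str
    decision: FilterDecision
    status: AnnotationStatus
    breadth: BreadthProfile


@dataclass(frozen=True)
class FunkFamSelection:
    family_id: str
    is_funkfam: bool
    rank_used: str
    distinct_at_rank: int
    rank_score: tuple[int, int, int, int]


def breadth_profile(
    members: Sequence[SequenceRecord],
    lineages: Mapping[str, LineageRecord],
) -> BreadthProfile:
    """Count distinct named taxa per rank among a family's members.

    Members whose taxon id is absent from the lineage table are tolerated;
    they simply contribute to no rank and are reported via
    ``n_members_with_lineage``.
    """
    per_rank: dict[str, set[str]] = {rank: set() for rank in RANKS}
    n_with = 0
    for member in members:
        lineage = lineages.get(member.taxon_id)
        if lineage is None:
            continue
        n_with += 1
        for rank in RANKS:
            name = lineage.ranks.get(rank)
            if name is not None:
                per_rank[rank].add(name)
    return BreadthProfile(
        family_id=members[0].family_id if members else "",
        distinct={rank: len(per_rank[rank]) for rank in RANKS},
        n_members_with_lineage=n_with,
    )


def select_funkfams(
    catalog: Sequence[FamilySummary],
    rank: str = "class",
    min_distinct: int = 2,
) -> list[FunkFamSelection]:
    """Select and rank FUnkFams.

    ``is_funkfam`` iff the family passed the quality filters, is not
    annotated, and spans >= ``min_distinct`` distinct taxa at ``rank``.
    Output is sorted by rank score descending with family id as the final,
    deterministic tiebreak, so reruns and member-order permutations yield
    identical lists.
    """
    if rank not in RANKS:
        raise ConfigurationError(f"unknown rank {rank!r}; must be one of {list(RANKS)}")
    if min_distinct < 1:
        raise ConfigurationError(f"min_distinct must be >= 1, got {min_distinct}")

    selections = []
    for fam in catalog:
        distinct_at_rank = fam.breadth.distinct[rank]
        is_funkfam = (
            fam.decision.passed
            and not fam.status.annotated
            and distinct_at_rank >= min_distinct
        )
        score = (
            fam.breadth.distinct["domain"],
            fam.breadth.distinct["phylum"],
            fam.breadth.distinct["class"],
            fam.decision.n_unique,
        )
        selections.append(
            FunkFamSelection(
                family_id=fam.family_id,
                is_funkfam=is_funkfam,
                rank_used=rank,
                distinct_at_rank=distinct_at_rank,
                rank_score=score,
            )
        )
    selections.sort(key=lambda s: (tuple(-x for x in s.rank_score), s.family_id))
    return selections


def breadth_histogram(
    selections: Sequence[FunkFamSelection],
    breadths: Mapping[str, BreadthProfile],
    ranks: Sequence[str] = ("domain", "phylum", "class"),
    min_distinct: int = 2,
) -> dict[str, int]:
    """Count FUnkFams spanning >= ``min_distinct`` taxa at each rank.

    Only selected families (``is_funkfam``) are counted; at the default
    selection threshold every FUnkFam spans >= 2 classes by definition, so
    the class entry equals the number of FUnkFams.
    """
    out: dict[str, int] = {}
    funk = [s for s in selections if s.is_funkfam]
    for rank in ranks:
        if rank not in RANKS:
            raise ConfigurationError(f"unknown rank {rank!r}")
        out[rank] = sum(
            1 for s in funk if breadths[s.family_id].distinct[rank] >= min_distinct
        )
    return out
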