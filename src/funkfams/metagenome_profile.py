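"""From per-sample read alignments to presence, abundance and ecology.

Reads are recruited to protein families from BLAST/Diamond tabular output:
each read keeps only its best hit (highest bit score, ties broken by lower
e-value then lexicographically smallest subject id), and the hit counts for
its family only if it has at least ``min_identity`` percent identity
(default 99.0) over the whole read — operationalized as an alignment length
of at least the sample's read length, since the 12-column tabular format
does not carry query coverage.

A family is *present* in a sample iff it recruits at least one accepted
read.  Abundance is RPKG — reads per kilobase of gene per genome
equivalent::

    rpkg[f, s] = counts[f, s] / (mean_member_len_aa[f] * 3 / 1000) / genome_equivalents[s]

which normalizes for family length (mean member protein length, converted
to kilobases of coding DNA) and for sequencing effort scaled by average
genome size (genome equivalents are a required metadata column, estimated
upstream).

Ecology summaries: per-environment prevalence, binary presence entropy
(used to pre-filter families with too little variation to test), a
phylum-breadth pre-filter, and Bray-Curtis dissimilarity between samples
with a within/between-environment comparison backed by a one-sided
Mann-Whitney U test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis as _sp_braycurtis
from scipy.spatial.distance import pdist, squareform
from scipy.stats import mannwhitneyu

from .catalog_io import AlignmentHit
from .family_screen import ConfigurationError
from .taxonomy_breadth import BreadthProfile, FunkFamSelection

__all__ = [
    "ReadAssignment",
    "PresenceAbundance",
    "BetaDiversityGroups",
    "best_hit_per_read",
    "call_presence",
    "profile_samples",
    "mean_family_length_aa",
    "rpkg",
    "prevalence",
    "presence_entropy",
    "entropy_filter",
    "phylum_filter",
    "bray_curtis",
    "bray_curtis_matrix",
    "beta_diversity_groups",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReadAssignment:
    read_id: str
    family_id: str
    best_hit: AlignmentHit
    accepted: bool


@dataclass(frozen=True)
class PresenceAbundance:
    """Family x sample matrices: read counts, presence calls and RPKG."""

    counts: pd.DataFrame
    presence: pd.DataFrame
    rpkg: pd.DataFrame
    family_mean_len_aa: Mapping[str, float]


@dataclass(frozen=True)
class BetaDiversityGroups:
    """Off-diagonal Bray-Curtis values split within/between two environments."""

    within_a: np.ndarray
    within_b: np.ndarray
    between: np.ndarray
    environments: tuple[str, str]
    p_value: float


def best_hit_per_read(
    hits: Iterable[AlignmentHit], subject_to_family: Mapping[str, str]
) -> list[ReadAssignment]:
    """Keep one hit per read: max bit score, then min e-value, then smallest subject id.

    Hits whose subject is not in ``subject_to_family`` are dropped (their
    count is logged); a read with no mappable hit yields no assignment.
    Assignments are returned with ``accepted=False``; acceptance is decided
    by :func:`call_presence` where the sample's read length is known.
    """
    best: dict[str, AlignmentHit] = {}
    order: list[str] = []
    n_unmapped = 0
    for hit in hits:
        if hit.subject_id not in subject_to_family:
            n_unmapped += 1
            continue
        prev = best.get(hit.read_id)
        if prev is None:
            best[hit.read_id] = hit
            order.append(hit.read_id)
        elif (-hit.bit_score, hit.evalue, hit.subject_id) < (
            -prev.bit_score,
            prev.evalue,
            prev.subject_id,
        ):
            best[hit.read_id] = hit
    if n_unmapped:
        logger.info("dropped %d hit(s) to subjects outside the catalog", n_unmapped)
    return [
        ReadAssignment(
            read_id=rid,
            family_id=subject_to_family[best[rid].subject_id],
            best_hit=best[rid],
            accepted=False,
        )
        for rid in order
    ]


def call_presence(
    assignments: Sequence[ReadAssignment],
    read_length: int,
    min_identity: float = 99.0,
) -> dict[str, int]:
    """Tally accepted reads per family for one sample.

    A read counts iff its best hit has ``pct_identity >= min_identity`` and
    an alignment spanning the whole read (``align_len >= read_length``).
    Presence is count >= 1.
    """
    if read_length is None or read_length <= 0:
        raise ValueError(f"read_length must be a positive integer, got {read_length}")
    counts: dict[str, int] = {}
    for a in assignments:
        hit = a.best_hit
        if hit.pct_identity >= min_identity and hit.align_len >= read_length:
            counts[a.family_id] = counts.get(a.family_id, 0) + 1
    return counts


def mean_family_length_aa(
    families: Mapping[str, Sequence]
) -> dict[str, float]:
    """Mean member protein length (amino acids) per family."""
    return {
        fid: float(np.mean([len(m.aa_seq) for m in members]))
        for fid, members in families.items()
    }


def profile_samples(
    per_sample_hits: Mapping[str, Iterable[AlignmentHit]],
    subject_to_family: Mapping[str, str],
    metadata: pd.DataFrame,
    family_mean_len_aa: Mapping[str, float],
    min_identity: float = 99.0,
) -> PresenceAbundance:
    """Build the family x sample count/presence/RPKG matrices.

    ``metadata`` is indexed by sample id and supplies ``read_length`` and
    ``genome_equivalents``.  Every family in ``family_mean_len_aa`` gets a
    row (zero-filled where no reads were recruited); samples follow the
    metadata order.
    """
    sample_ids = list(metadata.index)
    family_ids = sorted(family_mean_len_aa)
    counts = pd.DataFrame(0, index=family_ids, columns=sample_ids, dtype=int)
    for sid in sample_ids:
        hits = per_sample_hits.get(sid, ())
        assignments = best_hit_per_read(hits, subject_to_family)
        tally = call_presence(
            assignments,
            read_length=int(metadata.loc[sid, "read_length"]),
            min_identity=min_identity,
        )
        for fid, n in tally.items():
            if fid in counts.index:
                counts.loc[fid, sid] = n
    presence = counts >= 1
    rpkg_df = rpkg(counts, family_mean_len_aa, metadata["genome_equivalents"])
    return PresenceAbundance(
        counts=counts,
        presence=presence,
        rpkg=rpkg_df,
        family_mean_len_aa=dict(family_mean_len_aa),
    )


def rpkg(
    counts: pd.DataFrame,
    family_mean_len_aa: Mapping[str, float],
    genome_equivalents: pd.Series,
) -> pd.DataFrame:
    """Reads per kilobase of gene per genome equivalent.

    Family length is the mean member protein length in amino acids times 3
    (nucleotides per codon), expressed in kb; dividing by the sample's
    genome equivalents makes abundances comparable across samples.
    """
    ge = genome_equivalents.reindex(counts.columns)
    if ge.isna().any():
        missing = list(ge.index[ge.isna()])
        raise ValueError(f"missing genome_equivalents for sample(s) {missing}")
    if (ge <= 0).any():
        bad = list(ge.index[ge <= 0])
        raise ValueError(f"genome_equivalents must be > 0; offending sample(s) {bad}")
    len_kb = pd.Series(
        {fid: family_mean_len_aa[fid] * 3.0 / 1000.0 for fid in counts.index}
    )
    return counts.div(len_kb, axis=0).div(ge, axis=1)


def prevalence(
    presence: pd.DataFrame, sample_environments: pd.Series
) -> pd.DataFrame:
    """Fraction of each environment's samples in which each family is present.

    Returns a family x environment frame; environments with zero samples do
    not appear.
    """
    envs = sample_environments.reindex(presence.columns)
    out = {}
    for env in sorted(envs.dropna().unique()):
        cols = envs.index[envs == env]
        out[env] = presence[cols].mean(axis=1)
    return pd.DataFrame(out)


def presence_entropy(presence: pd.DataFrame | pd.Series) -> pd.Series | float:
    """Binary Shannon entropy (bits) of each family's presence pattern.

    H(p) = -p log2 p - (1-p) log2 (1-p), with p the presence fraction over
    all samples and 0 log 0 taken as 0; maximal (1 bit) at 50% prevalence.
    """
    if isinstance(presence, pd.Series):
        return float(_binary_entropy(np.array([presence.mean()]))[0])
    if presence.shape[1] < 1:
        raise ValueError("presence matrix has no samples")
    p = presence.mean(axis=1).to_numpy(dtype=float)
    return pd.Series(_binary_entropy(p), index=presence.index)


def _binary_entropy(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    for q in (p, 1.0 - p):
        mask = q > 0
        out[mask] -= q[mask] * np.log2(q[mask])
    return out


def entropy_filter(
    entropies: Mapping[str, float] | pd.Series, top_fraction: float = 0.25
) -> set[str]:
    """Retain families whose entropy reaches the top ``top_fraction`` quantile.

    The threshold is the (1 - top_fraction) empirical quantile (linear
    interpolation); families tied with the threshold are retained.  This
    drops families whose presence pattern is too uniform (all-present or
    all-absent) to carry association signal.
    """
    if not (0.0 < top_fraction <= 1.0):
        raise ConfigurationError(f"top_fraction must be in (0, 1], got {top_fraction}")
    series = pd.Series(entropies, dtype=float)
    if series.empty:
        raise ValueError("entropy_filter: empty entropy map")
    threshold = float(np.quantile(series.to_numpy(), 1.0 - top_fraction))
    return set(series.index[series >= threshold])


def phylum_filter(
    selections: Sequence[FunkFamSelection],
    breadths: Mapping[str, BreadthProfile],
    min_phyla: int = 2,
) -> set[str]:
    """Keep selected families whose members span >= ``min_phyla`` phyla."""
    return {
        s.family_id
        for s in selections
        if s.is_funkfam and breadths[s.family_id].distinct["phylum"] >= min_phyla
    }


def bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    """Bray-Curtis dissimilarity: 1 - 2 sum(min(x, y)) / (sum x + sum y).

    0 means identical composition, 1 means no shared families.  Undefined
    (error) when both vectors are all zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("bray_curtis: vectors must have equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("bray_curtis: abundances must be non-negative")
    if x.sum() == 0 and y.sum() == 0:
        raise ValueError("bray_curtis: undefined for two all-zero vectors")
    return float(_sp_braycurtis(x, y))


def bray_curtis_matrix(abundance: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis over samples (columns of a family x sample frame)."""
    zero = abundance.sum(axis=0) == 0
    if zero.any():
        raise ValueError(
            f"bray_curtis_matrix: all-zero sample(s) {list(abundance.columns[zero])}"
        )
    mat = squareform(pdist(abundance.T.to_numpy(dtype=float), metric="braycurtis"))
    return pd.DataFrame(mat, index=abundance.columns, columns=abundance.columns)


def beta_diversity_groups(
    bc_matrix: pd.DataFrame, sample_environments: pd.Series
) -> BetaDiversityGroups:
    """Split sample-pair dissimilarities into within-A, within-B and between.

    Also tests (one-sided Mann-Whitney U) whether between-environment
    dissimilarity stochastically exceeds the pooled within-environment
    dissimilarity.  An environment with fewer than two samples contributes
    an empty within-group distribution; the p-value is NaN when either the
    between or the pooled-within group is empty.
    """
    envs = sample_environments.reindex(bc_matrix.index)
    labels = sorted(envs.dropna().unique())
    if not 1 <= len(labels) <= 2:
        raise ValueError(f"expected one or two environments, got {labels}")
    env_a = labels[0]
    env_b = labels[1] if len(labels) == 2 else labels[0]
    ids = list(bc_matrix.index)
    within_a, within_b, between = [], [], []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            value = float(bc_matrix.iloc[i, j])
            ei, ej = envs.iloc[i], envs.iloc[j]
            if ei == ej == env_a:
                within_a.append(value)
            elif ei == ej == env_b:
                within_b.append(value)
            else:
                between.append(value)
    pooled_within = within_a + within_b
    if between and pooled_within:
        p_value = float(
            mannwhitneyu(between, pooled_within, alternative="greater").pvalue
        )
    else:
        p_value = float("nan")
    return BetaDiversityGroups(
        within_a=np.asarray(within_a),
        within_b=np.asarray(within_b),
        between=np.asarray(between),
        environments=(env_a, env_b),
        p_value=p_value,
    )
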