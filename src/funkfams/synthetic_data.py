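"""Seeded generator of complete, internally consistent pipeline fixtures.

Emits every input the pipeline consumes — protein-family catalog (FASTA +
membership TSV), lineage table, an annotation database, per-sample m8
alignment files and sample metadata — together with a ground-truth manifest
recording what was planted: each family's expected filter decision,
annotation flag, breadth counts and FUnkFam status; each (family, sample)
accepted read count; and the planted presence-covariate effects.

Families are planted into four classes: pass+annotated (one member copied
verbatim into the annotation database with a domain accession),
pass+unannotated+broad (the planted FUnkFams, spanning >= 2 classes in
>= 2 phyla), pass+unannotated+narrow (single class), and fail (too few
unique sequences or too many truncated members).

Member sequences are point-mutated copies of a random family ancestor; no
evolutionary realism is attempted, because no pipeline operation measures
similarity except exact equality.  Metagenome presence is drawn from a
logistic model with the planted covariate effects; accepted reads have
>= 99% identity over the whole read, and decoy hits (sub-threshold
identity, short alignments, unknown subjects, duplicate lower-scoring
rows) are injected and must never change a count.

Everything derives from a single integer seed: the same seed yields
byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog_io import RANKS

__all__ = [
    "AA_ALPHABET",
    "PlantedEffect",
    "SimConfig",
    "GroundTruth",
    "generate_catalog",
    "generate_metagenomes",
    "generate_all",
    "simulate_presence",
]

#: The 20 standard amino acids; sequences are drawn i.i.d. uniform from these.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

ENVIRONMENTS = ("ENV_A", "ENV_B")


@dataclass(frozen=True)
class PlantedEffect:
    """A presence-covariate effect planted into one FUnkFam.

    ``funkfam_index`` indexes the planted FUnkFams in family-id order; the
    effect applies (on the log-odds scale) only to samples in ``stratum``.
    """

    funkfam_index: int
    covariate: str
    stratum: str
    log_odds: float


@dataclass
class SimConfig:
    """Knobs of the fixture generator; the seed determines every emitted byte."""

    seed: int = 0
    n_families: int = 12
    members_per_family: tuple[int, int] = (3, 6)
    frac_annotated: float = 0.25
    frac_narrow: float = 1 / 6
    frac_fail: float = 0.25
    frac_truncated_members: float = 0.2
    mean_len_aa: int = 250
    mutation_rate: float = 0.02
    n_domains: int = 2
    phyla_per_domain: int = 3
    classes_per_phylum: int = 2
    n_samples_per_env: int = 10
    read_length: int = 100
    reads_per_present_family: tuple[int, int] = (1, 20)
    decoy_rate: float = 0.3
    base_presence_logit: float = -0.5
    genome_equivalents_range: tuple[float, float] = (5.0, 30.0)
    planted_effects: tuple[PlantedEffect, ...] = (
        PlantedEffect(funkfam_index=0, covariate="pheno_cat", stratum="ENV_A", log_odds=3.0),
    )

    def __post_init__(self) -> None:
        for name in ("frac_annotated", "frac_narrow", "frac_fail", "frac_truncated_members", "decoy_rate"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.frac_truncated_members > 0.5:
            raise ValueError("frac_truncated_members > 0.5 would fail planted passing families")

    @property
    def n_classes_total(self) -> int:
        return self.n_domains * self.phyla_per_domain * self.classes_per_phylum


@dataclass
class GroundTruth:
    """What the generator planted, keyed the way the pipeline reports it."""

    families: dict[str, dict] = field(default_factory=dict)
    samples: dict[str, dict] = field(default_factory=dict)
    counts: dict[str, dict[str, int]] = field(default_factory=dict)
    planted_effects: list[dict] = field(default_factory=list)

    @property
    def funkfam_ids(self) -> list[str]:
        return sorted(f for f, info in self.families.items() if info["is_funkfam"])

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        return cls(**raw)


# ---------------------------------------------------------------------------
# catalog generation
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA_ALPHABET), size=length))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    chars = list(seq)
    n_mut = max(1, rng.binomial(len(chars), rate))
    positions = rng.choice(len(chars), size=min(n_mut, len(chars)), replace=False)
    for pos in positions:
        alternatives = [a for a in AA_ALPHABET if a != chars[pos]]
        chars[pos] = alternatives[rng.integers(len(alternatives))]
    return "".join(chars)


def _class_paths(config: SimConfig) -> list[tuple[str, str, str, str]]:
    """All (domain, kingdom, phylum, class) name paths in the toy taxonomy."""
    paths = []
    for d in range(1, config.n_domains + 1):
        dom = f"Dom{d}"
        kin = f"{dom}.K1"
        for p in range(1, config.phyla_per_domain + 1):
            phy = f"{dom}.P{p}"
            for c in range(1, config.classes_per_phylum + 1):
                paths.append((dom, kin, phy, f"{phy}.C{c}"))
    return paths


def _family_kinds(config: SimConfig, rng: np.random.Generator) -> list[str]:
    n = config.n_families
    n_fail = round(config.frac_fail * n)
    n_annot = round(config.frac_annotated * n)
    n_narrow = round(config.frac_narrow * n)
    n_funk = n - n_fail - n_annot - n_narrow
    if n_funk < 1:
        raise ValueError("family-class fractions leave no FUnkFams to plant")
    kinds = (
        ["funkfam"] * n_funk
        + ["annotated"] * n_annot
        + ["narrow"] * n_narrow
        + [("fail_unique" if i % 2 == 0 else "fail_truncated") for i in range(n_fail)]
    )
    rng.shuffle(kinds)
    return kinds


def generate_catalog(config: SimConfig, outdir: str | Path) -> GroundTruth:
    """Write catalog, lineage and annotation-database files; return ground truth.

    Files: ``catalog.faa``, ``membership.tsv``, ``lineage.tsv``,
    ``annotation_db.faa``, ``annotation_db.tsv``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    class_paths = _class_paths(config)
    if config.n_classes_total < 2:
        raise ValueError(
            "taxonomy shape provides fewer than two classes; cannot plant broad families"
        )
    n_phyla_total = config.n_domains * config.phyla_per_domain
    if n_phyla_total < 2:
        raise ValueError("taxonomy shape provides fewer than two phyla")

    kinds = _family_kinds(config, rng)
    gt = GroundTruth()

    fasta_rows: list[tuple[str, str]] = []
    membership_rows: list[tuple[str, str, str, int, int]] = []
    lineage_rows: list[dict[str, str]] = []
    annot_fasta: list[tuple[str, str]] = []
    annot_tsv: list[tuple[str, str]] = []

    taxon_counter = 0
    seq_counter = 0
    db_counter = 0
    first_narrow_member: tuple[str, str] | None = None

    lo, hi = config.members_per_family
    for idx, kind in enumerate(kinds):
        fid = f"FAM{idx + 1:04d}"
        n_members = int(rng.integers(lo, hi + 1))

        # --- member classes -------------------------------------------------
        if kind == "funkfam":
            # guarantee >= 2 classes from >= 2 phyla
            phyla = {path[2]: [] for path in class_paths}
            for path in class_paths:
                phyla[path[2]].append(path)
            phylum_names = sorted(phyla)
            chosen_phyla = rng.choice(len(phylum_names), size=2, replace=False)
            base_classes = [
                phyla[phylum_names[i]][int(rng.integers(len(phyla[phylum_names[i]])))]
                for i in chosen_phyla
            ]
            n_extra = int(rng.integers(0, 2))
            extra = [class_paths[int(rng.integers(len(class_paths)))] for _ in range(n_extra)]
            classes = base_classes + extra
            member_classes = [classes[i % len(classes)] for i in range(n_members)]
        elif kind == "narrow":
            cls = class_paths[int(rng.integers(len(class_paths)))]
            member_classes = [cls] * n_members
        else:  # annotated or failing: breadth is irrelevant, draw freely
            member_classes = [
                class_paths[int(rng.integers(len(class_paths)))] for _ in range(n_members)
            ]

        # --- member sequences -----------------------------------------------
        length = int(rng.integers(int(0.8 * config.mean_len_aa), int(1.2 * config.mean_len_aa) + 1))
        ancestor = _random_seq(rng, length)
        seqs: list[str] = []
        if kind == "fail_unique":
            a = _mutate(rng, ancestor, config.mutation_rate)
            b = _mutate(rng, ancestor, config.mutation_rate)
            while b == a:
                b = _mutate(rng, ancestor, config.mutation_rate)
            seqs = [a, b] + [a] * (n_members - 2)
        else:
            seen: set[str] = set()
            for _ in range(n_members):
                s = _mutate(rng, ancestor, config.mutation_rate)
                while s in seen:
                    s = _mutate(rng, s, config.mutation_rate)
                seen.add(s)
                seqs.append(s)

        # --- truncation flags -----------------------------------------------
        if kind == "fail_truncated":
            n_trunc = n_members // 2 + 1
        else:
            n_trunc = min(int(config.frac_truncated_members * n_members), n_members // 2)
        trunc_idx = set(rng.choice(n_members, size=n_trunc, replace=False).tolist())

        # --- emit members ----------------------------------------------------
        member_ids: list[str] = []
        breadth_sets: dict[str, set[str]] = {rank: set() for rank in RANKS}
        for m in range(n_members):
            seq_counter += 1
            taxon_counter += 1
            sid = f"SEQ{seq_counter:05d}"
            tid = f"T{taxon_counter:05d}"
            member_ids.append(sid)
            dom, kin_name, phy, cls = member_classes[m]
            lineage = {
                "taxon_id": tid,
                "species": f"{cls}.sp{taxon_counter}",
                "genus": f"{cls}.g{taxon_counter}",
                "family": f"{cls}.F1",
                "order": f"{cls}.O1",
                "class": cls,
                "phylum": phy,
                "kingdom": kin_name,
                "domain": dom,
            }
            lineage_rows.append(lineage)
            for rank in RANKS:
                breadth_sets[rank].add(lineage[rank])
            truncated = m in trunc_idx
            has_start = 0 if truncated else 1
            has_stop = 1  # truncation planted on the start side only
            fasta_rows.append((sid, seqs[m]))
            membership_rows.append((sid, fid, tid, has_start, has_stop))

        # --- annotation database entries -------------------------------------
        annotated = kind == "annotated"
        if annotated:
            db_counter += 1
            member = int(rng.integers(n_members))
            annot_fasta.append((f"DB1_{db_counter:04d}", seqs[member]))
            annot_tsv.append((f"DB1_{db_counter:04d}", f"D{db_counter:04d}"))
        if kind == "narrow" and first_narrow_member is None:
            # an exact DB hit with *no* domain accessions: recorded, not annotation
            first_narrow_member = (fid, seqs[0])

        n_unique = len(set(seqs))
        frac_truncated = n_trunc / n_members
        passed = n_unique >= 3 and frac_truncated <= 0.5
        breadth = {rank: len(breadth_sets[rank]) for rank in RANKS}
        is_funkfam = passed and not annotated and breadth["class"] >= 2
        gt.families[fid] = {
            "kind": kind,
            "member_ids": member_ids,
            "n_members": n_members,
            "n_unique": n_unique,
            "frac_truncated": frac_truncated,
            "pass_filter": passed,
            "annotated": annotated,
            "breadth": breadth,
            "is_funkfam": is_funkfam,
            "mean_len_aa": float(np.mean([len(s) for s in seqs])),
        }

    if first_narrow_member is not None:
        db_counter += 1
        annot_fasta.append((f"DB1_{db_counter:04d}", first_narrow_member[1]))
        annot_tsv.append((f"DB1_{db_counter:04d}", ""))
    for _ in range(3):  # unrelated decoy database entries
        db_counter += 1
        annot_fasta.append((f"DB1_{db_counter:04d}", _random_seq(rng, config.mean_len_aa)))
        annot_tsv.append((f"DB1_{db_counter:04d}", f"D{db_counter:04d}"))

    _write_fasta(outdir / "catalog.faa", fasta_rows)
    with open(outdir / "membership.tsv", "w", encoding="utf-8") as fh:
        fh.write("seq_id\tfamily_id\ttaxon_id\thas_start\thas_stop\n")
        for row in membership_rows:
            fh.write("\t".join(map(str, row)) + "\n")
    with open(outdir / "lineage.tsv", "w", encoding="utf-8") as fh:
        fh.write("taxon_id\t" + "\t".join(RANKS) + "\n")
        for lineage in lineage_rows:
            fh.write(lineage["taxon_id"] + "\t" + "\t".join(lineage[r] for r in RANKS) + "\n")
    _write_fasta(outdir / "annotation_db.faa", annot_fasta)
    with open(outdir / "annotation_db.tsv", "w", encoding="utf-8") as fh:
        fh.write("seq_id\tdomain_accessions\n")
        for sid, acc in annot_tsv:
            fh.write(f"{sid}\t{acc}\n")
    return gt


def _write_fasta(path: Path, rows: Sequence[tuple[str, str]], width: int = 60) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sid, seq in rows:
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# metagenome generation
# ---------------------------------------------------------------------------


def _covariate_signal(value: object) -> float:
    """Map a covariate value to the x entering the planted logistic model."""
    if isinstance(value, (int, float, np.integer, np.floating)):
        return float(value)
    return 1.0 if str(value) == "X1" else 0.0


def simulate_presence(
    family_ids: Sequence[str],
    samples: pd.DataFrame,
    effects: Sequence[tuple[str, str, str, float]],
    base_logit: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw a family x sample presence matrix from a logistic model.

    ``effects`` are (family_id, covariate, stratum, log_odds) tuples; an
    effect contributes ``log_odds * x`` to the family's presence log-odds in
    samples of its stratum, where x is the numeric covariate value or an
    indicator of the non-reference categorical level.
    """
    effect_map: dict[str, list[tuple[str, str, float]]] = {}
    for fid, cov, stratum, beta in effects:
        effect_map.setdefault(fid, []).append((cov, stratum, beta))
    presence = pd.DataFrame(False, index=list(family_ids), columns=list(samples.index))
    for fid in family_ids:
        for sid, row in samples.iterrows():
            logit = base_logit
            for cov, stratum, beta in effect_map.get(fid, ()):
                if str(row["environment"]) == stratum:
                    logit += beta * _covariate_signal(row[cov])
            p = 1.0 / (1.0 + np.exp(-logit))
            presence.loc[fid, sid] = bool(rng.random() < p)
    return presence


def _sample_table(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    lo, hi = config.genome_equivalents_range
    for env in ENVIRONMENTS:
        for i in range(config.n_samples_per_env):
            rows.append(
                {
                    "sample_id": f"S_{env[-1]}{i + 1:03d}",
                    "environment": env,
                    "read_length": config.read_length,
                    "genome_equivalents": round(float(rng.uniform(lo, hi)), 3),
                    # alternate levels so both always reach the eligibility count
                    "pheno_cat": "X1" if i % 2 else "X0",
                    "pheno_num": round(float(rng.normal()), 4),
                }
            )
    return pd.DataFrame(rows).set_index("sample_id")


def generate_metagenomes(
    config: SimConfig, gt: GroundTruth, outdir: str | Path
) -> GroundTruth:
    """Write per-sample m8 files plus ``metadata.tsv``; record counts in ``gt``.

    Presence of each family in each sample follows the planted logistic
    model; each present family recruits a configured number of accepted
    reads (identity >= 99%, alignment spanning the read).  Decoy rows —
    sub-threshold identity, short alignments, hits to unknown subjects and
    duplicate lower-scoring hits for accepted reads — are injected and must
    never alter counts.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed + 1_000_003)

    samples = _sample_table(config, rng)
    samples.reset_index().to_csv(outdir / "metadata.tsv", sep="\t", index=False)
    for sid, row in samples.iterrows():
        gt.samples[sid] = {
            "environment": row["environment"],
            "read_length": int(row["read_length"]),
            "genome_equivalents": float(row["genome_equivalents"]),
            "pheno_cat": row["pheno_cat"],
            "pheno_num": float(row["pheno_num"]),
        }

    funk_ids = gt.funkfam_ids
    effects = []
    for eff in config.planted_effects:
        if eff.funkfam_index >= len(funk_ids):
            raise ValueError(
                f"planted effect references FUnkFam #{eff.funkfam_index}, "
                f"but only {len(funk_ids)} were planted"
            )
        effects.append((funk_ids[eff.funkfam_index], eff.covariate, eff.stratum, eff.log_odds))
        gt.planted_effects.append(
            {
                "family_id": funk_ids[eff.funkfam_index],
                "covariate": eff.covariate,
                "stratum": eff.stratum,
                "log_odds": eff.log_odds,
            }
        )

    family_ids = sorted(gt.families)
    presence = simulate_presence(
        family_ids, samples, effects, config.base_presence_logit, rng
    )

    lo, hi = config.reads_per_present_family
    all_members = {fid: gt.families[fid]["member_ids"] for fid in family_ids}
    for sid in samples.index:
        lines: list[str] = []
        read_idx = 0
        counts: dict[str, int] = {}
        for fid in family_ids:
            if not presence.loc[fid, sid]:
                counts[fid] = 0
                continue
            n_reads = int(rng.integers(lo, hi + 1))
            counts[fid] = n_reads
            for _ in range(n_reads):
                read_idx += 1
                rid = f"{sid}:r{read_idx:05d}"
                subject = all_members[fid][int(rng.integers(len(all_members[fid])))]
                pident = round(99.0 + float(rng.random()), 2)
                bit = round(180.0 + 20.0 * float(rng.random()), 1)
                lines.append(_m8_row(rid, subject, pident, config.read_length, bit))
                if rng.random() < 0.3:  # secondary, lower-scoring hit to another family
                    other = family_ids[int(rng.integers(len(family_ids)))]
                    osub = all_members[other][int(rng.integers(len(all_members[other])))]
                    lines.append(
                        _m8_row(rid, osub, round(99.0 + float(rng.random()), 2),
                                config.read_length, round(bit - 50.0, 1))
                    )
        n_accepted = sum(counts.values())
        n_decoys = int(config.decoy_rate * n_accepted)
        for j in range(n_decoys):
            rid = f"{sid}:d{j + 1:05d}"
            fid = family_ids[int(rng.integers(len(family_ids)))]
            subject = all_members[fid][int(rng.integers(len(all_members[fid])))]
            mode = j % 3
            if mode == 0:  # identity below the 99% threshold
                lines.append(
                    _m8_row(rid, subject, round(80.0 + 18.9 * float(rng.random()), 2),
                            config.read_length, 150.0)
                )
            elif mode == 1:  # alignment shorter than the read
                lines.append(
                    _m8_row(rid, subject, 99.5, config.read_length - 25, 150.0)
                )
            else:  # subject outside the catalog
                lines.append(_m8_row(rid, "UNMAPPED_1", 99.9, config.read_length, 150.0))
        with open(outdir / f"{sid}.m8", "w", encoding="utf-8") as fh:
            fh.write("".join(lines))
        gt.counts[sid] = counts
    return gt


def _m8_row(rid: str, subject: str, pident: float, length: int, bit: float) -> str:
    # query, subject, pident, length, mismatch, gapopen, qstart, qend, sstart, send, evalue, bitscore
    return (
        f"{rid}\t{subject}\t{pident}\t{length}\t0\t0\t1\t{length}"
        f"\t1\t{length}\t1e-30\t{bit}\n"
    )


def generate_all(config: SimConfig, outdir: str | Path) -> GroundTruth:
    """Generate catalog and metagenomes and write ``ground_truth.json``."""
    outdir = Path(outdir)
    gt = generate_catalog(config, outdir)
    gt = generate_metagenomes(config, gt, outdir)
    gt.to_json(outdir / "ground_truth.json")
    return gt
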