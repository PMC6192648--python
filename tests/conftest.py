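"""Shared helpers: hand-built records and small on-disk fixtures."""

from __future__ import annotations

from pathlib import Path

import pytest

from funkfams.catalog_io import AnnotationRecord, SequenceRecord


def seq_rec(
    seq_id: str,
    aa_seq: str,
    family_id: str = "F1",
    taxon_id: str = "T1",
    has_start: bool = True,
    has_stop: bool = True,
) -> SequenceRecord:
    return SequenceRecord(
        seq_id=seq_id,
        aa_seq=aa_seq,
        family_id=family_id,
        taxon_id=taxon_id,
        has_start=has_start,
        has_stop=has_stop,
    )


def annot_rec(
    seq_id: str,
    aa_seq: str,
    accessions: tuple[str, ...] = (),
    db_name: str = "DB1",
) -> AnnotationRecord:
    return AnnotationRecord(
        db_name=db_name, seq_id=seq_id, aa_seq=aa_seq, domain_accessions=accessions
    )


def write(path: Path, text: str) -> Path:
    path.write_text(text, encoding="utf-8")
    return path


@pytest.fixture
def tiny_catalog(tmp_path: Path) -> tuple[Path, Path]:
    """Three sequences forming one family; includes a trailing-stop sequence."""
    fasta = write(
        tmp_path / "cat.faa",
        ">s1\nMKVA\n>s2\nMKTA\n>s3\nMKV*\n",
    )
    tsv = write(
        tmp_path / "members.tsv",
        "seq_id\tfamily_id\ttaxon_id\thas_start\thas_stop\n"
        "s1\tfamA\tT1\t1\t1\n"
        "s2\tfamA\tT2\t1\t1\n"
        "s3\tfamA\tT3\t0\t1\n",
    )
    return fasta, tsv
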