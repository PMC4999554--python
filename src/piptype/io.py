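"""FASTA/FASTQ reading and deterministic TSV report writing."""

from __future__ import annotations

import hashlib
import warnings
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioRecord

from .errors import InputError
from .records import NUCLEOTIDE, PROTEIN, SequenceRecord

_NT_SET = frozenset("ACGTN")


def _guess_alphabet(residues: str) -> str:
    return NUCLEOTIDE if set(residues) <= _NT_SET else PROTEIN


def read_fasta(path, alphabet: str = "auto") -> list[SequenceRecord]:
    """All records of a FASTA file, order and ids preserved, uppercased.

    Duplicate ids raise; an empty file returns an empty list with a warning.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in seen:
                raise InputError(f"duplicate id {rec.id!r} in {path}")
            seen.add(rec.id)
            residues = str(rec.seq).upper()
            ab = _guess_alphabet(residues) if alphabet == "auto" else alphabet
            records.append(SequenceRecord(rec.id, residues, ab))
    except ValueError as exc:  # malformed record
        raise InputError(f"malformed FASTA in {path}: {exc}") from exc
    if not records:
        warnings.warn(f"no records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 70) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def read_fastq(path) -> tuple[list[SequenceRecord], list[str]]:
    """Records and Phred+33 quality strings of a standard 4-line FASTQ.

    Qualities are retained for transparency but unused downstream.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    quals: list[str] = []
    try:
        for idx, rec in enumerate(SeqIO.parse(str(path), "fastq")):
            records.append(SequenceRecord(rec.id, str(rec.seq).upper(), NUCLEOTIDE))
            quals.append(
                "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            )
    except ValueError as exc:
        raise InputError(f"malformed FASTQ in {path} near record {len(records) + 1}: {exc}") from exc
    if not records:
        warnings.warn(f"no records in {path}")
    return records, quals


def write_fastq(
    records: Sequence[SequenceRecord], path, qualities: Optional[Sequence[str]] = None
) -> None:
    """Write records with supplied or uniform placeholder ('I') qualities."""
    path = Path(path)
    with path.open("w") as fh:
        for i, rec in enumerate(records):
            q = qualities[i] if qualities is not None else "I" * len(rec.residues)
            if len(q) != len(rec.residues):
                raise InputError(f"quality length mismatch for record {rec.id!r}")
            fh.write(f"@{rec.id}\n{rec.residues}\n+\n{q}\n")


def write_report(table: pd.DataFrame, path) -> None:
    """Deterministic TSV: fixed column order, floats at 6 decimals."""
    if table.columns.empty:
        raise InputError("report table has no columns")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False, float_format="%.6f", lineterminator="\n")


def alignment_to_fasta(aln, ids: tuple[str, str], path) -> None:
    """Export a pairwise alignment as two-row gapped FASTA."""
    with Path(path).open("w") as fh:
        fh.write(f">{ids[0]}\n{aln.aligned_a}\n>{ids[1]}\n{aln.aligned_b}\n")


def file_digest(path) -> str:
    """SHA-256 of a file, for run logging."""
    h = hashlib.sha256()
    with Path(path).open("rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
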