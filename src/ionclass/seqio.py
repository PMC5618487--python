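"""Protein FASTA input/output and sequence validation.

Sequences are held as :class:`ProteinRecord` objects over the 20 canonical
amino-acid single-letter codes. Validation mirrors the benchmark-construction
rule used for curated ion-channel datasets: any sequence containing an
ambiguous or non-canonical residue (X, B, Z, U, O, ``*``, gaps, ...) is
rejected. Redundancy filtering (e.g. CD-HIT at 40% identity) and removal of
fragments or homology-only annotations operate on database metadata that plain
FASTA does not carry; they are an upstream contract of the caller, not code
here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 canonical residues in alphabetical single-letter order.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_ALPHABET_SET = frozenset(ALPHABET)

PathLike = Union[str, Path]


class FastaParseError(ValueError):
    """Raised for malformed FASTA input (e.g. sequence data before a header)."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with its FASTA identifier.

    The record itself is permissive about the alphabet so that freshly parsed
    files can be inspected; :func:`validate_record` issues the accept/reject
    verdict against the canonical alphabet.
    """

    id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __len__(self) -> int:  # pragma: no cover - convenience alias
        return len(self.sequence)


@dataclass(frozen=True)
class ValidationVerdict:
    """Accept/reject outcome for one record; truthy iff accepted."""

    accepted: bool
    reason: str | None = None

    def __bool__(self) -> bool:
        return self.accepted


def read_fasta(path: PathLike) -> list[ProteinRecord]:
    """Read a FASTA file into a list of :class:`ProteinRecord`.

    Records are returned in file order; sequences are upper-cased and internal
    whitespace is stripped. An empty file yields an empty list.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    FastaParseError
        If sequence data precedes the first ``>`` header; the message names
        the offending line number.
    """
    path = Path(path)
    with path.open() as handle:
        for lineno, line in enumerate(handle, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: sequence data before any FASTA header"
                )
            break
    records: list[ProteinRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        sequence = "".join(str(rec.seq).split()).upper()
        records.append(ProteinRecord(id=rec.id, sequence=sequence))
    return records


def validate_record(record: ProteinRecord, min_length: int = 2) -> ValidationVerdict:
    """Accept a record iff it is all-canonical and long enough.

    Rejection covers every character outside the 20-letter alphabet — the
    ambiguity codes X, B, Z, the rare residues U and O, stop ``*`` and gap
    characters alike. The verdict reports the first offending character and
    its 1-based position. ``min_length`` defaults to 2 because dipeptide
    counting needs at least one adjacent pair; the encoder separately enforces
    its own stricter ``L > lambda`` requirement.
    """
    for position, char in enumerate(record.sequence, start=1):
        if char not in _ALPHABET_SET:
            return ValidationVerdict(
                False, f"ambiguous residue {char} at position {position}"
            )
    if record.length < min_length:
        return ValidationVerdict(
            False,
            f"sequence length {record.length} below minimum {min_length}",
        )
    return ValidationVerdict(True)


def filter_valid(
    records: Iterable[ProteinRecord], min_length: int = 2
) -> tuple[list[ProteinRecord], list[tuple[ProteinRecord, str]]]:
    """Split records into (accepted, rejected-with-reason) per :func:`validate_record`."""
    accepted: list[ProteinRecord] = []
    rejected: list[tuple[ProteinRecord, str]] = []
    for record in records:
        verdict = validate_record(record, min_length=min_length)
        if verdict:
            accepted.append(record)
        else:
            rejected.append((record, verdict.reason or "rejected"))
    return accepted, rejected


def write_fasta(records: Sequence[ProteinRecord], path: PathLike) -> None:
    """Write records as standard FASTA, 60-column wrapped.

    ``read_fasta(write_fasta(x))`` reproduces the id/sequence pairs exactly,
    provided ids are single whitespace-free tokens (FASTA keeps only the first
    token as the id).
    """
    path = Path(path)
    seq_records = [
        SeqRecord(Seq(rec.sequence), id=rec.id, description="") for rec in records
    ]
    with path.open("w") as handle:
        SeqIO.write(seq_records, handle, "fasta")


def read_labels(path: PathLike) -> dict[str, str]:
    """Read a two-column (id, class) TSV into a dict; '#' lines are comments."""
    labels: dict[str, str] = {}
    with Path(path).open() as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 'id<TAB>label'")
            labels[parts[0]] = parts[1]
    return labels


def write_labels(labels: dict[str, str], path: PathLike) -> None:
    """Write an (id, class) mapping as a two-column TSV in insertion order."""
    with Path(path).open("w") as handle:
        for record_id, label in labels.items():
            handle.write(f"{record_id}\t{label}\n")
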