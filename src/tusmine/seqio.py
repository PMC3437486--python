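"""Sequence records and readers/writers for the standard flat formats.

Every downstream stage consumes :class:`SequenceRecord` and
:class:`HitRecord`.  Parsing of FASTA/FASTQ is delegated to Biopython;
this module layers on the validation the pipeline requires: unique ids,
a strict 5-letter alphabet (A/C/G/T/N after normalisation, U mapped to
T), and distinct error types for the failure modes callers want to
handle separately.

Coordinates everywhere in the package are 1-based inclusive, matching
the BLAST tabular convention.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

ALPHABET = frozenset("ACGTN")

_NORMALIZE = str.maketrans("acgtunU", "ACGTTNT")


class SeqIOError(ValueError):
    """Base class for sequence-file errors."""


class EmptyFileError(SeqIOError):
    pass


class MalformedRecordError(SeqIOError):
    pass


class DuplicateIdError(SeqIOError):
    pass


class AlphabetError(SeqIOError):
    pass


class HitTableError(ValueError):
    """Raised on malformed similarity-hit tables; carries the line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


def normalize_residues(raw: str, *, context: str = "") -> str:
    """Upper-case, map U->T, and reject anything outside {A,C,G,T,N}."""
    residues = raw.translate(_NORMALIZE)
    bad = set(residues) - ALPHABET
    if bad:
        where = f" in {context}" if context else ""
        raise AlphabetError(
            f"residues outside A/C/G/T/N{where}: {sorted(bad)!r}"
        )
    return residues


@dataclass
class SequenceRecord:
    """A single DNA sequence: a read, an EST, a tag, a TUS or a genome chunk."""

    id: str
    residues: str
    description: str = ""
    origin: str = "tus"  # sanger | roche454 | tag | tus | genome

    def __post_init__(self) -> None:
        if not self.id:
            raise MalformedRecordError("record id must be nonempty")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class HitRecord:
    """One line of 12-column tabular similarity output (BLAST outfmt 6)."""

    query: str
    subject: str
    pct_identity: float
    aln_len: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float
    qlen: int | None = None  # optional 13th sidecar column

    def __post_init__(self) -> None:
        if self.qstart > self.qend:
            raise HitTableError(f"qstart {self.qstart} > qend {self.qend}")
        if self.evalue < 0:
            raise HitTableError(f"negative evalue {self.evalue}")
        if not 0 <= self.pct_identity <= 100:
            raise HitTableError(f"pct_identity {self.pct_identity} outside [0,100]")

    def qcov_pct(self, qlen: int | None = None) -> float:
        """Query coverage percent, 100*aln_len/qlen."""
        n = qlen if qlen is not None else self.qlen
        if n is None:
            raise HitTableError(f"query length unknown for {self.query}")
        return 100.0 * self.aln_len / n


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path)


def read_fasta(path: str | Path, origin: str = "tus") -> list[SequenceRecord]:
    """Read a FASTA file into normalized records, in file order.

    Raises :class:`EmptyFileError` on an empty file,
    :class:`MalformedRecordError` if the file does not start with a
    header line, and :class:`DuplicateIdError` on repeated ids.
    """
    with _open_text(path) as fh:
        first = fh.read(1)
        if not first:
            raise EmptyFileError(f"empty FASTA file: {path}")
        if first != ">":
            raise MalformedRecordError(f"{path}: FASTA must start with '>'")
        fh.seek(0)
        records = []
        seen: set[str] = set()
        for rec in SeqIO.parse(fh, "fasta"):
            if not rec.id:
                raise MalformedRecordError(f"{path}: record with empty id")
            if rec.id in seen:
                raise DuplicateIdError(f"{path}: duplicate id {rec.id!r}")
            seen.add(rec.id)
            residues = normalize_residues(str(rec.seq), context=rec.id)
            if not residues:
                raise MalformedRecordError(f"{path}: record {rec.id!r} has no residues")
            records.append(
                SequenceRecord(
                    id=rec.id,
                    residues=residues,
                    description=rec.description[len(rec.id):].strip(),
                    origin=origin,
                )
            )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    """Write FASTA with `width`-column wrapped sequence lines."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def read_fastq(path: str | Path, origin: str = "tag") -> list[SequenceRecord]:
    """Read 4-line FASTQ (Sanger +33).

    Qualities are parsed (Biopython validates the encoding) but not kept:
    tag libraries arrive pre-filtered and no downstream computation uses
    per-base quality.
    """
    records = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            if rec.id in seen:
                raise DuplicateIdError(f"{path}: duplicate id {rec.id!r}")
            seen.add(rec.id)
            records.append(
                SequenceRecord(
                    id=rec.id,
                    residues=normalize_residues(str(rec.seq), context=rec.id),
                    origin=origin,
                )
            )
    if not records:
        raise EmptyFileError(f"empty FASTQ file: {path}")
    return records


def write_fastq(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write FASTQ with uniform placeholder qualities (Q40)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"@{rec.id}\n{rec.residues}\n+\n{'I' * len(rec.residues)}\n")


def read_hit_table(path: str | Path) -> list[HitRecord]:
    """Read 12-column tabular hits; '#' comment lines are skipped.

    A 13th column, if present, is taken as the query length sidecar.
    Raises :class:`HitTableError` naming the offending line on a wrong
    column count or a non-numeric field.
    """
    hits: list[HitRecord] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (12, 13):
                raise HitTableError(
                    f"expected 12 or 13 tab-separated columns, got {len(fields)}",
                    line_number=lineno,
                )
            try:
                hit = HitRecord(
                    query=fields[0],
                    subject=fields[1],
                    pct_identity=float(fields[2]),
                    aln_len=int(fields[3]),
                    mismatches=int(fields[4]),
                    gap_opens=int(fields[5]),
                    qstart=int(fields[6]),
                    qend=int(fields[7]),
                    sstart=int(fields[8]),
                    send=int(fields[9]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                    qlen=int(fields[12]) if len(fields) == 13 else None,
                )
            except ValueError as exc:
                if isinstance(exc, HitTableError):
                    raise HitTableError(str(exc), line_number=lineno) from None
                raise HitTableError(f"non-numeric field ({exc})", line_number=lineno) from None
            hits.append(hit)
    return hits


def write_hit_table(hits: Iterable[HitRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fields = [
                h.query, h.subject, f"{h.pct_identity:.2f}", str(h.aln_len),
                str(h.mismatches), str(h.gap_opens), str(h.qstart), str(h.qend),
                str(h.sstart), str(h.send), f"{h.evalue:.2e}", f"{h.bitscore:.1f}",
            ]
            if h.qlen is not None:
                fields.append(str(h.qlen))
            fh.write("\t".join(fields) + "\n")


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())
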