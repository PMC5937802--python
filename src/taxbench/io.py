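"""Streaming readers/writers for the formats the pipeline touches.

FASTA/FASTQ (via Biopython), Kraken-style per-read classifier output,
BLAST/DIAMOND 12-column tabular alignments (with or without a taxid column),
and the toolkit's own assignment and truth-manifest TSVs. All parsers are
generators: memory use is independent of file length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

#: Sentinel taxid for unclassified reads (Kraken convention).
UNCLASSIFIED = 0

_DNA_OK = set("ACGTN")


class ParseError(ValueError):
    """Malformed input; message carries file and line number."""


@dataclass
class SequenceRecord:
    """A named DNA sequence with optional per-base quality string."""

    id: str
    sequence: str
    quality: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record with empty id")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"{self.id}: quality length {len(self.quality)} != "
                f"sequence length {len(self.sequence)}"
            )


@dataclass(frozen=True)
class AlignmentHit:
    """One row of tabular protein-alignment output (outfmt-6 style)."""

    read_id: str
    subject_id: str
    percent_identity: float
    bitscore: float
    evalue: float
    taxid: int | None = None

    def __post_init__(self) -> None:
        if self.bitscore < 0:
            raise ValueError(f"{self.read_id}: negative bitscore")
        if self.evalue < 0:
            raise ValueError(f"{self.read_id}: negative evalue")


@dataclass(frozen=True)
class ReadAssignment:
    """Per-read taxon call; ``taxid == UNCLASSIFIED`` (0) means no call."""

    read_id: str
    taxid: int
    source: str

    @property
    def is_classified(self) -> bool:
        return self.taxid != UNCLASSIFIED


@dataclass(frozen=True)
class TruthRecord:
    """Ground-truth origin of a simulated read (0-based half-open coords)."""

    read_id: str
    accession: str
    taxid: int
    strand: str
    start: int
    end: int


@dataclass
class SkipReport:
    """Counts hits whose subject could not be mapped to a taxid."""

    unmapped: int = 0
    unmapped_subjects: set = field(default_factory=set)


# -- FASTA / FASTQ --------------------------------------------------------

def read_fasta(path: str | Path) -> Iterator[SequenceRecord]:
    for rec in SeqIO.parse(str(path), "fasta"):
        yield SequenceRecord(rec.id, str(rec.seq).upper())


def read_fastq(path: str | Path) -> Iterator[SequenceRecord]:
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        yield SequenceRecord(rec.id, str(rec.seq).upper(), qual)


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> int:
    n = 0
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")
            n += 1
    return n


def write_fastq(records: Iterable[SequenceRecord], path: str | Path,
                default_quality: str = "I") -> int:
    """Write FASTQ; records without quality get a constant quality symbol."""
    n = 0
    with open(path, "w") as fh:
        for rec in records:
            qual = rec.quality or default_quality * len(rec.sequence)
            fh.write(f"@{rec.id}\n{rec.sequence}\n+\n{qual}\n")
            n += 1
    return n


# -- Kraken per-read output ------------------------------------------------

def parse_kraken(path: str | Path) -> Iterator[ReadAssignment]:
    """Parse Kraken-style per-read TSV: status (C/U), read id, taxid, ...

    A 'U' status yields UNCLASSIFIED regardless of the taxid column; trailing
    columns (read length, k-mer breakdown) are ignored. Source is "kmer".
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 columns")
            status, read_id = fields[0], fields[1]
            if status == "U":
                yield ReadAssignment(read_id, UNCLASSIFIED, "kmer")
            elif status == "C":
                try:
                    taxid = int(fields[2])
                except ValueError:
                    raise ParseError(f"{path}:{lineno}: non-integer taxid") from None
                yield ReadAssignment(read_id, taxid, "kmer")
            else:
                raise ParseError(f"{path}:{lineno}: unknown status {status!r}")


# -- BLAST/DIAMOND tabular -------------------------------------------------

def load_taxid_map(path: str | Path) -> dict[str, int]:
    """Load a subject→taxid TSV; conflicting duplicate subjects are an error."""
    mapping: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns")
            subject, taxid = fields[0], int(fields[1])
            if subject in mapping and mapping[subject] != taxid:
                raise ParseError(
                    f"{path}:{lineno}: subject {subject!r} mapped to both "
                    f"{mapping[subject]} and {taxid}"
                )
            mapping[subject] = taxid
    return mapping


def parse_alignment_tab(
    path: str | Path,
    taxid_map: dict[str, int] | None = None,
    report: SkipReport | None = None,
) -> Iterator[AlignmentHit]:
    """Parse 12-column BLAST/DIAMOND tabular output.

    The taxid comes from a 13th column when present, else from `taxid_map`
    (subject→taxid). Hits whose subject cannot be mapped are emitted with
    ``taxid=None`` and counted in `report`.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 12:
                raise ParseError(
                    f"{path}:{lineno}: expected >=12 columns, got {len(fields)}"
                )
            read_id, subject = fields[0], fields[1]
            try:
                pident = float(fields[2])
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: malformed numeric field") from None
            taxid: int | None = None
            if len(fields) >= 13 and fields[12] not in ("", "N/A", "0"):
                taxid = int(fields[12])
            elif taxid_map is not None:
                taxid = taxid_map.get(subject)
            if taxid is None and report is not None:
                report.unmapped += 1
                report.unmapped_subjects.add(subject)
            yield AlignmentHit(read_id, subject, pident, bitscore, evalue, taxid)


def write_alignment_tab(hits: Iterable[AlignmentHit], path: str | Path) -> int:
    """Write hits as 13-column tabular (unused columns zero-filled)."""
    n = 0
    with open(path, "w") as fh:
        for h in hits:
            staxid = "" if h.taxid is None else str(h.taxid)
            fh.write(
                f"{h.read_id}\t{h.subject_id}\t{h.percent_identity}\t0\t0\t0\t"
                f"0\t0\t0\t0\t{h.evalue}\t{h.bitscore}\t{staxid}\n"
            )
            n += 1
    return n


# -- assignment TSV (toolkit's own format) --------------------------------

def read_assignments(path: str | Path) -> Iterator[ReadAssignment]:
    """Read the three-column assignment TSV (read_id, taxid, source)."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 columns")
            try:
                taxid = int(fields[1])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer taxid") from None
            yield ReadAssignment(fields[0], taxid, fields[2])


def write_assignments(assignments: Iterable[ReadAssignment], path: str | Path) -> int:
    n = 0
    with open(path, "w") as fh:
        fh.write("#read_id\ttaxid\tsource\n")
        for a in assignments:
            fh.write(f"{a.read_id}\t{a.taxid}\t{a.source}\n")
            n += 1
    return n


# -- truth manifest TSV ----------------------------------------------------

def read_truth(path: str | Path) -> Iterator[TruthRecord]:
    """Read the truth manifest (read_id, accession, taxid, strand, start, end)."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 6:
                raise ParseError(f"{path}:{lineno}: expected 6 columns")
            read_id, acc, taxid, strand, start, end = fields
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: bad strand {strand!r}")
            yield TruthRecord(read_id, acc, int(taxid), strand, int(start), int(end))


def write_truth(records: Iterable[TruthRecord], path: str | Path) -> int:
    n = 0
    with open(path, "w") as fh:
        fh.write("#read_id\taccession\ttaxid\tstrand\tstart\tend\n")
        for r in records:
            fh.write(f"{r.read_id}\t{r.accession}\t{r.taxid}\t{r.strand}\t{r.start}\t{r.end}\n")
            n += 1
    return n
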