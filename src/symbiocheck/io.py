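"""Sequence I/O: FASTA/FASTQ records and the assembler coverage-header dialect.

All coordinates exposed by this package are 0-based, half-open. Quality scores
are Phred+33 only; other encodings are rejected. Files ending in ``.gz`` are
read and written through gzip transparently.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord


class SequenceParseError(ValueError):
    """Raised when a sequence file violates its format."""


class HeaderDialectError(ValueError):
    """Raised when a scaffold header does not match the coverage dialect."""


#: SPAdes-style scaffold header: NODE_<n>_length_<L>_cov_<C>
SPADES_HEADER_RE = re.compile(
    r"NODE_\d+_length_(?P<length>\d+)_cov_(?P<cov>\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)"
)


@dataclass
class SequenceRecord:
    """A nucleotide or amino-acid sequence, optionally with Phred qualities.

    ``qual`` is present iff the record came from (or is destined for) FASTQ,
    and always has the same length as ``seq``.
    """

    id: str
    seq: str
    description: str = ""
    qual: Optional[list[int]] = None

    def __post_init__(self) -> None:
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise SequenceParseError(
                f"record {self.id!r}: sequence length {len(self.seq)} != "
                f"quality length {len(self.qual)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class Scaffold:
    """An assembled contig with its assembler-reported k-mer coverage."""

    id: str
    seq: str
    kmer_cov: float

    @property
    def length(self) -> int:
        return len(self.seq)


def _open(path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> Iterator[SequenceRecord]:
    """Stream records from a FASTA file, preserving order and descriptions."""
    with _open(path) as fh:
        first = None
        lineno = 0
        # locate the first non-blank line to give a useful error for junk input
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                first = line
                break
        if first is None:
            return
        if not first.startswith(">"):
            raise SequenceParseError(
                f"{path}: line {lineno}: expected FASTA header starting with '>'"
            )
    with _open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            desc = rec.description
            if desc.startswith(rec.id):
                desc = desc[len(rec.id):].strip()
            yield SequenceRecord(id=rec.id, seq=str(rec.seq), description=desc)


def read_fastq(path) -> Iterator[SequenceRecord]:
    """Stream records from a Phred+33 FASTQ file (4-line records)."""
    with _open(path) as fh:
        try:
            for rec in SeqIO.parse(fh, "fastq"):
                desc = rec.description
                if desc.startswith(rec.id):
                    desc = desc[len(rec.id):].strip()
                yield SequenceRecord(
                    id=rec.id,
                    seq=str(rec.seq),
                    description=desc,
                    qual=list(rec.letter_annotations["phred_quality"]),
                )
        except ValueError as exc:  # Biopython signals malformed FASTQ this way
            raise SequenceParseError(f"{path}: {exc}") from exc


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 70) -> None:
    with _open(path, "wt") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def write_fastq(records: Iterable[SequenceRecord], path) -> None:
    with _open(path, "wt") as fh:
        for rec in records:
            if rec.qual is None:
                raise SequenceParseError(
                    f"record {rec.id!r} has no qualities; cannot write FASTQ"
                )
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            qual = "".join(chr(q + 33) for q in rec.qual)
            fh.write(f"@{header}\n{rec.seq}\n+\n{qual}\n")


def parse_scaffold_header(header: str, pattern: re.Pattern = SPADES_HEADER_RE):
    """Extract (length, kmer_cov) from an assembler scaffold header.

    Raises :class:`HeaderDialectError` when the header does not match, in
    which case a sidecar coverage table (``scaffold_id<TAB>kmer_cov``) should
    be supplied instead.
    """
    m = pattern.search(header)
    if m is None:
        raise HeaderDialectError(
            f"scaffold header {header!r} does not match the coverage dialect; "
            "supply an explicit coverage table (id<TAB>kmer_cov)"
        )
    return int(m.group("length")), float(m.group("cov"))


def read_coverage_table(path) -> dict[str, float]:
    """Read a sidecar TSV mapping scaffold id to k-mer coverage."""
    out: dict[str, float] = {}
    with _open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise SequenceParseError(
                    f"{path}: line {lineno}: expected 'id<TAB>coverage'"
                )
            out[parts[0]] = float(parts[1])
    return out


def load_scaffolds(
    path,
    coverage_table: Optional[dict[str, float]] = None,
    header_pattern: re.Pattern = SPADES_HEADER_RE,
    warn=None,
) -> list[Scaffold]:
    """Load scaffolds from FASTA, taking coverage from headers or a sidecar.

    When the declared header length disagrees with the actual sequence
    length, ``warn`` (a callable) is invoked with a message and the actual
    length wins.
    """
    scaffolds = []
    for rec in read_fasta(path):
        if coverage_table is not None:
            if rec.id not in coverage_table:
                raise HeaderDialectError(
                    f"scaffold {rec.id!r} missing from coverage table"
                )
            cov = coverage_table[rec.id]
        else:
            declared_len, cov = parse_scaffold_header(rec.id, header_pattern)
            if declared_len != len(rec.seq) and warn is not None:
                warn(
                    f"scaffold {rec.id}: declared length {declared_len} != "
                    f"actual {len(rec.seq)}"
                )
        scaffolds.append(Scaffold(id=rec.id, seq=rec.seq, kmer_cov=cov))
    return scaffolds
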