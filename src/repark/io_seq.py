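"""FASTA/FASTQ input and output with alphabet validation.

Reads are treated as an unordered pool: no pairing semantics, no SAM/BAM.
Both formats may be gzip-compressed; lowercase bases are folded to upper
case and any non-N IUPAC ambiguity code is converted to N with a warning,
so that downstream k-mer logic only ever sees {A, C, G, T, N}.
"""

from __future__ import annotations

import gzip
import io
import logging
import os
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

from Bio import SeqIO

from .errors import AlphabetError, ParameterError, ParseError

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")
# IUPAC ambiguity codes other than N; mapped to N on ingest.
_AMBIGUITY = "RYSWKMBDHVU"
_AMBIG_TABLE = str.maketrans(_AMBIGUITY + _AMBIGUITY.lower(), "N" * (2 * len(_AMBIGUITY)))


@dataclass(frozen=True)
class SequenceRecord:
    """A single sequence with optional per-base qualities.

    ``seq`` is uppercase over {A,C,G,T,N}; ``qual`` is a Phred+33 string of
    the same length when present.
    """

    id: str
    seq: str
    qual: str | None = None

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise ParseError(f"record {self.id!r}: empty sequence")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ParseError(
                f"record {self.id!r}: quality length {len(self.qual)} "
                f"!= sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


def _open_text(path: str | os.PathLike) -> IO[str]:
    """Open plain or gzip-compressed text transparently (by magic bytes)."""
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def _detect_format(path: str | os.PathLike, handle: IO[str]) -> str:
    name = str(path)
    for ext in (".gz", ".bgz"):
        if name.endswith(ext):
            name = name[: -len(ext)]
    if name.endswith((".fa", ".fasta", ".fna")):
        return "fasta"
    if name.endswith((".fq", ".fastq")):
        return "fastq"
    first = handle.read(1)
    handle.seek(0)
    if first == ">":
        return "fasta"
    if first == "@":
        return "fastq"
    raise ParseError(f"{path}: cannot detect format (first byte {first!r})")


def clean_sequence(raw: str, record_id: str) -> str:
    """Uppercase, convert non-N ambiguity codes to N, reject anything else."""
    seq = raw.upper()
    converted = seq.translate(_AMBIG_TABLE)
    if converted != seq:
        n_conv = sum(a != b for a, b in zip(seq, converted))
        logger.warning(
            "record %r: converted %d ambiguity base(s) to N", record_id, n_conv
        )
        seq = converted
    bad = set(seq) - VALID_BASES
    if bad:
        raise AlphabetError(
            f"record {record_id!r}: invalid character(s) {sorted(bad)}"
        )
    return seq


def read_sequences(
    path: str | os.PathLike, format: str = "auto"
) -> Iterator[SequenceRecord]:
    """Stream validated records from a FASTA/FASTQ file (plain or .gz).

    Records are yielded in file order. Malformed records raise
    :class:`ParseError`; characters outside the IUPAC alphabet raise
    :class:`AlphabetError`.
    """
    if format not in ("fasta", "fastq", "auto"):
        raise ParameterError(f"unknown format {format!r}")
    handle = _open_text(path)
    try:
        fmt = _detect_format(path, handle) if format == "auto" else format
        last_id = "<start of file>"
        try:
            for rec in SeqIO.parse(handle, fmt):
                last_id = rec.id
                qual = None
                if fmt == "fastq":
                    phred = rec.letter_annotations["phred_quality"]
                    qual = "".join(chr(q + 33) for q in phred)
                yield SequenceRecord(
                    id=rec.id, seq=clean_sequence(str(rec.seq), rec.id), qual=qual
                )
        except ValueError as exc:
            raise ParseError(f"{path}: near record {last_id!r}: {exc}") from exc
    finally:
        handle.close()


def write_sequences(
    records: Iterable[SequenceRecord],
    path: str | os.PathLike,
    wrap: int = 60,
) -> str:
    """Write records as FASTA (or FASTQ if the path says so), return the path.

    ``wrap`` is the FASTA line width; 0 disables wrapping. Output order
    equals input order; duplicate ids are an error. An empty record stream
    produces an empty file.
    """
    if wrap < 0:
        raise ParameterError("wrap must be >= 0")
    name = str(path)
    gz = name.endswith(".gz")
    stem = name[:-3] if gz else name
    fastq = stem.endswith((".fq", ".fastq"))
    opener = gzip.open if gz else open
    seen: set[str] = set()
    with opener(path, "wt") as out:
        for rec in records:
            if rec.id in seen:
                raise ParseError(f"duplicate record id {rec.id!r}")
            seen.add(rec.id)
            if fastq:
                qual = rec.qual if rec.qual is not None else "I" * len(rec.seq)
                out.write(f"@{rec.id}\n{rec.seq}\n+\n{qual}\n")
            else:
                out.write(f">{rec.id}\n")
                if wrap == 0:
                    out.write(rec.seq + "\n")
                else:
                    for i in range(0, len(rec.seq), wrap):
                        out.write(rec.seq[i : i + wrap] + "\n")
    return str(path)
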