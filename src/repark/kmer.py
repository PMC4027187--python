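"""Canonical k-mer counting and the multiplicity histogram.

Every length-k window of every read is counted under its canonical form
(the lexicographic minimum of the window and its reverse complement), the
double-strand convention used by standard k-mer counters. Windows that
contain N are skipped; reads shorter than k contribute nothing.

Counting is exact (no floor, no saturation). Internally k-mers are packed
two bits per base into uint64 (so k <= 32) and whole reads are processed
with vectorised numpy, which keeps multi-megabase read pools tractable in
pure Python.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np

from .errors import ParameterError
from .io_seq import SequenceRecord

logger = logging.getLogger(__name__)

DEFAULT_K = 31  # largest k packing into 62 bits; the conventional counting size

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# base -> 2-bit code; anything else (N) -> 4, which poisons the window
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)

# chunk of concatenated read bases processed per vectorised pass
_CHUNK_BASES = 4_000_000


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T(/N) string."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    """Canonical form: lexicographic min of the k-mer and its reverse complement.

    Idempotent; raises for N or any non-ACGT character.
    """
    if set(kmer) - set("ACGT"):
        raise ParameterError(f"k-mer contains non-ACGT characters: {kmer!r}")
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


@dataclass
class KmerSpectrum:
    """Multiplicities of the canonical k-mers of a read pool."""

    k: int
    counts: dict[str, int]

    @property
    def total_kmers(self) -> int:
        return sum(self.counts.values())

    def __len__(self) -> int:
        return len(self.counts)


@dataclass
class SpectrumHistogram:
    """bins[m] = number of distinct canonical k-mers with multiplicity m."""

    bins: dict[int, int]

    def as_dense(self) -> np.ndarray:
        """Counts indexed by multiplicity, index 0 unused."""
        m_max = max(self.bins) if self.bins else 0
        dense = np.zeros(m_max + 2, dtype=np.int64)
        for m, n in self.bins.items():
            dense[m] = n
        return dense


def _encode_codes(
    chunk: np.ndarray, k: int
) -> tuple[np.ndarray, np.ndarray]:
    """Canonical uint64 codes and validity mask for all k-windows of a chunk.

    ``chunk`` holds 2-bit base codes with 4 marking N or read separators.
    """
    n = chunk.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    b = chunk.astype(np.uint64)
    fwd = np.zeros(n, dtype=np.uint64)
    rev = np.zeros(n, dtype=np.uint64)
    rb = np.uint64(3) - np.minimum(b, 3).astype(np.uint64)  # complement codes
    for j in range(k):
        fwd |= (b[j : j + n] & np.uint64(3)) << np.uint64(2 * (k - 1 - j))
        rev |= rb[j : j + n] << np.uint64(2 * j)
    bad = np.cumsum(chunk > 3)
    valid = (bad[k - 1 :] - np.concatenate(([0], bad[: n - 1]))) == 0
    return np.minimum(fwd, rev), valid


def _decode_codes(codes: np.ndarray, k: int) -> list[str]:
    """uint64 canonical codes back to k-mer strings, vectorised."""
    n = codes.size
    chars = np.empty((n, k), dtype=np.uint8)
    for j in range(k):
        chars[:, k - 1 - j] = _DECODE[
            ((codes >> np.uint64(2 * j)) & np.uint64(3)).astype(np.intp)
        ]
    flat = chars.reshape(n * k) if n else chars.reshape(0)
    raw = flat.tobytes()
    return [raw[i * k : (i + 1) * k].decode("ascii") for i in range(n)]


def count_kmers(reads: Iterable[SequenceRecord], k: int = DEFAULT_K) -> KmerSpectrum:
    """Count canonical k-mers over a read pool.

    k must be at least 2 and at most 32 (two-bit packing); odd k is
    recommended because even k admits k-mers equal to their own reverse
    complement, whose double-strand counting convention is ambiguous.
    """
    if k < 2:
        raise ParameterError(f"k must be >= 2, got {k}")
    if k > 32:
        raise ParameterError(f"k must be <= 32 (uint64 packing), got {k}")
    if k % 2 == 0:
        logger.warning(
            "even k=%d admits self-reverse-complement k-mers; odd k recommended", k
        )

    acc: dict[int, int] = {}
    buf: list[np.ndarray] = []
    buf_len = 0
    sep = np.array([4], dtype=np.uint8)

    def flush() -> None:
        nonlocal buf, buf_len
        if not buf:
            return
        chunk = np.concatenate(buf)
        buf, buf_len = [], 0
        codes, valid = _encode_codes(chunk, k)
        uniq, cnt = np.unique(codes[valid], return_counts=True)
        for code, c in zip(uniq.tolist(), cnt.tolist()):
            acc[code] = acc.get(code, 0) + c

    for rec in reads:
        if len(rec.seq) < k:
            continue
        arr = _ENCODE[np.frombuffer(rec.seq.encode("ascii"), dtype=np.uint8)]
        buf.extend((arr, sep))
        buf_len += arr.size + 1
        if buf_len >= _CHUNK_BASES:
            flush()
    flush()

    codes = np.fromiter(acc.keys(), dtype=np.uint64, count=len(acc))
    order = np.argsort(codes)  # deterministic construction order
    kmers = _decode_codes(codes[order], k)
    values = np.fromiter(acc.values(), dtype=np.int64, count=len(acc))[order]
    return KmerSpectrum(k=k, counts=dict(zip(kmers, values.tolist())))


def histogram(spectrum: KmerSpectrum) -> SpectrumHistogram:
    """Multiplicity histogram of a spectrum.

    Conservation invariant: sum_m m * bins[m] == spectrum.total_kmers.
    """
    if not spectrum.counts:
        raise ParameterError("cannot build a histogram of an empty spectrum")
    values = np.fromiter(spectrum.counts.values(), dtype=np.int64)
    mult, n = np.unique(values, return_counts=True)
    return SpectrumHistogram(bins=dict(zip(mult.tolist(), n.tolist())))


def write_spectrum(spectrum: KmerSpectrum, path: str | os.PathLike) -> str:
    """Two-column TSV (kmer, count), lexicographically sorted."""
    with open(path, "wt") as out:
        for kmer in sorted(spectrum.counts):
            out.write(f"{kmer}\t{spectrum.counts[kmer]}\n")
    return str(path)


def read_spectrum(path: str | os.PathLike) -> KmerSpectrum:
    counts: dict[str, int] = {}
    k = 0
    with open(path) as fh:
        for line in fh:
            kmer, c = line.split("\t")
            counts[kmer] = int(c)
            k = len(kmer)
    if not counts:
        raise ParameterError(f"{path}: empty spectrum file")
    return KmerSpectrum(k=k, counts=counts)


def write_histogram(hist: SpectrumHistogram, path: str | os.PathLike) -> str:
    """Two-column TSV (multiplicity, n_distinct), the layout of `jellyfish histo`."""
    with open(path, "wt") as out:
        for m in sorted(hist.bins):
            out.write(f"{m}\t{hist.bins[m]}\n")
    return str(path)


def read_histogram(path: str | os.PathLike) -> SpectrumHistogram:
    """Read a histogram TSV (accepts space- or tab-separated columns)."""
    bins: dict[int, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            m, n = line.split()
            bins[int(m)] = int(n)
    if not bins:
        raise ParameterError(f"{path}: empty histogram file")
    return SpectrumHistogram(bins=bins)
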