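"""Repeat-library summary statistics: counts, total length, N50/N90.

N-xx convention: sort lengths descending and report the length at which
the running cumulative sum first reaches xx% of the total — so consensuses
of that length or longer hold at least xx% of the library.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from typing import Iterable

from .assembly import RepeatLibrary
from .errors import ParameterError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LibraryMetrics:
    n_consensuses: int
    total_len: int
    min_len: int
    max_len: int
    n50: int
    n90: int

    def as_dict(self) -> dict:
        return asdict(self)


def nxx(lengths: Iterable[int], x: float) -> int:
    """Length at which the descending cumulative sum first reaches x * total."""
    lens = sorted(lengths, reverse=True)
    if not lens:
        raise ParameterError("nxx of an empty length set is undefined")
    if not 0 < x < 1:
        raise ParameterError(f"x must be in (0, 1), got {x}")
    if min(lens) < 1:
        raise ParameterError("lengths must be >= 1")
    target = x * sum(lens)
    acc = 0
    for length in lens:
        acc += length
        if acc >= target:
            return length
    return lens[-1]  # unreachable: acc ends at total >= target


def summarize(library: RepeatLibrary) -> LibraryMetrics:
    """Library metrics; an empty library yields all-zero metrics with a warning."""
    lens = [c.length for c in library.consensuses]
    if not lens:
        logger.warning("empty repeat library: metrics are all zero")
        return LibraryMetrics(0, 0, 0, 0, 0, 0)
    return LibraryMetrics(
        n_consensuses=len(lens),
        total_len=sum(lens),
        min_len=min(lens),
        max_len=max(lens),
        n50=nxx(lens, 0.5),
        n90=nxx(lens, 0.9),
    )
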