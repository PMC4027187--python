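"""Synthetic genomes with planted repeat families, and shotgun reads.

The generator emulates a whole-genome shotgun experiment at desk scale: a
uniform-random unique background into which repeat families are planted
(dispersed copies or one tandem block), each copy independently mutated
at a per-family substitution divergence; reads of fixed length are drawn
at uniform positions from both strands with i.i.d. substitution errors.
No indels, no GC bias, no coverage overdispersion, single-end only — the
features that matter to k-mer abundance analysis are copy number, unit
length, divergence, depth and error rate, all of which are controlled
exactly, and every planted copy is recorded as ground truth.

One global integer seed drives independent per-stage generators (derived
by fixed offsets), so stages can be re-run in isolation and the whole
simulation is a pure function of its parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

from .errors import ParameterError, SimulationError
from .io_seq import SequenceRecord

_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)
_ENCODE = np.full(256, 0, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i

# fixed per-stage offsets for deriving independent generators from one seed
_STAGE_GENOME = 0
_STAGE_READS = 1
_STAGE_SPIKE = 2

# planted repeat content may not exceed this fraction of the final genome
_MAX_REPEAT_FRACTION = 0.9


@dataclass(frozen=True)
class RepeatFamilySpec:
    """One planted repeat family.

    divergence is the per-base substitution rate applied independently to
    every copy; dispersed copies are scattered, a tandem family occupies
    one contiguous block of copy_number adjacent units.
    """

    family_id: str
    unit_len: int
    copy_number: int
    divergence: float = 0.0
    arrangement: str = "dispersed"

    def __post_init__(self) -> None:
        if self.unit_len < 1 or self.copy_number < 1:
            raise ParameterError("unit_len and copy_number must be >= 1")
        if not 0 <= self.divergence <= 0.3:
            raise ParameterError("divergence must be in [0, 0.3]")
        if self.arrangement not in ("dispersed", "tandem"):
            raise ParameterError(f"unknown arrangement {self.arrangement!r}")


@dataclass(frozen=True)
class TruthInterval:
    """Ground-truth placement of one repeat copy (0-based half-open)."""

    family_id: str
    copy_index: int
    start: int
    end: int
    divergence: float


@dataclass
class SimulatedGenome:
    record: SequenceRecord
    truth: list[TruthInterval]
    unique_len: int
    masters: dict[str, str] = field(default_factory=dict)

    @property
    def seq(self) -> str:
        return self.record.seq

    def __len__(self) -> int:
        return len(self.record.seq)

    @property
    def repeat_fraction(self) -> float:
        """Exact planted repeat fraction from the truth bookkeeping."""
        return 1.0 - self.unique_len / len(self)


def _codes_to_str(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def _mutate(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each base with probability rate, always to a different base."""
    if rate <= 0:
        return codes.copy()
    mask = rng.random(codes.size) < rate
    shift = rng.integers(1, 4, size=codes.size)
    out = codes.copy()
    out[mask] = (out[mask] + shift[mask]) % 4
    return out


def simulate_genome(
    unique_len: int,
    families: Iterable[RepeatFamilySpec],
    seed: int,
) -> SimulatedGenome:
    """Plant repeat families into a uniform-random unique background.

    Copies (tandem families as one block) are spliced in at uniformly
    chosen background positions, so truth intervals never overlap and
    genome length = unique_len + total planted length.
    """
    families = list(families)
    if unique_len < 1:
        raise ParameterError("unique_len must be >= 1")
    total_repeat = sum(
        f.unit_len * f.copy_number for f in families
    )
    genome_len = unique_len + total_repeat
    if total_repeat > _MAX_REPEAT_FRACTION * genome_len:
        raise SimulationError(
            f"planted repeat content ({total_repeat} bp) exceeds "
            f"{_MAX_REPEAT_FRACTION:.0%} of the genome"
        )

    rng = np.random.default_rng([seed, _STAGE_GENOME])
    background = rng.integers(0, 4, size=unique_len, dtype=np.uint8)

    # one block per dispersed copy; one block per tandem family
    blocks: list[tuple[np.ndarray, list[tuple[str, int, int, int, float]]]] = []
    masters: dict[str, str] = {}
    for fam in families:
        master = rng.integers(0, 4, size=fam.unit_len, dtype=np.uint8)
        masters[fam.family_id] = _codes_to_str(master)
        if fam.arrangement == "dispersed":
            for ci in range(fam.copy_number):
                copy = _mutate(master, fam.divergence, rng)
                blocks.append(
                    (copy, [(fam.family_id, ci, 0, fam.unit_len, fam.divergence)])
                )
        else:
            units = [
                _mutate(master, fam.divergence, rng)
                for _ in range(fam.copy_number)
            ]
            entries = [
                (fam.family_id, ci, ci * fam.unit_len, (ci + 1) * fam.unit_len,
                 fam.divergence)
                for ci in range(fam.copy_number)
            ]
            blocks.append((np.concatenate(units), entries))

    positions = np.sort(rng.integers(0, unique_len + 1, size=len(blocks)))
    pieces: list[np.ndarray] = []
    truth: list[TruthInterval] = []
    cursor = 0  # position in background
    offset = 0  # length emitted so far
    for (block, entries), pos in zip(blocks, positions):
        pieces.append(background[cursor:pos])
        offset += pos - cursor
        cursor = pos
        for fam_id, ci, s, e, div in entries:
            truth.append(TruthInterval(fam_id, ci, offset + s, offset + e, div))
        pieces.append(block)
        offset += block.size
    pieces.append(background[cursor:])
    genome = np.concatenate(pieces) if pieces else background

    return SimulatedGenome(
        record=SequenceRecord(id="synthetic_genome", seq=_codes_to_str(genome)),
        truth=truth,
        unique_len=unique_len,
        masters=masters,
    )


def simulate_reads(
    genome: SimulatedGenome,
    read_len: int,
    coverage: float,
    error_rate: float = 0.0,
    seed: int = 0,
) -> list[SequenceRecord]:
    """Uniform single-end shotgun reads from both strands.

    n_reads = round(coverage * genome_len / read_len); substitution errors
    are i.i.d. at error_rate, always to a different base.
    """
    L = len(genome)
    if read_len > L:
        raise SimulationError(f"read_len {read_len} exceeds genome length {L}")
    if coverage <= 0:
        raise ParameterError("coverage must be > 0")
    if not 0 <= error_rate < 1:
        raise ParameterError("error_rate must be in [0, 1)")
    rng = np.random.default_rng([seed, _STAGE_READS])
    n = int(round(coverage * L / read_len))
    g = _ENCODE[np.frombuffer(genome.seq.encode("ascii"), dtype=np.uint8)]
    starts = rng.integers(0, L - read_len + 1, size=n)
    strands = rng.integers(0, 2, size=n)
    mat = g[starts[:, None] + np.arange(read_len)[None, :]]
    minus = strands == 1
    mat[minus] = (3 - mat[minus])[:, ::-1]
    if error_rate > 0:
        mask = rng.random(mat.shape) < error_rate
        shift = rng.integers(1, 4, size=mat.shape, dtype=np.uint8)
        mat[mask] = (mat[mask] + shift[mask]) % 4
    chars = _DECODE[mat]
    raw = chars.tobytes()
    return [
        SequenceRecord(
            id=f"read_{i}",
            seq=raw[i * read_len : (i + 1) * read_len].decode("ascii"),
        )
        for i in range(n)
    ]


def spike_contaminant(
    reads: Iterable[SequenceRecord],
    contaminant: SequenceRecord,
    depth_multiplier: float,
    read_len: int,
    seed: int,
    host_coverage: float,
) -> Iterator[SequenceRecord]:
    """Append reads from a circular contaminant at depth_multiplier times
    the host coverage.

    The contaminant is sampled as a circle: reads starting near the end
    wrap across the origin. Host coverage must be given explicitly — it is
    a property of the host experiment, not recoverable from the read
    stream itself.
    """
    if depth_multiplier <= 1:
        raise ParameterError("depth_multiplier must be > 1")
    if host_coverage <= 0:
        raise ParameterError("host_coverage must be > 0")
    L = len(contaminant.seq)
    if L < read_len:
        raise SimulationError(
            f"contaminant ({L} bp) shorter than read length {read_len}"
        )
    yield from reads
    rng = np.random.default_rng([seed, _STAGE_SPIKE])
    cov = depth_multiplier * host_coverage
    n = int(round(cov * L / read_len))
    doubled = contaminant.seq + contaminant.seq
    starts = rng.integers(0, L, size=n)
    strands = rng.integers(0, 2, size=n)
    comp = str.maketrans("ACGT", "TGCA")
    for i in range(n):
        seq = doubled[starts[i] : starts[i] + read_len]
        if strands[i] == 1:
            seq = seq.translate(comp)[::-1]
        yield SequenceRecord(id=f"contam_{i}", seq=seq)


def truth_to_bed(genome: SimulatedGenome, path: str) -> str:
    """Ground-truth repeat intervals as BED (name = family_id/copy_index)."""
    with open(path, "wt") as out:
        for iv in sorted(genome.truth, key=lambda t: t.start):
            out.write(
                f"{genome.record.id}\t{iv.start}\t{iv.end}\t"
                f"{iv.family_id}/{iv.copy_index}\t0\t+\n"
            )
    return path
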