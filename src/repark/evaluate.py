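"""Library evaluation against a reference: mapping, repeat classification,
masking and known-family completeness.

Consensuses are mapped with an exact-seed, chain-and-extend aligner:
seed_len-mer seeds of both query strands are looked up in a reference
index, chained per (target, strand, diagonal band), and the whole query is
aligned to the chained window with unit-cost gapped alignment (edlib).
Identity is matches / aligned query columns, gaps counting as
non-matches.

Operational repeat definition: a consensus is repetitive when it aligns
more than once to the reference at or above the identity threshold
(default 80%). The mapping stage keeps hits down to 50% identity so the
threshold can be varied downstream. Overlapping hits of one query at one
locus are merged (best identity kept) before any counting, so a single
occurrence split by a gap never counts as two alignments.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib

from .assembly import RepeatLibrary
from .errors import ParameterError
from .io_seq import SequenceRecord
from .kmer import revcomp

logger = logging.getLogger(__name__)

DEFAULT_SEED_LEN = 16
DEFAULT_MAP_IDENTITY = 0.5  # mapping floor; repeat calls filter higher
DEFAULT_REPEAT_IDENTITY = 0.8

_DIAG_BAND = 20  # seeds within this diagonal spread chain together
_MAX_SEED_GAP = 200  # max target gap between chained seeds


@dataclass(frozen=True)
class AlignmentHit:
    """Placement of a query consensus on a reference target."""

    query_id: str
    target_id: str
    t_start: int
    t_end: int
    strand: str
    identity: float
    q_cov: float


@dataclass
class EvaluationReport:
    """Per-library evaluation quantities.

    ``repetitive_len + non_repetitive_len`` always equals the library's
    total length; fractions are in [0, 1].
    """

    per_consensus_hits: dict[str, int] = field(default_factory=dict)
    repetitive_count: int = 0
    repetitive_len: int = 0
    non_repetitive_count: int = 0
    non_repetitive_len: int = 0
    masked_fraction: float | None = None
    family_completeness: dict[str, float] | None = None

    def as_dict(self) -> dict:
        return {
            "per_consensus_hits": self.per_consensus_hits,
            "repetitive_count": self.repetitive_count,
            "repetitive_len": self.repetitive_len,
            "non_repetitive_count": self.non_repetitive_count,
            "non_repetitive_len": self.non_repetitive_len,
            "masked_fraction": self.masked_fraction,
            "family_completeness": self.family_completeness,
        }


def _index_reference(
    reference: Sequence[SequenceRecord], seed_len: int
) -> dict[str, list[tuple[int, int]]]:
    index: dict[str, list[tuple[int, int]]] = {}
    for ti, rec in enumerate(reference):
        seq = rec.seq
        for p in range(len(seq) - seed_len + 1):
            seed = seq[p : p + seed_len]
            if "N" in seed:
                continue
            index.setdefault(seed, []).append((ti, p))
    return index


def _chain_seeds(
    seed_hits: list[tuple[int, int]]
) -> list[list[tuple[int, int]]]:
    """Group (q_pos, t_pos) seed matches of one target/strand into
    diagonal-banded clusters."""
    seed_hits.sort(key=lambda h: (h[1] - h[0], h[1]))  # by diagonal, then t
    clusters: list[list[tuple[int, int]]] = []
    for q, t in seed_hits:
        d = t - q
        placed = False
        if clusters:
            lq, lt = clusters[-1][-1]
            if abs(d - (lt - lq)) <= _DIAG_BAND and abs(t - lt) <= _MAX_SEED_GAP:
                clusters[-1].append((q, t))
                placed = True
        if not placed:
            clusters.append([(q, t)])
    return clusters


def _align_window(
    query_seg: str, target_seq: str, t_lo: int, t_hi: int
) -> tuple[int, int, float] | None:
    """Align a query segment into target_seq[t_lo:t_hi]; return
    (t_start, t_end, identity) or None when edlib finds nothing."""
    window = target_seq[t_lo:t_hi]
    res = edlib.align(query_seg, window, mode="HW", task="path")
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    cigar = res["cigar"] or ""
    matches = q_cols = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch == "=":
            matches += n
            q_cols += n
        elif ch in "XI":  # mismatch / query-consuming gap
            q_cols += n
        # 'D' consumes only the target
    if q_cols == 0:
        return None
    start, end = res["locations"][0]
    return t_lo + start, t_lo + end + 1, matches / q_cols


def _merge_hits(hits: list[AlignmentHit]) -> list[AlignmentHit]:
    """Merge overlapping hits of one query on one target: union interval,
    best identity kept."""
    out: list[AlignmentHit] = []
    for h in sorted(hits, key=lambda h: (h.t_start, h.t_end)):
        if out and h.t_start < out[-1].t_end:
            prev = out[-1]
            best = prev if prev.identity >= h.identity else h
            out[-1] = AlignmentHit(
                query_id=prev.query_id,
                target_id=prev.target_id,
                t_start=prev.t_start,
                t_end=max(prev.t_end, h.t_end),
                strand=best.strand,
                identity=best.identity,
                q_cov=best.q_cov,
            )
        else:
            out.append(h)
    return out


def map_consensuses(
    library: RepeatLibrary,
    reference: Sequence[SequenceRecord],
    seed_len: int = DEFAULT_SEED_LEN,
    min_identity: float = DEFAULT_MAP_IDENTITY,
) -> list[AlignmentHit]:
    """Map every library consensus onto the reference, both strands.

    Consensuses shorter than seed_len are skipped with a warning. Output
    is deterministic, ordered by (query, target, t_start).
    """
    if not library.consensuses or not reference:
        raise ParameterError("library and reference must both be nonempty")
    if not 0 < min_identity <= 1:
        raise ParameterError("min_identity must be in (0, 1]")
    reference = list(reference)
    index = _index_reference(reference, seed_len)
    all_hits: list[AlignmentHit] = []

    for cons in library.consensuses:
        if cons.length < seed_len:
            logger.warning(
                "consensus %s (%d bp) shorter than seed length %d: skipped",
                cons.id, cons.length, seed_len,
            )
            continue
        per_target: dict[str, list[AlignmentHit]] = {}
        for strand, query in (("+", cons.seq), ("-", revcomp(cons.seq))):
            by_target: dict[int, list[tuple[int, int]]] = {}
            for q in range(len(query) - seed_len + 1):
                for ti, t in index.get(query[q : q + seed_len], ()):
                    by_target.setdefault(ti, []).append((q, t))
            for ti, seed_hits in by_target.items():
                tseq = reference[ti].seq
                windows: set[tuple[int, int, int, int]] = set()
                pad = _DIAG_BAND + 10
                for cluster in _chain_seeds(seed_hits):
                    # local extension: align only the seed-supported query
                    # segment (plus a pad), so partial matches — including
                    # a rotated circular element split in two — stay local
                    q_lo = max(0, min(q for q, _ in cluster) - pad)
                    q_hi = min(
                        len(query),
                        max(q for q, _ in cluster) + seed_len + pad,
                    )
                    diags = [t - q for q, t in cluster]
                    t_lo = max(0, q_lo + min(diags) - pad)
                    t_hi = min(len(tseq), q_hi + max(diags) + pad)
                    windows.add((q_lo, q_hi, t_lo, t_hi))
                for q_lo, q_hi, t_lo, t_hi in sorted(windows):
                    res = _align_window(query[q_lo:q_hi], tseq, t_lo, t_hi)
                    if res is None:
                        continue
                    t_start, t_end, identity = res
                    if identity < min_identity:
                        continue
                    per_target.setdefault(reference[ti].id, []).append(
                        AlignmentHit(
                            query_id=cons.id,
                            target_id=reference[ti].id,
                            t_start=t_start,
                            t_end=t_end,
                            strand=strand,
                            identity=identity,
                            q_cov=(q_hi - q_lo) / len(query),
                        )
                    )
        for tid in sorted(per_target):
            all_hits.extend(_merge_hits(per_target[tid]))

    all_hits.sort(key=lambda h: (h.query_id, h.target_id, h.t_start))
    return all_hits


def classify_repetitive(
    hits: Iterable[AlignmentHit],
    library: RepeatLibrary,
    min_identity: float = DEFAULT_REPEAT_IDENTITY,
) -> EvaluationReport:
    """Partition the library into repetitive / non-repetitive consensuses.

    Repetitive = at least two qualifying (identity >= min_identity) hits.
    """
    qualifying: dict[str, int] = {c.id: 0 for c in library.consensuses}
    for h in hits:
        if h.identity >= min_identity and h.query_id in qualifying:
            qualifying[h.query_id] += 1
    report = EvaluationReport(per_consensus_hits=qualifying)
    for cons in library.consensuses:
        if qualifying[cons.id] >= 2:
            report.repetitive_count += 1
            report.repetitive_len += cons.length
        else:
            report.non_repetitive_count += 1
            report.non_repetitive_len += cons.length
    return report


def _union_length(intervals: list[tuple[int, int]]) -> int:
    total = 0
    cur_s = cur_e = None
    for s, e in sorted(intervals):
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def mask_reference(
    hits: Iterable[AlignmentHit],
    reference: Sequence[SequenceRecord],
    min_identity: float = DEFAULT_REPEAT_IDENTITY,
) -> float:
    """Fraction of reference bases covered by at least one qualifying hit."""
    lengths = {rec.id: len(rec.seq) for rec in reference}
    per_target: dict[str, list[tuple[int, int]]] = {}
    for h in hits:
        if h.identity < min_identity:
            continue
        if h.target_id not in lengths:
            raise ParameterError(f"hit on unknown target {h.target_id!r}")
        if not 0 <= h.t_start < h.t_end <= lengths[h.target_id]:
            raise ParameterError(
                f"hit [{h.t_start},{h.t_end}) out of bounds on {h.target_id!r}"
            )
        per_target.setdefault(h.target_id, []).append((h.t_start, h.t_end))
    covered = sum(_union_length(iv) for iv in per_target.values())
    total = sum(lengths.values())
    return covered / total if total else 0.0


def family_completeness(
    known_families: Sequence[SequenceRecord],
    library: RepeatLibrary,
    min_identity: float = DEFAULT_REPEAT_IDENTITY,
    seed_len: int = DEFAULT_SEED_LEN,
) -> dict[str, float]:
    """Per-family fraction of bases covered by library-consensus alignments.

    The family consensus plays the reference role and the library the
    probe role, so a family split across several library consensuses still
    scores as complete.
    """
    if not known_families or not library.consensuses:
        raise ParameterError("families and library must both be nonempty")
    hits = map_consensuses(
        library, known_families, seed_len=seed_len,
        min_identity=DEFAULT_MAP_IDENTITY,
    )
    out: dict[str, float] = {}
    for fam in known_families:
        ivs = [
            (h.t_start, h.t_end)
            for h in hits
            if h.target_id == fam.id and h.identity >= min_identity
        ]
        out[fam.id] = _union_length(ivs) / len(fam.seq)
    return out


def hits_to_bed(hits: Iterable[AlignmentHit], path: str) -> str:
    """Write hits as 6-column BED (score = identity in per-mille)."""
    with open(path, "wt") as out:
        for h in hits:
            out.write(
                f"{h.target_id}\t{h.t_start}\t{h.t_end}\t{h.query_id}\t"
                f"{round(h.identity * 1000)}\t{h.strand}\n"
            )
    return path


def hits_to_tsv(hits: Iterable[AlignmentHit], path: str) -> str:
    """psl-like tab-separated hit table with a header line."""
    with open(path, "wt") as out:
        out.write("query\ttarget\tt_start\tt_end\tstrand\tidentity\tq_cov\n")
        for h in hits:
            out.write(
                f"{h.query_id}\t{h.target_id}\t{h.t_start}\t{h.t_end}\t"
                f"{h.strand}\t{h.identity:.4f}\t{h.q_cov:.4f}\n"
            )
    return path
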