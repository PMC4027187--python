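"""Unitig assembly of abundant k-mers over a strand-canonical de Bruijn graph.

Each abundant counting k-mer is treated as an ultra-short read: it
contributes its constituent assembly k-mers (k_asm <= k_count, default 29
against counted 31-mers) as graph edges, with coverage accumulated under
the canonical form so that an edge and its reverse complement are one
edge. Repeat consensuses are exactly the maximal unambiguous paths
(unitigs); bubbles are deliberately not popped, so diverged repeat copies
stay as separate consensuses.

Isolated cycles (e.g. a circular element whose every k-mer is abundant)
are emitted as a single unitig traversing the cycle once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ParameterError
from .kmer import canonical, revcomp

DEFAULT_K_ASM = 29
DEFAULT_MIN_LEN = 50  # shorter consensuses are unusable for classification

_BASES = "ACGT"


@dataclass
class DeBruijnGraph:
    """Edges are canonical k_asm-mers mapped to coverage counts."""

    k_asm: int
    edges: dict[str, int]

    def __len__(self) -> int:
        return len(self.edges)

    def has_edge(self, kmer: str) -> bool:
        return canonical(kmer) in self.edges

    def nodes(self) -> set[str]:
        """All (k_asm-1)-mer prefixes/suffixes, in canonical form."""
        out: set[str] = set()
        for e in self.edges:
            out.add(canonical(e[:-1]))
            out.add(canonical(e[1:]))
        return out

    def out_edges(self, node: str) -> list[str]:
        """Oriented successor edges of an oriented (k_asm-1)-mer node."""
        return [node + b for b in _BASES if canonical(node + b) in self.edges]

    def in_edges(self, node: str) -> list[str]:
        return [b + node for b in _BASES if canonical(b + node) in self.edges]


@dataclass(frozen=True)
class RepeatConsensus:
    """An assembled repeat consensus: one unitig in canonical orientation."""

    id: str
    seq: str
    mean_cov: float

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class RepeatLibrary:
    """Deterministically ordered consensus set plus the parameters that built it."""

    consensuses: list[RepeatConsensus]
    params: dict = field(default_factory=dict)

    @property
    def total_len(self) -> int:
        return sum(c.length for c in self.consensuses)

    def __len__(self) -> int:
        return len(self.consensuses)

    def __iter__(self):
        return iter(self.consensuses)


def build_graph(abundant_kmers: "set[str] | list[str]", k_asm: int = DEFAULT_K_ASM) -> DeBruijnGraph:
    """Decompose abundant counting k-mers into canonical assembly edges.

    Each input k-mer of length k_count contributes its
    ``k_count - k_asm + 1`` constituent k_asm-mers, coverage accumulated.
    """
    if k_asm < 2:
        raise ParameterError(f"k_asm must be >= 2, got {k_asm}")
    edges: dict[str, int] = {}
    for kmer in abundant_kmers:
        if k_asm > len(kmer):
            raise ParameterError(
                f"k_asm={k_asm} exceeds input k-mer length {len(kmer)}"
            )
        for i in range(len(kmer) - k_asm + 1):
            sub = canonical(kmer[i : i + k_asm])
            edges[sub] = edges.get(sub, 0) + 1
    return DeBruijnGraph(k_asm=k_asm, edges=edges)


def _extend_right(graph: DeBruijnGraph, seq: str, covs: list[int],
                  used: set[str], start_edge: str) -> tuple[str, list[int]]:
    """Grow a unitig rightward while the walk stays unambiguous."""
    k = graph.k_asm
    while True:
        node = seq[-(k - 1):]
        outs = graph.out_edges(node)
        if len(outs) != 1:
            break
        nxt = outs[0]
        # the next junction must also be unambiguous from its side
        if len(graph.in_edges(nxt[1:])) != 1:
            break
        key = canonical(nxt)
        if key in used or key == start_edge:
            break  # already consumed, or wrapped around a cycle
        used.add(key)
        seq += nxt[-1]
        covs.append(graph.edges[key])
    return seq, covs


def assemble_unitigs(graph: DeBruijnGraph, min_len: int = DEFAULT_MIN_LEN) -> RepeatLibrary:
    """Emit all maximal unambiguous paths as repeat consensuses.

    Every edge lies in exactly one unitig before the length filter;
    consensuses are canonically oriented (lexicographic min of sequence
    and reverse complement) and sorted by descending length then sequence,
    so identical inputs give byte-identical libraries.
    """
    if not graph.edges:
        return RepeatLibrary(consensuses=[], params={"k_asm": graph.k_asm,
                                                     "min_len": min_len})
    used: set[str] = set()
    raw: list[tuple[str, list[int]]] = []
    for edge in sorted(graph.edges):
        if edge in used:
            continue
        used.add(edge)
        seq, covs = _extend_right(graph, edge, [graph.edges[edge]], used, edge)
        # extend left by walking right from the reverse complement
        seq_rc, covs_rc = _extend_right(
            graph, revcomp(seq), covs[::-1], used, edge
        )
        seq, covs = revcomp(seq_rc), covs_rc[::-1]
        raw.append((seq, covs))

    consensuses = []
    for seq, covs in raw:
        if len(seq) < min_len:
            continue
        oriented = min(seq, revcomp(seq))
        consensuses.append((oriented, sum(covs) / len(covs)))
    consensuses.sort(key=lambda t: (-len(t[0]), t[0]))
    lib = [
        RepeatConsensus(id=f"repark_{i + 1}", seq=s, mean_cov=c)
        for i, (s, c) in enumerate(consensuses)
    ]
    return RepeatLibrary(
        consensuses=lib, params={"k_asm": graph.k_asm, "min_len": min_len}
    )


def clip_tips(
    graph: DeBruijnGraph, max_tip_edges: int = 4, min_cov_ratio: float = 0.5
) -> DeBruijnGraph:
    """Remove short, weakly covered dead-end paths (off by default upstream).

    A tip is a path of at most ``max_tip_edges`` edges starting at a node
    with no other incident edges and ending at a junction; it is removed
    when its mean coverage is below ``min_cov_ratio`` times the coverage
    of the strongest junction edge it attaches to. Idempotent.
    """
    if max_tip_edges < 1:
        raise ParameterError("max_tip_edges must be >= 1")
    removed: set[str] = set()

    def live_out(node: str) -> list[str]:
        return [e for e in graph.out_edges(node) if canonical(e) not in removed]

    def live_in(node: str) -> list[str]:
        return [e for e in graph.in_edges(node) if canonical(e) not in removed]

    for edge in sorted(graph.edges):
        if edge in removed:
            continue
        for oriented in (edge, revcomp(edge)):
            start = oriented[:-1]
            if live_in(start) or len(live_out(start)) != 1:
                continue  # the edge does not begin a dead end here
            path = [canonical(oriented)]
            cur = oriented
            junction = None
            while True:
                node = cur[1:]
                outs = live_out(node)
                ins = live_in(node)
                if len(ins) > 1 or len(outs) > 1:
                    junction = node
                    break
                if len(outs) == 0 or len(path) >= max_tip_edges:
                    break  # isolated path or tip too long: keep it
                cur = outs[0]
                path.append(canonical(cur))
            if junction is None:
                continue
            attach = [
                graph.edges[canonical(e)]
                for e in live_out(junction) + live_in(junction)
                if canonical(e) != path[-1]
            ]
            if not attach:
                continue
            mean_tip = sum(graph.edges[e] for e in path) / len(path)
            if mean_tip < min_cov_ratio * max(attach):
                removed.update(path)
                break  # this edge is gone; skip the other orientation
    kept = {e: c for e, c in graph.edges.items() if e not in removed}
    return DeBruijnGraph(k_asm=graph.k_asm, edges=kept)


def write_library(library: RepeatLibrary, path: str, wrap: int = 60) -> str:
    """FASTA with headers ``>repark_<n> len=<L> cov=<c>``."""
    with open(path, "wt") as out:
        for c in library.consensuses:
            out.write(f">{c.id} len={c.length} cov={c.mean_cov:.2f}\n")
            if wrap == 0:
                out.write(c.seq + "\n")
            else:
                for i in range(0, len(c.seq), wrap):
                    out.write(c.seq[i : i + wrap] + "\n")
    return path
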