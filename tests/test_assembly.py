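import random

import pytest

from repark.assembly import (
    DeBruijnGraph, assemble_unitigs, build_graph, clip_tips, write_library,
)
from repark.errors import ParameterError
from repark.kmer import canonical, count_kmers, histogram
from repark.simulate import RepeatFamilySpec, simulate_genome, simulate_reads
from repark.threshold import estimate_threshold, extract_abundant

from conftest import random_seq, rc


def kmers_of(seq: str, k: int) -> list[str]:
    return [seq[i : i + k] for i in range(len(seq) - k + 1)]


class TestBuildGraph:
    def test_single_kmer_same_k(self, rng):
        s = random_seq(rng, 31)
        g = build_graph({s}, k_asm=31)
        assert len(g.edges) == 1
        assert list(g.edges.values()) == [1]

    def test_single_kmer_smaller_k(self, rng):
        s = random_seq(rng, 31)
        g = build_graph({s}, k_asm=29)
        assert len(g.edges) == 3
        assert set(g.edges) == {canonical(w) for w in kmers_of(s, 29)}

    def test_k_asm_too_large(self, rng):
        with pytest.raises(ParameterError):
            build_graph({random_seq(rng, 31)}, k_asm=32)

    def test_planted_repeat_edges_are_unit_internal_kmers(self, rng):
        unit = random_seq(rng, 100)
        abundant = set(kmers_of(unit, 31))
        g = build_graph(abundant, k_asm=29)
        assert set(g.edges) == {canonical(w) for w in kmers_of(unit, 29)}


class TestAssembleUnitigs:
    def test_single_path(self, rng):
        seq = random_seq(rng, 10)
        g = build_graph({seq}, k_asm=8)  # 3-edge path
        lib = assemble_unitigs(g, min_len=1)
        assert len(lib) == 1
        cons = lib.consensuses[0]
        assert cons.length == 10
        assert cons.seq in (seq, rc(seq))

    def test_fork_splits_unitigs(self):
        # two 5-mers sharing a 4-mer prefix node: perfect fork
        a, b = "AACGT", "AACGG"
        g = build_graph({a, b}, k_asm=5)
        lib = assemble_unitigs(g, min_len=1)
        assert len(lib) == 2
        for cons in lib:
            for w in kmers_of(cons.seq, 5):
                assert g.has_edge(w)

    def test_edge_conservation(self, rng):
        reads = [random_seq(rng, 60) for _ in range(8)]
        abundant = {canonical(w) for s in reads for w in kmers_of(s, 31)}
        g = build_graph(abundant, k_asm=29)
        lib = assemble_unitigs(g, min_len=1)
        n_edges_in_unitigs = sum(c.length - 29 + 1 for c in lib)
        assert n_edges_in_unitigs == len(g.edges)

    def test_substring_soundness(self, rng):
        abundant = {canonical(random_seq(rng, 31)) for _ in range(30)}
        g = build_graph(abundant, k_asm=29)
        for cons in assemble_unitigs(g, min_len=1):
            for w in kmers_of(cons.seq, 29):
                assert g.has_edge(w)

    def test_strand_invariance(self, rng):
        abundant = [canonical(random_seq(rng, 31)) for _ in range(40)]
        lib_fwd = assemble_unitigs(build_graph(abundant, 29), min_len=1)
        lib_rev = assemble_unitigs(
            build_graph([rc(s) for s in abundant], 29), min_len=1
        )
        assert [c.seq for c in lib_fwd] == [c.seq for c in lib_rev]

    def test_determinism_under_input_order(self, rng):
        abundant = [canonical(random_seq(rng, 31)) for _ in range(40)]
        l1 = assemble_unitigs(build_graph(abundant, 29))
        shuffled = list(abundant)
        random.Random(1).shuffle(shuffled)
        l2 = assemble_unitigs(build_graph(shuffled, 29))
        assert [(c.id, c.seq, c.mean_cov) for c in l1] == [
            (c.id, c.seq, c.mean_cov) for c in l2
        ]

    def test_isolated_cycle_emitted_once(self, rng):
        circle = random_seq(rng, 200)
        doubled = circle + circle[:31]
        abundant = {canonical(w) for w in kmers_of(doubled, 31)[:200]}
        g = build_graph(abundant, k_asm=29)
        lib = assemble_unitigs(g, min_len=1)
        assert len(lib) == 1
        assert lib.consensuses[0].length == len(g.edges) + 28

    def test_empty_graph_gives_empty_library(self):
        lib = assemble_unitigs(DeBruijnGraph(k_asm=29, edges={}))
        assert len(lib) == 0 and lib.total_len == 0

    def test_min_len_filter(self, rng):
        abundant = {canonical(random_seq(rng, 31))}
        lib = assemble_unitigs(build_graph(abundant, 29), min_len=50)
        assert len(lib) == 0  # a lone 31-mer only reaches 31 bp


class TestPlantedRepeatReconstruction:
    def test_exact_unit_recovered(self):
        """Error-free planted repeat: one consensus, equal to the unit."""
        genome = simulate_genome(
            5_000, [RepeatFamilySpec("fam0", 100, 10, 0.0)], seed=11
        )
        reads = simulate_reads(genome, 100, 30.0, 0.0, seed=11)
        spec = count_kmers(reads, k=31)
        est = estimate_threshold(histogram(spec))
        abundant = extract_abundant(spec, est.T)
        lib = assemble_unitigs(build_graph(abundant, 29), min_len=50)
        assert len(lib) == 1
        unit = genome.masters["fam0"]
        assert lib.consensuses[0].seq in (unit, rc(unit))


class TestClipTips:
    def _path_graph(self, seq, k):
        return {canonical(w): 50 for w in kmers_of(seq, k)}

    def test_low_cov_tip_removed(self, rng):
        trunk = random_seq(rng, 30)
        edges = self._path_graph(trunk, 8)
        # 1-edge tip branching off an interior node
        node = trunk[10:17]
        tip = node + ("A" if trunk[17] != "A" else "C")
        edges[canonical(tip)] = 1
        g = DeBruijnGraph(k_asm=8, edges=edges)
        clipped = clip_tips(g, max_tip_edges=1, min_cov_ratio=0.5)
        assert canonical(tip) not in clipped.edges
        assert len(clipped.edges) == len(edges) - 1

    def test_no_dead_ends_unchanged(self, rng):
        circle = random_seq(rng, 100)
        edges = self._path_graph(circle + circle[:7], 8)
        g = DeBruijnGraph(k_asm=8, edges=edges)
        clipped = clip_tips(g, max_tip_edges=3, min_cov_ratio=0.9)
        assert clipped.edges == g.edges

    def test_idempotent(self, rng):
        trunk = random_seq(rng, 30)
        edges = self._path_graph(trunk, 8)
        node = trunk[10:17]
        tip = node + ("A" if trunk[17] != "A" else "C")
        edges[canonical(tip)] = 1
        g = DeBruijnGraph(k_asm=8, edges=edges)
        once = clip_tips(g, 1, 0.5)
        twice = clip_tips(once, 1, 0.5)
        assert once.edges == twice.edges

    def test_unitig_count_never_increases_on_noisy_repeat(self):
        genome = simulate_genome(
            3_000, [RepeatFamilySpec("f", 100, 10, 0.0)], seed=4
        )
        reads = simulate_reads(genome, 100, 30.0, 0.01, seed=4)
        spec = count_kmers(reads, k=31)
        abundant = extract_abundant(spec, 60)
        g = build_graph(abundant, 29)
        n_raw = len(assemble_unitigs(g, min_len=1))
        n_clipped = len(assemble_unitigs(clip_tips(g, 4, 0.5), min_len=1))
        assert n_clipped <= n_raw


def test_library_fasta_output(tmp_path, rng):
    abundant = {canonical(random_seq(rng, 31)) for _ in range(5)}
    lib = assemble_unitigs(build_graph(abundant, 29), min_len=1)
    p = tmp_path / "lib.fa"
    write_library(lib, str(p))
    text = p.read_text()
    assert text.count(">") == len(lib)
    assert "len=" in text and "cov=" in text
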