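import random

import pytest

from repark.assembly import RepeatConsensus, RepeatLibrary
from repark.errors import ParameterError
from repark.evaluate import (
    AlignmentHit, classify_repetitive, family_completeness, map_consensuses,
    mask_reference,
)
from repark.io_seq import SequenceRecord

from conftest import random_seq, rc


def library_of(*seqs):
    return RepeatLibrary(
        consensuses=[
            RepeatConsensus(id=f"c{i}", seq=s, mean_cov=10.0)
            for i, s in enumerate(seqs)
        ]
    )


def mutate(seq, rate, r):
    out = []
    for b in seq:
        if r.random() < rate:
            out.append(r.choice([x for x in "ACGT" if x != b]))
        else:
            out.append(b)
    return "".join(out)


class TestMapConsensuses:
    def test_exact_substring_twice(self, rng):
        cons = random_seq(rng, 120)
        spacer1, spacer2, spacer3 = (random_seq(rng, 300) for _ in range(3))
        ref = SequenceRecord(id="chr", seq=spacer1 + cons + spacer2 + cons + spacer3)
        hits = map_consensuses(library_of(cons), [ref])
        assert len(hits) == 2
        assert all(h.identity == 1.0 for h in hits)
        assert hits[0].t_start == 300 and hits[1].t_start == 720

    def test_reverse_complement_copy_found(self, rng):
        cons = random_seq(rng, 100)
        ref = SequenceRecord(
            id="chr", seq=random_seq(rng, 200) + rc(cons) + random_seq(rng, 200)
        )
        hits = map_consensuses(library_of(cons), [ref])
        assert len(hits) == 1
        assert hits[0].identity == 1.0
        assert hits[0].strand == "-"

    def test_absent_consensus_no_hits(self, rng):
        hits = map_consensuses(
            library_of(random_seq(rng, 100)),
            [SequenceRecord(id="chr", seq=random_seq(rng, 2000))],
        )
        assert hits == []

    def test_short_consensus_skipped(self, rng):
        lib = library_of("ACGTACGTAC")  # 10 bp < seed_len
        ref = SequenceRecord(id="chr", seq=random_seq(rng, 500))
        assert map_consensuses(lib, [ref], seed_len=16) == []

    def test_mutated_copies_identity_near_rate(self, rng):
        cons = random_seq(rng, 400)
        parts = [random_seq(rng, 200)]
        for _ in range(5):
            parts.append(mutate(cons, 0.10, rng))
            parts.append(random_seq(rng, 200))
        ref = SequenceRecord(id="chr", seq="".join(parts))
        hits = map_consensuses(library_of(cons), [ref])
        assert len(hits) == 5
        for h in hits:
            assert h.identity == pytest.approx(0.90, abs=0.03)
            assert h.identity >= 0.80

    def test_deterministic_ordering(self, rng):
        cons = random_seq(rng, 100)
        ref = SequenceRecord(
            id="chr",
            seq=random_seq(rng, 100) + cons + random_seq(rng, 100) + cons,
        )
        h1 = map_consensuses(library_of(cons), [ref])
        h2 = map_consensuses(library_of(cons), [ref])
        assert h1 == h2

    def test_strand_symmetry_of_reference(self, rng):
        cons = random_seq(rng, 150)
        body = random_seq(rng, 300) + cons + random_seq(rng, 300) + cons
        fwd = SequenceRecord(id="chr", seq=body)
        rev = SequenceRecord(id="chr", seq=rc(body))
        hf = map_consensuses(library_of(cons), [fwd])
        hr = map_consensuses(library_of(cons), [rev])
        assert len(hf) == len(hr) == 2
        assert sorted(h.identity for h in hf) == sorted(h.identity for h in hr)

    def test_empty_inputs_rejected(self, rng):
        with pytest.raises(ParameterError):
            map_consensuses(library_of(), [SequenceRecord(id="c", seq="ACGT")])


class TestClassifyRepetitive:
    def _hits(self, spec):
        return [
            AlignmentHit(
                query_id=q, target_id="chr", t_start=100 * i, t_end=100 * i + 50,
                strand="+", identity=ident, q_cov=1.0,
            )
            for i, (q, ident) in enumerate(spec)
        ]

    def test_two_qualifying_hits_is_repetitive(self, rng):
        lib = library_of(random_seq(rng, 60))
        hits = self._hits([("c0", 0.85), ("c0", 0.85)])
        rep = classify_repetitive(hits, lib)
        assert rep.repetitive_count == 1 and rep.non_repetitive_count == 0

    def test_single_qualifying_hit_is_not(self, rng):
        lib = library_of(random_seq(rng, 60))
        hits = self._hits([("c0", 1.0), ("c0", 0.79)])
        rep = classify_repetitive(hits, lib)
        assert rep.repetitive_count == 0 and rep.non_repetitive_count == 1

    def test_partition_conserves_total_length(self, rng):
        r = random.Random(5)
        lib = library_of(*(random_seq(rng, r.randint(50, 200)) for _ in range(10)))
        hits = self._hits(
            [(f"c{r.randint(0, 9)}", r.uniform(0.5, 1.0)) for _ in range(40)]
        )
        for thr in (0.5, 0.8, 0.95):
            rep = classify_repetitive(hits, lib, thr)
            assert rep.repetitive_len + rep.non_repetitive_len == lib.total_len

    def test_monotone_in_identity_threshold(self, rng):
        r = random.Random(6)
        lib = library_of(*(random_seq(rng, 60) for _ in range(8)))
        hits = self._hits(
            [(f"c{r.randint(0, 7)}", r.uniform(0.5, 1.0)) for _ in range(60)]
        )
        counts = [
            classify_repetitive(hits, lib, t).repetitive_count
            for t in (0.5, 0.8, 0.95, 0.99)
        ]
        assert counts == sorted(counts, reverse=True)


class TestMaskReference:
    def _hit(self, s, e, ident=0.9):
        return AlignmentHit(
            query_id="q", target_id="chr", t_start=s, t_end=e, strand="+",
            identity=ident, q_cov=1.0,
        )

    def test_interval_union(self):
        ref = [SequenceRecord(id="chr", seq="A" * 200)]
        frac = mask_reference([self._hit(0, 50), self._hit(25, 100)], ref)
        assert frac == 0.5

    def test_no_hits_zero(self):
        assert mask_reference([], [SequenceRecord(id="chr", seq="A" * 100)]) == 0.0

    def test_out_of_range_rejected(self):
        ref = [SequenceRecord(id="chr", seq="A" * 100)]
        with pytest.raises(ParameterError):
            mask_reference([self._hit(50, 150)], ref)

    def test_monotone_nonincreasing_in_identity(self):
        ref = [SequenceRecord(id="chr", seq="A" * 1000)]
        r = random.Random(2)
        hits = [
            self._hit(s, s + 50, r.uniform(0.5, 1.0))
            for s in r.sample(range(900), 30)
        ]
        fracs = [mask_reference(hits, ref, t) for t in (0.5, 0.7, 0.9)]
        assert fracs == sorted(fracs, reverse=True)


class TestFamilyCompleteness:
    def test_identical_consensus_full_coverage(self, rng):
        fam = SequenceRecord(id="famA", seq=random_seq(rng, 200))
        assert family_completeness([fam], library_of(fam.seq)) == {"famA": 1.0}

    def test_unrelated_family_zero(self, rng):
        fam = SequenceRecord(id="famA", seq=random_seq(rng, 200))
        lib = library_of(random_seq(rng, 200))
        assert family_completeness([fam], lib) == {"famA": 0.0}

    def test_family_split_across_two_consensuses(self, rng):
        fam_seq = random_seq(rng, 120)
        fam = SequenceRecord(id="famA", seq=fam_seq)
        lib = library_of(fam_seq[0:60], fam_seq[55:120])
        assert family_completeness([fam], lib, seed_len=16) == {"famA": 1.0}
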