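import random

import pytest

from repark.io_seq import SequenceRecord

_COMP = str.maketrans("ACGT", "TGCA")


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def brute_force_spectrum(reads, k):
    """Independent oracle: enumerate every substring, canonicalize by hand."""
    counts = {}
    for rec in reads:
        seq = rec.seq if isinstance(rec, SequenceRecord) else rec
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if "N" in w:
                continue
            w = min(w, rc(w))
            counts[w] = counts.get(w, 0) + 1
    return counts


def random_seq(rng: random.Random, n: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(alphabet) for _ in range(n))


@pytest.fixture
def rng():
    return random.Random(20240917)


def make_reads(rng: random.Random, n_reads: int, length: int, with_n=False) -> list:
    alphabet = "ACGTN" if with_n else "ACGT"
    return [
        SequenceRecord(id=f"r{i}", seq=random_seq(rng, length, alphabet))
        for i in range(n_reads)
    ]
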