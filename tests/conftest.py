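"""Shared fixtures and fixture builders for the test-suite.

All fixtures are generated programmatically; nothing is read from disk
except files the tests themselves write to tmp_path.
"""

from __future__ import annotations

import numpy as np
import pytest

from phagealign.genome_io import Genome, GenomeSet

BASES = "ACGT"


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def genome_set(*seqs: str, ids=None) -> GenomeSet:
    ids = ids or [f"g{i}" for i in range(len(seqs))]
    return GenomeSet([Genome(gid, seq) for gid, seq in zip(ids, seqs)])


def distinct_flanks(rng: np.random.Generator, n: int, lo: int = 30, hi: int = 51):
    """Per-genome random flanks whose block-adjacent base differs everywhere.

    Returns (left_flanks, right_flanks): the last base of each left
    flank and the first base of each right flank are pairwise distinct
    (n <= 4), so no exact match can extend across the block boundary.
    """
    assert n <= 4
    lefts, rights = [], []
    for g in range(n):
        left = random_seq(rng, int(rng.integers(lo, hi)))
        right = random_seq(rng, int(rng.integers(lo, hi)))
        lefts.append(left[:-1] + BASES[g])
        rights.append(BASES[g] + right[1:])
    return lefts, rights


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def transposition_pair(rng: np.random.Generator, block_len: int = 12,
                       segment_len: int = 150) -> GenomeSet:
    """Two genomes identical except for a transposed block pair.

    g0 = A X B Y C and g1 = A Y B X C with X, Y of ``block_len`` bp and
    junction bases chosen so the X/X and Y/Y matches have exactly
    ``block_len`` bp: the column graph is cyclic for m <= block_len and
    acyclic above.
    """
    a = random_seq(rng, segment_len)
    b = random_seq(rng, segment_len)
    c = random_seq(rng, segment_len)
    x = random_seq(rng, block_len)
    y = random_seq(rng, block_len)
    # force the four junction contexts to differ between the two genomes
    a0, a1 = a[:-1] + "A", a[:-1] + "C"
    b0, b1 = "A" + b[1:-1] + "A", "C" + b[1:-1] + "C"
    c0, c1 = "A" + c[1:], "C" + c[1:]
    g0 = a0 + x + b0 + y + c0
    g1 = a1 + y + b1 + x + c1
    return genome_set(g0, g1)
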