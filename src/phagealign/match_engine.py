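"""Maximal exact match (MEM) enumeration between genome pairs.

The whole alignment rests on *matches*: asserted exact equalities
between two same-length segments of two genomes.  This module
enumerates every maximal exact match of length >= m between every
unordered genome pair (forward strand, inter-genome only), and finds
the minimal m for which the resulting column graph is acyclic.

MEMs are found by exact seed-and-extend: every MEM of length >= m
contains a shared k-mer (k = min(m, 21)), so hashing the k-mers of one
sequence and extending each shared occurrence maximally enumerates all
of them; a per-diagonal coverage map removes redundant seeds, since two
seeds on the same diagonal inside one MEM extend to the same MEM.
`N` never matches anything, including itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Sequence, Tuple

from .errors import MatchBoundsError, TooFewGenomesError

_SEED_CAP = 21  # seeds longer than this gain nothing and slow hashing


@dataclass(frozen=True, order=True)
class Match:
    """An exact equality between genome_a[start_a..] and genome_b[start_b..].

    Coordinates are 1-based inclusive; ``length`` >= 1 and the two
    segments are character-identical over {A,C,G,T}.
    """

    genome_a: str
    start_a: int
    genome_b: str
    start_b: int
    length: int

    @property
    def end_a(self) -> int:
        return self.start_a + self.length - 1

    @property
    def end_b(self) -> int:
        return self.start_b + self.length - 1


@dataclass
class MatchSet:
    """All matches of length >= m, each unordered pair stored once."""

    matches: List[Match]
    m: int

    @property
    def total_match_length(self) -> int:
        """Sum of match lengths, each pairwise match counted once (M_l)."""
        return sum(match.length for match in self.matches)

    def __len__(self) -> int:
        return len(self.matches)

    def __iter__(self):
        return iter(self.matches)

    def filtered(self, m: int) -> "MatchSet":
        """The subset of matches with length >= m.

        MEM maximality does not depend on the threshold, so filtering a
        MatchSet computed at a smaller m is equivalent to recomputing.
        """
        if m < self.m:
            raise ValueError(f"cannot filter down to m={m} < {self.m}")
        return MatchSet([x for x in self.matches if x.length >= m], m)


def _pair_mems(a: str, b: str, m: int) -> List[Tuple[int, int, int]]:
    """All MEMs of length >= m between two sequences.

    Returns 0-based (start_a, start_b, length) triples.
    """
    la, lb = len(a), len(b)
    if la < m or lb < m:
        return []
    k = min(m, _SEED_CAP)
    index: dict = {}
    for i in range(la - k + 1):
        word = a[i:i + k]
        if "N" in word:
            continue
        index.setdefault(word, []).append(i)
    out: List[Tuple[int, int, int]] = []
    covered: dict = {}  # diagonal (i - j) -> inclusive end in a of last MEM
    for j in range(lb - k + 1):
        word = b[j:j + k]
        hits = index.get(word)
        if hits is None:
            continue
        for i in hits:
            diag = i - j
            # a later seed on the same diagonal cannot cross the mismatch
            # that ended the previous MEM, so start <= end means "inside"
            if covered.get(diag, -1) >= i:
                continue
            sa, sb = i, j
            while sa > 0 and sb > 0 and a[sa - 1] == b[sb - 1] and a[sa - 1] != "N":
                sa -= 1
                sb -= 1
            ea, eb = i + k, j + k  # exclusive
            while ea < la and eb < lb and a[ea] == b[eb] and a[ea] != "N":
                ea += 1
                eb += 1
            covered[diag] = ea - 1
            if ea - sa >= m:
                out.append((sa, sb, ea - sa))
    out.sort()
    return out


def find_mems(genomes, m: int) -> MatchSet:
    """Every maximal exact match of length >= m between every genome pair.

    Forward strand only, inter-genome only.  Output is deterministic:
    sorted by genome pair, then start_a, then start_b.  ``genomes`` is a
    GenomeSet (any object with an ordered ``genomes`` sequence of
    ``id``/``seq`` records).
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    glist = list(genomes.genomes)
    if len(glist) < 2:
        raise TooFewGenomesError("at least two genomes are required to find matches")
    matches: List[Match] = []
    for ia in range(len(glist)):
        for ib in range(ia + 1, len(glist)):
            ga, gb = glist[ia], glist[ib]
            for sa, sb, length in _pair_mems(ga.seq, gb.seq, m):
                matches.append(Match(ga.id, sa + 1, gb.id, sb + 1, length))
    return MatchSet(matches, m)


def auto_m(genomes, m_start: int = 15, ceiling: int = 500) -> Tuple[int, MatchSet]:
    """Smallest m >= m_start whose column graph is acyclic, with its matches.

    Searches upward one unit at a time (a cycle at m means some
    rearranged repeat of length >= m still matches; raising m past its
    length removes it).  Raises AutoMCeilingError, carrying the
    remaining strongly connected components as rearrangement evidence,
    if the ceiling is reached while still cyclic.
    """
    from . import alignment_graph, column_builder
    from .errors import AutoMCeilingError

    if m_start < 1:
        raise ValueError("m_start must be >= 1")
    base = find_mems(genomes, m_start)
    last_sccs = []
    for m in range(m_start, ceiling + 1):
        subset = base.filtered(m)
        partition = column_builder.split_invalid(
            column_builder.build_columns(genomes, subset))
        report = alignment_graph.collinearity_from_partition(partition, genomes)
        if report.ok:
            return m, subset
        last_sccs = report.sccs
    raise AutoMCeilingError(
        f"column graph still cyclic at m={ceiling}; "
        f"{len(last_sccs)} strongly connected component(s) indicate rearrangements",
        sccs=last_sccs,
    )


def write_matches_tsv(matches: MatchSet, path) -> None:
    """genome_a<TAB>start_a<TAB>genome_b<TAB>start_b<TAB>length, one per line."""
    with open(path, "w") as handle:
        for x in matches:
            handle.write(f"{x.genome_a}\t{x.start_a}\t{x.genome_b}\t{x.start_b}\t{x.length}\n")


def read_matches_tsv(path, m: int) -> MatchSet:
    """Read matches in the TSV interchange format (external MEM finders)."""
    matches = []
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            ga, sa, gb, sb, length = line.split("\t")
            matches.append(Match(ga, int(sa), gb, int(sb), int(length)))
    matches.sort()
    return MatchSet(matches, m)
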