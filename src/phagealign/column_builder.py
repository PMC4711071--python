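"""Alignment columns as Union-Find equivalence classes of genome positions.

Each match asserts per-base equalities between two genomes; the columns
of the multiple alignment are the equivalence classes of genome
positions under the transitive closure of those assertions.  A column
is *valid* when it holds at most one position per genome; invalid
columns (the footprint of duplications and tandem repeats) are split
into singletons.

Positions are manipulated internally as 0-based global indices into the
concatenation of all genomes; the public Position/Column views use
1-based per-genome offsets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, List, Tuple

import numpy as np

from .errors import MatchBoundsError


@dataclass(frozen=True, order=True)
class Position:
    """Position ``offset`` (1-based) of genome number ``genome_index``."""

    genome_index: int
    offset: int


@dataclass(frozen=True)
class Column:
    """An equivalence class of genome positions with its support."""

    positions: frozenset
    support: frozenset

    @property
    def valid(self) -> bool:
        """At most one position per genome (|positions| == |support|)."""
        return len(self.positions) == len(self.support)


def genome_starts(genomes) -> np.ndarray:
    """Cumulative 0-based start of each genome in the concatenation (len n+1)."""
    lengths = [g.length for g in genomes]
    return np.concatenate([[0], np.cumsum(lengths)]).astype(np.int64)


class ColumnPartition:
    """A partition of every genome position into columns.

    ``col_of[p]`` is the column id of global position ``p``;
    ``columns[c]`` is the sorted array of global positions in column
    ``c``.  Column ids are assigned in order of each column's smallest
    position, so the numbering is deterministic.
    """

    def __init__(self, genomes, col_of: np.ndarray, columns: List[np.ndarray]):
        self.genomes = genomes
        self.col_of = col_of
        self.columns = columns
        self.starts = genome_starts(genomes)

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    @property
    def n_positions(self) -> int:
        return int(self.col_of.shape[0])

    def genome_of(self, gpos) -> np.ndarray:
        """Genome index of each global position."""
        return np.searchsorted(self.starts, np.asarray(gpos), side="right") - 1

    def to_local(self, gpos: int) -> Position:
        gi = int(self.genome_of(gpos))
        return Position(gi, int(gpos - self.starts[gi] + 1))

    def global_index(self, genome_index: int, offset: int) -> int:
        return int(self.starts[genome_index]) + offset - 1

    def column_id_at(self, genome_index: int, offset: int) -> int:
        return int(self.col_of[self.global_index(genome_index, offset)])

    def column(self, cid: int) -> Column:
        members = self.columns[cid]
        gidx = self.genome_of(members)
        positions = frozenset(
            Position(int(gi), int(p - self.starts[gi] + 1))
            for gi, p in zip(gidx, members))
        return Column(positions, frozenset(int(g) for g in gidx))

    def supports(self, cid: int) -> np.ndarray:
        return np.unique(self.genome_of(self.columns[cid]))

    def iter_multi_columns(self) -> Iterator[int]:
        """Ids of columns holding more than one position."""
        for cid, members in enumerate(self.columns):
            if len(members) > 1:
                yield cid

    def is_valid_partition(self) -> bool:
        for cid in self.iter_multi_columns():
            members = self.columns[cid]
            if np.unique(self.genome_of(members)).size != members.size:
                return False
        return True


def _find(parent: List[int], x: int) -> int:
    while parent[x] != x:
        parent[x] = parent[parent[x]]  # path halving
        x = parent[x]
    return x


def build_columns(genomes, matches) -> ColumnPartition:
    """Union-Find transitive closure of the per-base equalities in ``matches``.

    Every unmatched position ends up in its own singleton column.  The
    result may contain invalid columns; apply :func:`split_invalid`.
    """
    starts = genome_starts(genomes)
    total = int(starts[-1])
    parent = list(range(total))
    size = [1] * total
    index = {g.id: i for i, g in enumerate(genomes)}

    for match in matches:
        ia, ib = index[match.genome_a], index[match.genome_b]
        la = genomes[ia].length
        lb = genomes[ib].length
        if not (1 <= match.start_a and match.end_a <= la
                and 1 <= match.start_b and match.end_b <= lb):
            raise MatchBoundsError(f"match out of genome bounds: {match}")
        pa = int(starts[ia]) + match.start_a - 1
        pb = int(starts[ib]) + match.start_b - 1
        for t in range(match.length):
            ra = _find(parent, pa + t)
            rb = _find(parent, pb + t)
            if ra == rb:
                continue
            if size[ra] < size[rb]:
                ra, rb = rb, ra
            parent[rb] = ra
            size[ra] += size[rb]

    col_of = np.empty(total, dtype=np.int64)
    columns: List[List[int]] = []
    root_to_cid: dict = {}
    for p in range(total):
        r = _find(parent, p)
        cid = root_to_cid.get(r)
        if cid is None:
            cid = len(columns)
            root_to_cid[r] = cid
            columns.append([])
        columns[cid].append(p)
        col_of[p] = cid
    arrays = [np.asarray(c, dtype=np.int64) for c in columns]
    return ColumnPartition(genomes, col_of, arrays)


def split_invalid(partition: ColumnPartition) -> ColumnPartition:
    """Split every column holding two or more positions of one genome.

    The whole offending column becomes singletons, one per position;
    valid columns pass through untouched.  Idempotent.
    """
    col_of = partition.col_of.copy()
    columns: List[np.ndarray] = []
    for members in partition.columns:
        if members.size > 1:
            gidx = partition.genome_of(members)
            if np.unique(gidx).size != members.size:
                for p in members:
                    col_of[p] = len(columns)
                    columns.append(np.asarray([p], dtype=np.int64))
                continue
        cid = len(columns)
        columns.append(members)
        col_of[members] = cid
    return ColumnPartition(partition.genomes, col_of, columns)


def write_columns_tsv(partition: ColumnPartition, path) -> None:
    """Debug dump: column_id<TAB>genome<TAB>position (1-based)."""
    with open(path, "w") as handle:
        for cid, members in enumerate(partition.columns):
            for p in members:
                pos = partition.to_local(int(p))
                gid = partition.genomes[pos.genome_index].id
                handle.write(f"{cid}\t{gid}\t{pos.offset}\n")
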