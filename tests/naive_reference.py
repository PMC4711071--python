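"""Independent brute-force reference implementation used as a test oracle.

Everything here is deliberately naive and mechanism-independent of the
package: MEMs come from a quadratic dynamic program over the full
equality matrix, columns from repeated set-merging (no union-find),
cycle detection from Kosaraju's algorithm written out by hand, merging
from dict walks, and contraction from reachability sets computed by
DFS.  Outputs are canonical structures (frozensets / sorted tuples)
that the package's results are converted to for comparison.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Dict, FrozenSet, List, Set, Tuple

import numpy as np

Pos = Tuple[int, int]          # (genome_index, 1-based offset)
ColKey = FrozenSet[Pos]


# ---------------------------------------------------------------------------
# MEMs: full dynamic program over the equality matrix


def naive_mems(a: str, b: str, m: int) -> Set[Tuple[int, int, int]]:
    """All maximal exact matches of length >= m as 1-based (sa, sb, len)."""
    arr_a = np.frombuffer(a.encode(), dtype=np.uint8)
    arr_b = np.frombuffer(b.encode(), dtype=np.uint8)
    la, lb = len(arr_a), len(arr_b)
    if la == 0 or lb == 0:
        return set()
    eq = (arr_a[:, None] == arr_b[None, :]) & (arr_a[:, None] != ord("N"))
    run = np.zeros((la, lb), dtype=np.int32)
    run[0, :] = eq[0, :]
    run[:, 0] = eq[:, 0]
    for i in range(1, la):
        run[i, 1:] = np.where(eq[i, 1:], run[i - 1, :-1] + 1, 0)
    # a cell ends a maximal run when the next diagonal cell is not equal
    ext = np.zeros((la, lb), dtype=bool)
    ext[:la - 1, :lb - 1] = eq[1:, 1:]
    ends = (run >= m) & ~ext
    out = set()
    for i, j in np.argwhere(ends):
        length = int(run[i, j])
        out.add((int(i) - length + 2, int(j) - length + 2, length))
    return out


def naive_find_mems(genomes, m: int) -> Set[Tuple[str, int, str, int, int]]:
    out = set()
    glist = list(genomes.genomes)
    for ia in range(len(glist)):
        for ib in range(ia + 1, len(glist)):
            for sa, sb, length in naive_mems(glist[ia].seq, glist[ib].seq, m):
                out.add((glist[ia].id, sa, glist[ib].id, sb, length))
    return out


# ---------------------------------------------------------------------------
# columns: repeated set-merging


def naive_columns(genomes, matches) -> Set[ColKey]:
    """Transitive closure of match equalities; singletons for the rest."""
    glist = list(genomes.genomes)
    index = {g.id: i for i, g in enumerate(glist)}
    owner: Dict[Pos, Set[Pos]] = {}

    def get(pos: Pos) -> Set[Pos]:
        if pos not in owner:
            owner[pos] = {pos}
        return owner[pos]

    for match in matches:
        ia, ib = index[match.genome_a], index[match.genome_b]
        for t in range(match.length):
            pa = (ia, match.start_a + t)
            pb = (ib, match.start_b + t)
            sa, sb = get(pa), get(pb)
            if sa is sb:
                continue
            if len(sa) < len(sb):
                sa, sb = sb, sa
            sa |= sb
            for pos in sb:
                owner[pos] = sa
    cols = {frozenset(s) for s in owner.values()}
    for gi, g in enumerate(glist):
        for off in range(1, g.length + 1):
            if (gi, off) not in owner:
                cols.add(frozenset({(gi, off)}))
    return cols


def naive_split(columns: Set[ColKey]) -> Set[ColKey]:
    out = set()
    for col in columns:
        genomes_seen = [gi for gi, _off in col]
        if len(set(genomes_seen)) != len(col):
            for pos in col:
                out.add(frozenset({pos}))
        else:
            out.add(col)
    return out


def naive_column_edges(columns: Set[ColKey], genomes) -> Set[Tuple[ColKey, ColKey, int]]:
    """(from_column, to_column, genome) for every consecutive position pair."""
    where: Dict[Pos, ColKey] = {}
    for col in columns:
        for pos in col:
            where[pos] = col
    edges = set()
    for gi, g in enumerate(genomes.genomes):
        for off in range(1, g.length):
            edges.add((where[(gi, off)], where[(gi, off + 1)], gi))
    return edges


# ---------------------------------------------------------------------------
# cycle detection: Kosaraju by hand


def naive_sccs(nodes, edges: Set[Tuple]) -> List[Set]:
    succ: Dict = {n: [] for n in nodes}
    pred: Dict = {n: [] for n in nodes}
    for u, v in edges:
        succ[u].append(v)
        pred[v].append(u)
    order = []
    seen = set()
    for start in nodes:
        if start in seen:
            continue
        stack = [(start, iter(succ[start]))]
        seen.add(start)
        while stack:
            node, it = stack[-1]
            advanced = False
            for nxt in it:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append((nxt, iter(succ[nxt])))
                    advanced = True
                    break
            if not advanced:
                order.append(node)
                stack.pop()
    comps = []
    assigned = set()
    for start in reversed(order):
        if start in assigned:
            continue
        comp = {start}
        assigned.add(start)
        stack = [start]
        while stack:
            node = stack.pop()
            for nxt in pred[node]:
                if nxt not in assigned:
                    assigned.add(nxt)
                    comp.add(nxt)
                    stack.append(nxt)
        comps.append(comp)
    return comps


def naive_is_cyclic(columns: Set[ColKey], genomes) -> bool:
    edges = {(u, v) for u, v, _gi in naive_column_edges(columns, genomes)}
    comps = naive_sccs(list(columns), edges)
    if any(len(c) > 1 for c in comps):
        return True
    return any(u == v for u, v in edges)


# ---------------------------------------------------------------------------
# merging and contraction on dicts

NVertex = Tuple[Tuple[Tuple[int, Tuple[int, int]], ...], Fraction]
# canonical: (sorted ((genome, (start, end)), ...), identity fraction)


def _vertex(segments: Dict[int, Tuple[int, int]], identity: Fraction) -> NVertex:
    return (tuple(sorted(segments.items())), identity)


def naive_merge(columns: Set[ColKey], genomes) -> List[Dict[int, Tuple[int, int]]]:
    """Merge consecutive same-support column runs; returns segment dicts."""
    where: Dict[Pos, ColKey] = {}
    for col in columns:
        for pos in col:
            where[pos] = col
    lengths = {gi: g.length for gi, g in enumerate(genomes.genomes)}

    def successor(col: ColKey):
        succ = set()
        for gi, off in col:
            if off + 1 > lengths[gi]:
                return None
            succ.add(where[(gi, off + 1)])
        if len(succ) != 1:
            return None
        nxt = succ.pop()
        if len(nxt) != len(col):
            return None
        return nxt

    nxt_map: Dict[ColKey, ColKey] = {}
    has_prev: Set[ColKey] = set()
    for col in columns:
        nxt = successor(col)
        if nxt is not None:
            nxt_map[col] = nxt
            has_prev.add(nxt)

    vertices = []
    for col in columns:
        if col in has_prev:
            continue
        run = 1
        cur = col
        while cur in nxt_map:
            cur = nxt_map[cur]
            run += 1
        segments = {gi: (off, off + run - 1) for gi, off in col}
        vertices.append(segments)
    return vertices


def _identity_of(genomes, segments: Dict[int, Tuple[int, int]]) -> Fraction:
    rows = [genomes.genomes[gi].seq[s - 1:e] for gi, (s, e) in sorted(segments.items())]
    length = len(rows[0])
    same = 0
    for k in range(length):
        chars = {row[k] for row in rows}
        if len(chars) == 1 and "N" not in chars:
            same += 1
    return Fraction(same, length)


def naive_contract(vertices: List[Dict[int, Tuple[int, int]]], genomes) -> Set[NVertex]:
    """Greedy topological-order contraction using brute-force reachability.

    "Between U and V" is taken literally: every vertex reachable from U
    that reaches V, computed by DFS on the vertex DAG.
    """
    import heapq

    verts = [dict(v) for v in vertices]
    n = len(verts)

    def sort_key(i):
        gi = min(verts[i])
        return (gi, verts[i][gi][0])

    # vertex DAG edges from per-genome segment order
    succ: Dict[int, Set[int]] = {i: set() for i in range(n)}
    pred: Dict[int, Set[int]] = {i: set() for i in range(n)}
    by_genome: Dict[int, List[int]] = {}
    for i, v in enumerate(verts):
        for gi in v:
            by_genome.setdefault(gi, []).append(i)
    for gi, ids in by_genome.items():
        ids.sort(key=lambda i: verts[i][gi][0])
        for u, w in zip(ids, ids[1:]):
            succ[u].add(w)
            pred[w].add(u)

    # canonical topological order: Kahn's algorithm with a key heap
    indeg = {i: len(pred[i]) for i in range(n)}
    heap = [(sort_key(i), i) for i in range(n) if indeg[i] == 0]
    heapq.heapify(heap)
    topo = []
    while heap:
        _key, node = heapq.heappop(heap)
        topo.append(node)
        for nxt in succ[node]:
            indeg[nxt] -= 1
            if indeg[nxt] == 0:
                heapq.heappush(heap, (sort_key(nxt), nxt))
    assert len(topo) == n, "vertex graph is cyclic"

    _fwd_cache: Dict[int, Set[int]] = {}

    def reach_fwd(src: int) -> Set[int]:
        if src not in _fwd_cache:
            seen = {src}
            stack = [src]
            while stack:
                node = stack.pop()
                for nxt in succ[node]:
                    if nxt not in seen:
                        seen.add(nxt)
                        stack.append(nxt)
            _fwd_cache[src] = seen
        return _fwd_cache[src]

    # same-support vertices are totally ordered; index them per class
    classes: Dict[FrozenSet[int], List[int]] = {}
    for i in range(n):
        classes.setdefault(frozenset(verts[i]), []).append(i)
    for ids in classes.values():
        ids.sort(key=sort_key)
    class_pos = {i: k for ids in classes.values() for k, i in enumerate(ids)}

    consumed = [False] * n
    result: List[Dict[int, Tuple[int, int]]] = []
    for u in topo:
        if consumed[u]:
            continue
        consumed[u] = True
        support = frozenset(verts[u])
        ids = classes[support]
        chain = [u]
        absorbed: Set[int] = set()
        last = u
        while True:
            nxt_pos = class_pos[last] + 1
            if nxt_pos >= len(ids):
                break
            v = ids[nxt_pos]
            if consumed[v]:
                break
            between = {x for x in reach_fwd(last) - {last, v}
                       if v in reach_fwd(x)}
            if any(consumed[x] for x in between):
                break
            if not all(frozenset(verts[x]) <= support for x in between):
                break
            spans = {verts[v][gi][1] - verts[last][gi][0] + 1 for gi in support}
            if len(spans) != 1:
                break
            chain.append(v)
            absorbed |= between
            consumed[v] = True
            last = v
        if len(chain) == 1:
            result.append(verts[u])
            continue
        for x in absorbed:
            consumed[x] = True
        result.append({gi: (verts[u][gi][0], verts[last][gi][1])
                       for gi in support})
    return {_vertex(v, _identity_of(genomes, v)) for v in result}


# ---------------------------------------------------------------------------
# canonicalisation of package results for comparison


def canon_partition(partition) -> Set[ColKey]:
    out = set()
    for cid in range(partition.n_columns):
        col = partition.column(cid)
        out.add(frozenset((p.genome_index, p.offset) for p in col.positions))
    return out


def canon_partition_edges(partition, genomes) -> Set[Tuple[ColKey, ColKey, int]]:
    cols = {cid: frozenset((p.genome_index, p.offset)
                           for p in partition.column(cid).positions)
            for cid in range(partition.n_columns)}
    edges = set()
    for gi, g in enumerate(genomes.genomes):
        for off in range(1, g.length):
            edges.add((cols[partition.column_id_at(gi, off)],
                       cols[partition.column_id_at(gi, off + 1)], gi))
    return edges


def canon_graph(graph) -> Set[NVertex]:
    return {_vertex(dict(v.segments), v.identity) for v in graph.vertices}
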