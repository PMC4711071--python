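"""The column graph and its condensations: exact and gapless alignments.

The column graph links columns by per-genome positional adjacency; the
genome set is functionally collinear exactly when that graph is acyclic.
Consecutive columns with identical support merge into *exact* alignment
vertices; chains of same-support vertices whose spanning segments have
equal length in every supported genome *contract* further into gapless
alignment vertices carrying a percent-identity statistic.  Vertices
supported by the full genome set are *anchors*; the ordered anchors
form the backbone, and the region between two anchors can be re-aligned
on its own (usually at a smaller m).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np

from .column_builder import ColumnPartition, genome_starts
from .errors import AnchorOrderError, CyclicGraphError


@dataclass
class AlignmentVertex:
    """A set of equal-length per-genome segments forming a gapless alignment.

    ``segments`` maps genome index to a 1-based inclusive (start, end)
    pair; all segments have length ``length``.  ``identity`` is the
    exact fraction of columns in which every supported genome carries
    the same nucleotide (1 for exact vertices); displayed percentages
    are truncated, not rounded.  ``kind`` is ``exact`` (>=2 genomes, all
    rows identical), ``singleton`` (one genome, unaligned), or
    ``contracted``.  For contracted vertices ``parts`` keeps the merged
    sub-vertices so the expansion can be recovered.
    """

    segments: Dict[int, Tuple[int, int]]
    length: int
    identity: Fraction
    kind: str
    parts: Optional[List["AlignmentVertex"]] = None

    @property
    def support(self) -> frozenset:
        return frozenset(self.segments)

    @property
    def identity_percent(self) -> int:
        """Identity as a truncated (floored) integer percentage."""
        return (self.identity.numerator * 100) // self.identity.denominator

    def segment(self, genome_index: int) -> Tuple[int, int]:
        return self.segments[genome_index]

    def sort_key(self) -> Tuple[int, int]:
        g = min(self.segments)
        return (g, self.segments[g][0])

    def canonical(self, genomes) -> Tuple:
        segs = tuple(sorted((genomes[g].id, s, e) for g, (s, e) in self.segments.items()))
        return (segs, self.identity)


@dataclass(frozen=True)
class Edge:
    """Per-genome successor link; skipped_bp counts bases hidden between."""

    genome_index: int
    source: int
    target: int
    skipped_bp: int


@dataclass
class CollinearityReport:
    """OK, or the nontrivial strongly connected components as evidence.

    Each SCC is reported as a dict mapping genome id to the (min, max)
    1-based positions its columns touch in that genome.
    """

    ok: bool
    sccs: List[Dict[str, Tuple[int, int]]] = field(default_factory=list)


class AlignmentGraph:
    """A DAG of alignment vertices with per-genome ordered edges."""

    def __init__(self, genomes, vertices: List[AlignmentVertex], edges: List[Edge],
                 spans: Optional[Dict[int, Tuple[int, int]]] = None):
        self.genomes = genomes
        self.vertices = vertices
        self.edges = edges
        # per-genome region covered by this graph (whole genome if omitted)
        self.spans = spans or {
            gi: (1, genomes[gi].length) for gi in range(len(genomes.genomes))
        }
        self.anchor_ids: Optional[List[int]] = None
        self.gapless_anchor_pairs: List[Tuple[int, int]] = []

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def genome_path(self, genome_index: int) -> List[int]:
        """Vertex ids visited by a genome, in increasing position order."""
        ids = [i for i, v in enumerate(self.vertices) if genome_index in v.segments]
        ids.sort(key=lambda i: self.vertices[i].segments[genome_index][0])
        return ids

    def nx_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(range(len(self.vertices)))
        for e in self.edges:
            g.add_edge(e.source, e.target)
        return g

    def topological_ids(self) -> List[int]:
        """Canonical topological order (ties by smallest first-genome coordinate)."""
        return list(nx.lexicographical_topological_sort(
            self.nx_digraph(), key=lambda i: self.vertices[i].sort_key()))

    def check_conservation(self) -> None:
        """Vertex lengths plus skipped bp must tile each genome span exactly."""
        for gi, (lo, hi) in self.spans.items():
            path = self.genome_path(gi)
            covered = sum(self.vertices[i].length for i in path)
            skipped = sum(e.skipped_bp for e in self.edges if e.genome_index == gi)
            expect = hi - lo + 1
            if covered + skipped != expect:
                raise AssertionError(
                    f"conservation violated for genome {self.genomes[gi].id!r}: "
                    f"{covered} aligned + {skipped} skipped != {expect}")

    def to_json_dict(self) -> dict:
        verts = []
        for v in self.vertices:
            verts.append({
                "kind": v.kind,
                "length": v.length,
                "identity": [v.identity.numerator, v.identity.denominator],
                "identity_percent": v.identity_percent,
                "segments": {
                    self.genomes[g].id: [s, e]
                    for g, (s, e) in sorted(v.segments.items())
                },
            })
        edges = [{
            "genome": self.genomes[e.genome_index].id,
            "from": e.source,
            "to": e.target,
            "skipped_bp": e.skipped_bp,
        } for e in sorted(self.edges, key=lambda e: (e.genome_index, e.source, e.target))]
        out = {
            "genomes": [{"id": g.id, "length": g.length} for g in self.genomes],
            "vertices": verts,
            "edges": edges,
        }
        if self.anchor_ids is not None:
            out["anchors"] = list(self.anchor_ids)
            out["gapless_anchor_pairs"] = [list(p) for p in self.gapless_anchor_pairs]
        return out


def _assemble(genomes, vertices: List[AlignmentVertex],
              spans: Optional[Dict[int, Tuple[int, int]]] = None) -> AlignmentGraph:
    """Sort vertices canonically, rebuild per-genome edges, verify conservation."""
    vertices = sorted(vertices, key=AlignmentVertex.sort_key)
    graph = AlignmentGraph(genomes, vertices, [], spans=spans)
    edges: List[Edge] = []
    for gi in list(graph.spans):
        path = graph.genome_path(gi)
        for u, v in zip(path, path[1:]):
            gap = vertices[v].segments[gi][0] - vertices[u].segments[gi][1] - 1
            if gap < 0:
                raise AssertionError(
                    f"overlapping segments on genome {genomes[gi].id!r}")
            edges.append(Edge(gi, u, v, gap))
    graph.edges = edges
    graph.check_conservation()
    return graph


# ---------------------------------------------------------------------------
# column graph


def build_column_graph(partition: ColumnPartition, genomes=None) -> nx.MultiDiGraph:
    """Directed multigraph over columns, one edge per genome adjacency."""
    genomes = genomes if genomes is not None else partition.genomes
    graph = nx.MultiDiGraph(partition=partition, genomes=genomes)
    graph.add_nodes_from(range(partition.n_columns))
    col_of = partition.col_of
    starts = partition.starts
    for gi in range(len(genomes.genomes)):
        lo, hi = int(starts[gi]), int(starts[gi + 1])
        for p in range(lo, hi - 1):
            graph.add_edge(int(col_of[p]), int(col_of[p + 1]), genome=gi)
    return graph


def _adjacency_pairs(partition: ColumnPartition) -> np.ndarray:
    """Unique (from_column, to_column) pairs over all genome adjacencies."""
    col_of = partition.col_of
    starts = partition.starts
    chunks = []
    for gi in range(len(partition.genomes.genomes)):
        lo, hi = int(starts[gi]), int(starts[gi + 1])
        if hi - lo >= 2:
            chunks.append(np.stack([col_of[lo:hi - 1], col_of[lo + 1:hi]], axis=1))
    if not chunks:
        return np.empty((0, 2), dtype=np.int64)
    return np.unique(np.concatenate(chunks), axis=0)


def _scc_intervals(partition: ColumnPartition, component: Set[int]) -> Dict[str, Tuple[int, int]]:
    per_genome: Dict[str, Tuple[int, int]] = {}
    for cid in component:
        for p in partition.columns[cid]:
            pos = partition.to_local(int(p))
            gid = partition.genomes[pos.genome_index].id
            lo, hi = per_genome.get(gid, (pos.offset, pos.offset))
            per_genome[gid] = (min(lo, pos.offset), max(hi, pos.offset))
    return per_genome


def collinearity_from_partition(partition: ColumnPartition, genomes=None) -> CollinearityReport:
    """Acyclicity test on the column adjacencies, with SCC evidence if cyclic."""
    pairs = _adjacency_pairs(partition)
    graph = nx.DiGraph()
    graph.add_nodes_from(range(partition.n_columns))
    graph.add_edges_from(map(tuple, pairs))
    sccs = []
    for comp in nx.strongly_connected_components(graph):
        if len(comp) > 1 or graph.has_edge(next(iter(comp)), next(iter(comp))):
            sccs.append(comp)
    if not sccs:
        return CollinearityReport(True)
    intervals = [_scc_intervals(partition, comp) for comp in sccs]
    intervals.sort(key=lambda d: sorted(d.items()))
    return CollinearityReport(False, intervals)


def check_collinear(graph: nx.MultiDiGraph) -> CollinearityReport:
    """OK iff the column graph is acyclic; otherwise every nontrivial SCC.

    Non-collinearity is a result, not an error: the SCC intervals are
    user-facing rearrangement evidence.
    """
    return collinearity_from_partition(graph.graph["partition"], graph.graph["genomes"])


# ---------------------------------------------------------------------------
# merging and contraction


def merge_partition(partition: ColumnPartition, genomes=None) -> AlignmentGraph:
    """Merge maximal runs of consecutive same-support columns into vertices."""
    genomes = genomes if genomes is not None else partition.genomes
    col_of = partition.col_of
    starts = partition.starts
    ncols = partition.n_columns
    gidx_all = partition.genome_of(np.arange(partition.n_positions))
    gend = starts[gidx_all + 1]  # exclusive end of each position's genome

    nxt = np.full(ncols, -1, dtype=np.int64)
    for cid, members in enumerate(partition.columns):
        succ_pos = members + 1
        if np.any(succ_pos >= gend[members]):
            continue  # some position sits at its genome's end
        succ = col_of[succ_pos]
        first = int(succ[0])
        if np.all(succ == first) and partition.columns[first].size == members.size:
            nxt[cid] = first

    has_prev = np.zeros(ncols, dtype=bool)
    has_prev[nxt[nxt >= 0]] = True

    vertices: List[AlignmentVertex] = []
    for cid in range(ncols):
        if has_prev[cid]:
            continue
        run_len = 1
        last = cid
        while nxt[last] >= 0:
            last = int(nxt[last])
            run_len += 1
        first_members = partition.columns[cid]
        gidx = partition.genome_of(first_members)
        segments = {
            int(g): (int(p - starts[g] + 1), int(p - starts[g] + run_len))
            for g, p in zip(gidx, first_members)
        }
        kind = "exact" if len(segments) >= 2 else "singleton"
        vertices.append(AlignmentVertex(segments, run_len, Fraction(1), kind))
    return _assemble(genomes, vertices)


def merge_same_support(graph: nx.MultiDiGraph) -> AlignmentGraph:
    """The expanded alignment graph: column runs with identical support merged.

    Raises CyclicGraphError on non-collinear input.
    """
    report = check_collinear(graph)
    if not report.ok:
        raise CyclicGraphError(
            f"column graph is cyclic ({len(report.sccs)} strongly connected "
            "component(s)); the genome set is not functionally collinear",
            sccs=report.sccs)
    return merge_partition(graph.graph["partition"], graph.graph["genomes"])


def _segment_identity(genomes, segments: Dict[int, Tuple[int, int]]) -> Fraction:
    """Fraction of columns where every supported genome has the same base.

    `N` counts as disagreeing with everything, including itself.
    """
    rows = [
        np.frombuffer(genomes[g].seq[s - 1:e].encode(), dtype=np.uint8)
        for g, (s, e) in sorted(segments.items())
    ]
    stacked = np.stack(rows)
    agree = np.all(stacked == stacked[0], axis=0) & (stacked[0] != ord("N"))
    return Fraction(int(agree.sum()), int(stacked.shape[1]))


def contract(expanded: AlignmentGraph, max_length: Optional[int] = None) -> AlignmentGraph:
    """Merge chains of contractible vertex pairs into gapless vertices.

    A pair (U, V) is contractible when U precedes V, both have the same
    support, every vertex between them has support included in V's, and
    the per-genome segments spanning U..V all have the same length.  The
    scan is greedy over the canonical topological order, so the result
    is deterministic.  ``max_length`` optionally caps contracted vertex
    length (off by default).
    """
    genomes = expanded.genomes
    verts = expanded.vertices
    paths = {gi: expanded.genome_path(gi) for gi in expanded.spans}
    where: Dict[int, Dict[int, int]] = {
        gi: {vid: k for k, vid in enumerate(path)} for gi, path in paths.items()
    }

    def next_same_support(last: int, support: frozenset):
        """First later vertex with identical support, plus the vertices between.

        Returns None when no such vertex exists, when a between-vertex
        has support not included in ``support``, or when the walks of
        the supported genomes disagree."""
        candidate = None
        between: Set[int] = set()
        for gi in support:
            path = paths[gi]
            k = where[gi][last] + 1
            collected = []
            found = None
            while k < len(path):
                vid = path[k]
                if verts[vid].support == support:
                    found = vid
                    break
                if not verts[vid].support <= support:
                    return None
                collected.append(vid)
                k += 1
            if found is None:
                return None
            if candidate is None:
                candidate = found
            elif candidate != found:
                return None
            between.update(collected)
        return candidate, between

    consumed = [False] * len(verts)
    result: List[AlignmentVertex] = []
    for u in expanded.topological_ids():
        if consumed[u]:
            continue
        consumed[u] = True
        support = verts[u].support
        chain = [u]
        absorbed: Set[int] = set()
        last = u
        while True:
            step = next_same_support(last, support)
            if step is None:
                break
            v, between = step
            if consumed[v] or any(consumed[x] for x in between):
                break
            spans = {
                gi: verts[v].segments[gi][1] - verts[last].segments[gi][0] + 1
                for gi in support
            }
            if len(set(spans.values())) != 1:
                break
            total = verts[v].segments[min(support)][1] - \
                verts[chain[0]].segments[min(support)][0] + 1
            if max_length is not None and total > max_length:
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
        segments = {
            gi: (verts[chain[0]].segments[gi][0], verts[last].segments[gi][1])
            for gi in support
        }
        length = segments[min(support)][1] - segments[min(support)][0] + 1
        parts = sorted((verts[i] for i in chain + sorted(absorbed)),
                       key=AlignmentVertex.sort_key)
        result.append(AlignmentVertex(
            segments, length, _segment_identity(genomes, segments),
            "contracted", parts=parts))
    return _assemble(genomes, result, spans=dict(expanded.spans))


# ---------------------------------------------------------------------------
# anchors, zooming, statistics


def compute_anchors(graph: AlignmentGraph, genomes=None) -> List[int]:
    """Vertices supported by every genome, in backbone order.

    Also records on the graph the consecutive anchor pairs that bound a
    gapless alignment (equal span length in every genome) — the boxed
    pairs of the anchor view.
    """
    genomes = genomes if genomes is not None else graph.genomes
    full = frozenset(range(len(genomes.genomes)))
    anchors = [i for i, v in enumerate(graph.vertices) if v.support == full]
    anchors.sort(key=lambda i: graph.vertices[i].segments[min(full)][0] if full else 0)
    pairs = []
    for a, b in zip(anchors, anchors[1:]):
        va, vb = graph.vertices[a], graph.vertices[b]
        spans = {vb.segments[gi][1] - va.segments[gi][0] + 1 for gi in full}
        if len(spans) == 1:
            pairs.append((a, b))
    graph.anchor_ids = anchors
    graph.gapless_anchor_pairs = pairs
    return anchors


def realign_between(graph: AlignmentGraph, anchor_a: int, anchor_b: int,
                    m_override: Optional[int] = None) -> AlignmentGraph:
    """Align the sub-sequences strictly between two anchors on their own.

    The interior of every genome is extracted, the full pipeline is run
    on it (with ``m_override`` if given, else the minimal acyclic m
    starting from 15), and the result is reported in original genome
    coordinates.  Genomes with an empty interior do not take part.
    """
    from .genome_io import Genome, GenomeSet
    from . import column_builder, match_engine

    genomes = graph.genomes
    full = frozenset(range(len(genomes.genomes)))
    va, vb = graph.vertices[anchor_a], graph.vertices[anchor_b]
    if va.support != full or vb.support != full:
        raise AnchorOrderError("both endpoints of a zoom must be anchors")
    for gi in full:
        if va.segments[gi][1] >= vb.segments[gi][0]:
            raise AnchorOrderError(
                f"anchors are not ordered on genome {genomes[gi].id!r}")

    interiors = {}
    for gi in sorted(full):
        lo = va.segments[gi][1] + 1
        hi = vb.segments[gi][0] - 1
        if lo <= hi:
            interiors[gi] = (lo, hi)
    spans = dict(interiors)
    if not interiors:
        return AlignmentGraph(genomes, [], [], spans={})
    if len(interiors) == 1:
        (gi, (lo, hi)), = interiors.items()
        vertex = AlignmentVertex({gi: (lo, hi)}, hi - lo + 1, Fraction(1), "singleton")
        return _assemble(genomes, [vertex], spans=spans)

    sub_list = [
        Genome(genomes[gi].id, genomes[gi].seq[lo - 1:hi])
        for gi, (lo, hi) in interiors.items()
    ]
    sub = GenomeSet(sub_list)
    sub_to_orig = {k: gi for k, gi in enumerate(interiors)}
    if m_override is not None:
        matches = match_engine.find_mems(sub, m_override)
    else:
        _m, matches = match_engine.auto_m(sub, 15)
    partition = column_builder.split_invalid(column_builder.build_columns(sub, matches))
    report = collinearity_from_partition(partition, sub)
    if not report.ok:
        raise CyclicGraphError(
            "sub-region between anchors is not collinear at the requested m",
            sccs=report.sccs)
    contracted = contract(merge_partition(partition, sub))

    translated = []
    for v in contracted.vertices:
        segments = {}
        for sk, (s, e) in v.segments.items():
            gi = sub_to_orig[sk]
            off = interiors[gi][0] - 1
            segments[gi] = (s + off, e + off)
        translated.append(AlignmentVertex(segments, v.length, v.identity, v.kind))
    return _assemble(genomes, translated, spans=spans)


@dataclass(frozen=True)
class GraphStats:
    """Vertex counts before/after contraction, >=2-genome and contracted."""

    vertices_before: int
    vertices_after: int
    vertices_ge2: int
    contracted_count: int


def graph_stats(expanded: AlignmentGraph, contracted: AlignmentGraph) -> GraphStats:
    return GraphStats(
        vertices_before=expanded.n_vertices,
        vertices_after=contracted.n_vertices,
        vertices_ge2=sum(1 for v in contracted.vertices if len(v.segments) >= 2),
        contracted_count=sum(1 for v in contracted.vertices if v.kind == "contracted"),
    )
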