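"""Column graph, collinearity, merging, contraction, anchors and zooming."""

from fractions import Fraction

import networkx as nx
import pytest

from phagealign import (
    alignment_graph,
    column_builder,
    match_engine,
    pipeline,
    synthetic,
)
from phagealign.alignment_graph import (
    build_column_graph,
    check_collinear,
    compute_anchors,
    contract,
    graph_stats,
    merge_same_support,
    realign_between,
)
from phagealign.column_builder import build_columns, split_invalid
from phagealign.errors import AnchorOrderError, CyclicGraphError
from phagealign.match_engine import Match, MatchSet

import naive_reference as ref
from conftest import distinct_flanks, genome_set, random_seq, transposition_pair


def columns_of(gs, matches):
    return split_invalid(build_columns(gs, matches))


def expanded_of(gs, m):
    part = columns_of(gs, match_engine.find_mems(gs, m))
    return alignment_graph.merge_partition(part, gs)


class TestColumnGraph:
    def test_single_genome_is_a_path(self):
        gs = genome_set("ACGT")
        graph = build_column_graph(columns_of(gs, MatchSet([], 1)), gs)
        assert graph.number_of_nodes() == 4
        assert sorted(graph.edges()) == [(0, 1), (1, 2), (2, 3)]

    def test_one_edge_per_genome_adjacency(self):
        seq = "ACGTA"
        gs = genome_set(seq, seq)
        ms = MatchSet([Match("g0", 1, "g1", 1, 5)], 5)
        graph = build_column_graph(columns_of(gs, ms), gs)
        # 5 shared columns; both genomes contribute an edge between each pair
        assert graph.number_of_nodes() == 5
        assert graph.number_of_edges() == 8
        genomes_on = {(u, v): sorted(d["genome"] for d in graph[u][v].values())
                      for u, v in set(graph.edges())}
        assert all(val == [0, 1] for val in genomes_on.values())

    def test_transposition_creates_cycle(self, rng):
        gs = transposition_pair(rng, block_len=20)
        graph = build_column_graph(
            columns_of(gs, match_engine.find_mems(gs, 15)), gs)
        report = check_collinear(graph)
        assert not report.ok
        assert len(report.sccs) == 1
        assert not nx.is_directed_acyclic_graph(nx.DiGraph(graph.edges()))

    def test_scc_report_matches_handrolled_kosaraju(self, rng):
        gs = transposition_pair(rng, block_len=20)
        part = columns_of(gs, match_engine.find_mems(gs, 15))
        report = alignment_graph.collinearity_from_partition(part, gs)
        cols = ref.canon_partition(part)
        assert not report.ok
        assert ref.naive_is_cyclic(cols, gs)

    def test_collinear_random_pairs_pass(self):
        import numpy as np
        for seed in range(20):
            r = np.random.default_rng(seed)
            gs = genome_set(random_seq(r, 1000), random_seq(r, 1000))
            part = columns_of(gs, match_engine.find_mems(gs, 15))
            assert alignment_graph.collinearity_from_partition(part, gs).ok


class TestMerge:
    def test_three_shared_columns_make_one_exact_vertex(self):
        # one 3 bp match flanked by unrelated sequence: the classic
        # five-vertex shape (2 flank vertices per genome + 1 shared)
        gs = genome_set("TTACGTT", "GGACGGG")
        ms = MatchSet([Match("g0", 3, "g1", 3, 3)], 3)
        graph = merge_same_support(build_column_graph(columns_of(gs, ms), gs))
        assert graph.n_vertices == 5
        shared = [v for v in graph.vertices if len(v.segments) == 2]
        assert len(shared) == 1
        assert shared[0].length == 3 and shared[0].kind == "exact"
        assert shared[0].segments == {0: (3, 5), 1: (3, 5)}

    def test_alternating_support_merges_nothing(self):
        # matches only at positions 1 and 3: supports alternate, so the
        # vertex count equals the column count
        gs = genome_set("ACA", "AGA")
        ms = MatchSet([Match("g0", 1, "g1", 1, 1), Match("g0", 3, "g1", 3, 1)], 1)
        part = columns_of(gs, ms)
        graph = merge_same_support(build_column_graph(part, gs))
        assert graph.n_vertices == part.n_columns == 4

    def test_cyclic_input_raises(self, rng):
        gs = transposition_pair(rng, block_len=20)
        graph = build_column_graph(
            columns_of(gs, match_engine.find_mems(gs, 15)), gs)
        with pytest.raises(CyclicGraphError):
            merge_same_support(graph)

    def test_matches_naive_merge(self):
        spec = synthetic.MosaicSpec(n_genomes=3, n_modules=3, seed=17,
                                    module_length_range=(60, 150),
                                    universal_block_lengths=(50,))
        gs, _ = synthetic.generate(spec)
        part = columns_of(gs, match_engine.find_mems(gs, 12))
        got = {tuple(sorted(v.segments.items()))
               for v in alignment_graph.merge_partition(part, gs).vertices}
        want = {tuple(sorted(v.items()))
                for v in ref.naive_merge(ref.canon_partition(part), gs)}
        assert got == want


class TestContract:
    def _flanked(self, rng, mids, shared_len=25):
        """Genomes U + mid_i + V with per-genome mids and guarded junctions."""
        n = len(mids)
        u = random_seq(rng, shared_len)
        v = random_seq(rng, shared_len)
        lefts, rights = distinct_flanks(rng, n)
        seqs = [lefts[i] + u + mids[i] + v + rights[i] for i in range(n)]
        return genome_set(*seqs), u, v, lefts

    def test_same_length_interior_contracts_with_identity(self, rng):
        mid0 = random_seq(rng, 10)
        mid1 = "".join("ACGT"[("ACGT".index(c) + 1) % 4] if i in (2, 7) else c
                       for i, c in enumerate(mid0))
        gs, u, v, lefts = self._flanked(rng, [mid0, mid1])
        res = pipeline.align(gs, m=15)
        assert res.ok
        contracted = [x for x in res.contracted.vertices if x.kind == "contracted"]
        assert len(contracted) == 1
        vert = contracted[0]
        assert vert.length == 25 + 10 + 25
        # brute-force column count: U and V agree fully, the middle at 8/10
        matching_mid = sum(a == b for a, b in zip(mid0, mid1))
        assert vert.identity == Fraction(25 + 25 + matching_mid, 60)
        # expansion bookkeeping: parts tile the contracted span exactly
        for gi, (s, e) in vert.segments.items():
            covered = sorted(p.segments[gi] for p in vert.parts
                             if gi in p.segments)
            assert covered[0][0] == s and covered[-1][1] == e
            assert all(b2 == e1 + 1 for (_a1, e1), (b2, _e2)
                       in zip(covered, covered[1:]))

    def test_unequal_span_blocks_contraction(self, rng):
        gs, _u, _v, _ = self._flanked(rng, [random_seq(rng, 10),
                                            random_seq(rng, 13)])
        res = pipeline.align(gs, m=15)
        assert res.ok
        assert all(v.kind != "contracted" for v in res.contracted.vertices)

    def test_foreign_support_between_blocks_contraction(self, rng):
        # q is shared by a third genome: the in-between vertex's support
        # is not included in sp(V), so U..V must not contract
        u, v = random_seq(rng, 25), random_seq(rng, 25)
        q = random_seq(rng, 16)
        a1, a2 = random_seq(rng, 8), random_seq(rng, 8)
        b1, b2 = random_seq(rng, 8), random_seq(rng, 8)
        lefts, rights = distinct_flanks(rng, 3)
        g0 = lefts[0] + u + a1 + q + b1 + v + rights[0]
        g1 = lefts[1] + u + a2 + q + b2 + v + rights[1]
        g2 = lefts[2] + q + rights[2]
        gs = genome_set(g0, g1, g2)
        res = pipeline.align(gs, m=15)
        assert res.ok
        assert all(x.kind != "contracted" for x in res.contracted.vertices)
        # control: without the third genome the same chain contracts
        gs2 = genome_set(g0, g1)
        res2 = pipeline.align(gs2, m=15)
        contracted = [x for x in res2.contracted.vertices if x.kind == "contracted"]
        assert len(contracted) == 1
        assert contracted[0].length == len(u) + 8 + len(q) + 8 + len(v)

    def test_matches_naive_contraction(self):
        spec = synthetic.MosaicSpec(n_genomes=3, n_modules=3, seed=23,
                                    module_length_range=(60, 150),
                                    linker_length_range=(5, 20),
                                    universal_block_lengths=(50,),
                                    substitution_rate=0.02)
        gs, _ = synthetic.generate(spec)
        res = pipeline.align(gs, m=12)
        assert res.ok
        assert ref.canon_graph(res.contracted) == ref.naive_contract(
            [dict(v.segments) for v in res.expanded.vertices], gs)

    def test_identity_never_below_exact_core(self):
        spec = synthetic.MosaicSpec(seed=6)
        gs, _ = synthetic.generate(spec)
        res = pipeline.align(gs, m=15, auto=True)
        assert res.ok
        for v in res.contracted.vertices:
            if v.kind != "contracted":
                continue
            exact_core = sum(p.length for p in v.parts
                             if p.kind == "exact" and p.support == v.support)
            assert v.identity >= Fraction(exact_core, v.length)


class TestAnchorsAndZoom:
    def test_identical_genomes_single_anchor(self, rng):
        seq = random_seq(rng, 300)
        gs = genome_set(seq, seq, seq)
        res = pipeline.align(gs, m=15)
        anchors = compute_anchors(res.contracted)
        assert len(anchors) == 1
        assert res.contracted.vertices[anchors[0]].length == 300

    def test_planted_universal_blocks_are_the_anchors(self):
        # force both variants of every module to be used so nothing else
        # is universal
        choices = [[0, 1, 0, 1], [1, 0, 1, 0], [0, 1, 1, 0], [1, 0, 0, 1]]
        spec = synthetic.MosaicSpec(n_genomes=4, n_modules=4,
                                    variants_per_module=2, seed=31,
                                    module_length_range=(150, 300),
                                    universal_block_lengths=(200, 200, 200),
                                    substitution_rate=0.0, indel_rate=0.0,
                                    variant_choices=choices)
        gs, truth = synthetic.generate(spec)
        res = pipeline.align(gs, m=15)
        anchors = compute_anchors(res.expanded)
        assert len(anchors) == 3
        for ordinal, per_genome in enumerate(truth.anchors):
            v = res.expanded.vertices[anchors[ordinal]]
            for gid, (s, e) in per_genome.items():
                vs, ve = v.segments[gs.index(gid)]
                assert vs <= s and e <= ve

    def test_anchors_are_articulation_points(self):
        spec = synthetic.MosaicSpec(seed=12)
        gs, _ = synthetic.generate(spec)
        res = pipeline.align(gs, m=15, auto=True)
        anchors = compute_anchors(res.contracted)
        assert len(anchors) >= 2
        und = res.contracted.nx_digraph().to_undirected()
        for a in anchors:
            if und.degree(a) == 0:
                continue
            cut = und.copy()
            cut.remove_node(a)
            if cut.number_of_nodes() > 1:
                assert not nx.is_connected(cut)

    def test_gapless_anchor_pair_flagged(self, rng):
        u, v = random_seq(rng, 40), random_seq(rng, 40)
        mid0, mid1 = random_seq(rng, 12), random_seq(rng, 12)
        lefts, rights = distinct_flanks(rng, 2)
        gs = genome_set(lefts[0] + u + mid0 + v + rights[0],
                        lefts[1] + u + mid1 + v + rights[1])
        expanded = expanded_of(gs, 15)
        anchors = compute_anchors(expanded)
        assert len(anchors) == 2
        assert expanded.gapless_anchor_pairs == [(anchors[0], anchors[1])]

    def test_zoom_reveals_small_shared_block(self, rng):
        u, v = random_seq(rng, 40), random_seq(rng, 40)
        block = random_seq(rng, 15)
        lefts, rights = distinct_flanks(rng, 3)
        seqs = []
        for i in range(3):
            # unequal interior lengths keep the two anchors uncontracted
            interior = random_seq(rng, 30 + 10 * i) + block + random_seq(rng, 30)
            seqs.append(lefts[i] + u + interior + v + rights[i])
        gs = genome_set(*seqs)
        res = pipeline.align(gs, m=25)
        anchors = compute_anchors(res.contracted)
        assert len(anchors) == 2
        # at the global m the interior is unaligned
        interior_aligned = [x for x in res.contracted.vertices
                            if len(x.segments) >= 2 and x.length >= 15
                            and x.kind == "exact"]
        assert {x.length for x in interior_aligned} == {40}
        sub = realign_between(res.contracted, anchors[0], anchors[1],
                              m_override=15)
        hits = [x for x in sub.vertices
                if len(x.segments) == 3 and x.length >= 15]
        assert len(hits) == 1
        # reported in original coordinates: the block really is there
        for gi, (s, e) in hits[0].segments.items():
            assert block in gs[gi].seq[s - 1:e]

    def test_zoom_with_empty_interior(self):
        # adjacent anchors with nothing between them can only exist in a
        # hand-built graph (the merge step would fuse them otherwise)
        gs = genome_set("ACGT", "ACGT")
        u = alignment_graph.AlignmentVertex(
            {0: (1, 2), 1: (1, 2)}, 2, Fraction(1), "exact")
        v = alignment_graph.AlignmentVertex(
            {0: (3, 4), 1: (3, 4)}, 2, Fraction(1), "exact")
        graph = alignment_graph._assemble(gs, [u, v])
        sub = realign_between(graph, 0, 1)
        assert sub.n_vertices == 0

    def test_zoom_with_one_sided_interior(self, rng):
        u, v = random_seq(rng, 40), random_seq(rng, 40)
        lefts, rights = distinct_flanks(rng, 2)
        # the 1 bp insertion must not extend either flanking match
        mid = next(c for c in "ACGT" if c not in {v[0], u[-1]})
        gs = genome_set(lefts[0] + u + v + rights[0],
                        lefts[1] + u + mid + v + rights[1])
        expanded = expanded_of(gs, 20)
        anchors = compute_anchors(expanded)
        assert len(anchors) == 2
        sub = realign_between(expanded, anchors[0], anchors[1])
        assert sub.n_vertices == 1
        (only,) = sub.vertices
        assert only.kind == "singleton" and only.length == 1

    def test_zoom_rejects_unordered_anchors(self, rng):
        spec = synthetic.MosaicSpec(seed=14)
        gs, _ = synthetic.generate(spec)
        res = pipeline.align(gs, m=15, auto=True)
        anchors = compute_anchors(res.contracted)
        assert len(anchors) >= 2
        with pytest.raises(AnchorOrderError):
            realign_between(res.contracted, anchors[1], anchors[0])


class TestPipelineProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    dna = st.text(alphabet="ACGTN", min_size=20, max_size=120)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.lists(dna, min_size=2, max_size=4),
           st.text(alphabet="ACGT", min_size=8, max_size=20))
    def test_invariants_on_arbitrary_genomes(self, seqs, shared):
        """Conservation, column homogeneity and identity bounds hold for
        arbitrary genome sets (a shared block guarantees some matches)."""
        gs = genome_set(*[s + shared + s[::-1] for s in seqs])
        part = columns_of(gs, match_engine.find_mems(gs, 8))
        assert sum(len(c) for c in part.columns) == gs.total_length
        for cid in part.iter_multi_columns():
            chars = {gs[p.genome_index].seq[p.offset - 1]
                     for p in part.column(cid).positions}
            assert len(chars) == 1 and chars != {"N"}
        report = alignment_graph.collinearity_from_partition(part, gs)
        if not report.ok:
            return  # palindromic flanks can legitimately cross
        expanded = alignment_graph.merge_partition(part, gs)
        contracted = contract(expanded)
        for graph in (expanded, contracted):
            graph.check_conservation()
        for v in contracted.vertices:
            assert 0 <= v.identity <= 1
            if v.kind == "exact":
                rows = {gs[gi].seq[s - 1:e] for gi, (s, e) in v.segments.items()}
                assert len(rows) == 1


class TestConservationAndStats:
    def test_per_genome_bp_conservation(self):
        for seed in range(5):
            spec = synthetic.MosaicSpec(seed=seed)
            gs, _ = synthetic.generate(spec)
            res = pipeline.align(gs, m=15, auto=True)
            assert res.ok
            for graph in (res.expanded, res.contracted):
                graph.check_conservation()  # raises on violation
                for gi, g in enumerate(gs.genomes):
                    path = graph.genome_path(gi)
                    covered = sum(graph.vertices[i].length for i in path)
                    skipped = sum(e.skipped_bp for e in graph.edges
                                  if e.genome_index == gi)
                    assert covered + skipped == g.length

    def test_topological_order_exists(self):
        spec = synthetic.MosaicSpec(seed=19)
        gs, _ = synthetic.generate(spec)
        res = pipeline.align(gs, m=15, auto=True)
        order = res.contracted.topological_ids()
        position = {vid: k for k, vid in enumerate(order)}
        assert all(position[e.source] < position[e.target]
                   for e in res.contracted.edges)

    def test_stats_single_genome_trivia(self):
        gs = genome_set("ACGTACGTAC")
        part = columns_of(gs, MatchSet([], 1))
        expanded = alignment_graph.merge_partition(part, gs)
        contracted = contract(expanded)
        stats = graph_stats(expanded, contracted)
        assert stats.vertices_ge2 == 0 and stats.contracted_count == 0
        assert stats.vertices_before == stats.vertices_after == 1

    def test_stats_on_planted_instance(self):
        spec = synthetic.MosaicSpec(seed=1)
        gs, _ = synthetic.generate(spec)
        res = pipeline.align(gs, m=15)
        s = res.stats
        assert s.vertices_before > s.vertices_after
        assert s.vertices_ge2 >= 3  # at least the planted anchors
        assert s.contracted_count == sum(
            1 for v in res.contracted.vertices if v.kind == "contracted")
        assert s.vertices_ge2 == sum(
            1 for v in res.contracted.vertices if len(v.segments) >= 2)
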