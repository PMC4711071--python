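"""End-to-end convenience pipeline: genomes -> contracted alignment graph."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from . import alignment_graph, column_builder, match_engine
from .alignment_graph import AlignmentGraph, CollinearityReport, GraphStats


@dataclass
class PipelineResult:
    """Everything the pipeline computed for one genome set.

    When the input is not collinear at the requested m (and auto-m was
    not asked for), ``report.ok`` is False and the graphs are None.
    """

    genomes: object
    m: int
    matches: match_engine.MatchSet
    partition: column_builder.ColumnPartition
    report: CollinearityReport
    expanded: Optional[AlignmentGraph] = None
    contracted: Optional[AlignmentGraph] = None
    stats: Optional[GraphStats] = None

    @property
    def ok(self) -> bool:
        return self.report.ok


def align(genomes, m: int = 15, auto: bool = False, ceiling: int = 500,
          matches: Optional[match_engine.MatchSet] = None) -> PipelineResult:
    """Run matches -> columns -> split -> collinearity -> merge -> contract.

    With ``auto`` the smallest acyclic m >= ``m`` is searched first.  A
    pre-computed MatchSet (e.g. from an external MEM finder) can be
    passed to bypass the internal one.
    """
    if matches is None:
        if auto:
            m, matches = match_engine.auto_m(genomes, m_start=m, ceiling=ceiling)
        else:
            matches = match_engine.find_mems(genomes, m)
    partition = column_builder.split_invalid(
        column_builder.build_columns(genomes, matches))
    report = alignment_graph.collinearity_from_partition(partition, genomes)
    result = PipelineResult(genomes, m, matches, partition, report)
    if not report.ok:
        return result
    result.expanded = alignment_graph.merge_partition(partition, genomes)
    result.contracted = alignment_graph.contract(result.expanded)
    result.stats = alignment_graph.graph_stats(result.expanded, result.contracted)
    alignment_graph.compute_anchors(result.expanded)
    alignment_graph.compute_anchors(result.contracted)
    return result
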