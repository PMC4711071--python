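"""Graphviz-DOT rendering of alignment graphs and anchor views.

Vertices are drawn as boxes listing the per-genome coordinates of the
aligned segments, the alignment length and the truncated identity
percentage; edges are one color per genome.  Vertices shorter than a
readability threshold (20 bp by default) are masked, and any edge whose
path hides at least one base pair — masked vertices or skipped bases —
is drawn dotted with the hidden count as its label, so no base pair is
silently lost from the display.

Output is deterministic: identical input yields byte-identical DOT.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

from .alignment_graph import AlignmentGraph, compute_anchors

# Graphviz X11 color names, one per genome, cycled if more genomes than colors.
_PALETTE = [
    "red", "blue", "forestgreen", "darkorange", "purple", "deepskyblue",
    "magenta", "saddlebrown", "gold3", "turquoise4", "olivedrab", "navy",
    "crimson", "darkcyan", "chocolate", "slateblue",
]


@dataclass
class RenderOptions:
    """Display knobs mirroring the interactive tool's semantics."""

    mask_threshold: int = 20
    color_map: Optional[Dict[str, str]] = None
    show_positions: bool = True
    anchor_view: bool = False

    def __post_init__(self):
        if self.mask_threshold < 0:
            raise ValueError("mask_threshold must be >= 0")
        if self.color_map is not None:
            colors = list(self.color_map.values())
            if len(set(colors)) != len(colors):
                raise ValueError("colors must be unique per genome")


def _colors(graph: AlignmentGraph, opts: RenderOptions) -> Dict[int, str]:
    colors = {gi: _PALETTE[gi % len(_PALETTE)]
              for gi in range(len(graph.genomes.genomes))}
    if opts.color_map:
        for gi, g in enumerate(graph.genomes):
            if g.id in opts.color_map:
                colors[gi] = opts.color_map[g.id]
    return colors


def _label(graph: AlignmentGraph, vid: int, opts: RenderOptions) -> str:
    v = graph.vertices[vid]
    lines = []
    if opts.show_positions:
        for gi, (s, e) in sorted(v.segments.items()):
            lines.append(f"{graph.genomes[gi].id}:{s}-{e}")
    lines.append(f"len={v.length} id={v.identity_percent}%")
    return "\\n".join(lines)


def to_dot(graph: AlignmentGraph, opts: Optional[RenderOptions] = None) -> str:
    """Render an alignment graph as DOT text.

    One node per unmasked vertex; per-genome colored edges between
    consecutive unmasked vertices on each genome path.  An edge hiding
    >= 1 bp (masked vertices in between, or skipped bases) is dotted and
    labeled with the hidden count.
    """
    opts = opts or RenderOptions()
    colors = _colors(graph, opts)
    visible = [i for i, v in enumerate(graph.vertices)
               if v.length >= opts.mask_threshold]
    vset = set(visible)
    out: List[str] = []
    out.append("digraph alignment {")
    out.append("  rankdir=LR;")
    out.append('  node [shape=box, fontname="Helvetica"];')
    for vid in visible:
        out.append(f'  v{vid} [label="{_label(graph, vid, opts)}"];')
    skipped = {(e.genome_index, e.source, e.target): e.skipped_bp for e in graph.edges}
    for gi in sorted(graph.spans):
        path = graph.genome_path(gi)
        color = colors[gi]
        prev = None
        hidden = 0
        for vid in path:
            if vid not in vset:
                hidden += graph.vertices[vid].length
                continue
            if prev is not None:
                # account skipped bp of every hop between prev and vid
                hop_prev = prev
                gap = 0
                for hop in path[path.index(prev) + 1:path.index(vid) + 1]:
                    gap += skipped.get((gi, hop_prev, hop), 0)
                    hop_prev = hop
                total_hidden = hidden + gap
                attrs = [f'color="{color}"']
                if total_hidden > 0:
                    attrs.append("style=dotted")
                    attrs.append(f'label="{total_hidden} bp"')
                out.append(f"  v{prev} -> v{vid} [{', '.join(attrs)}];")
            prev = vid
            hidden = 0
    out.append("}")
    return "\n".join(out) + "\n"


def anchor_view_dot(graph: AlignmentGraph, genomes=None,
                    opts: Optional[RenderOptions] = None) -> str:
    """Linear backbone of anchors; boxed clusters group gapless anchor runs."""
    opts = opts or RenderOptions(anchor_view=True)
    if graph.anchor_ids is None:
        compute_anchors(graph, genomes)
    anchors = graph.anchor_ids or []
    gapless = set(graph.gapless_anchor_pairs)
    out: List[str] = []
    out.append("digraph anchors {")
    out.append("  rankdir=LR;")
    out.append('  node [shape=box, fontname="Helvetica"];')
    # maximal runs of consecutive anchors linked by gapless pairs share a box
    runs: List[List[int]] = []
    for a in anchors:
        if runs and (runs[-1][-1], a) in gapless:
            runs[-1].append(a)
        else:
            runs.append([a])
    cluster = 0
    for run in runs:
        if len(run) >= 2:
            out.append(f"  subgraph cluster_{cluster} {{")
            out.append('    style=solid; color=black; label="gapless";')
            for vid in run:
                out.append(f'    v{vid} [label="{_label(graph, vid, opts)}"];')
            out.append("  }")
            cluster += 1
        else:
            vid = run[0]
            out.append(f'  v{vid} [label="{_label(graph, vid, opts)}"];')
    for a, b in zip(anchors, anchors[1:]):
        out.append(f"  v{a} -> v{b};")
    out.append("}")
    return "\n".join(out) + "\n"
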