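"""Synthetic mosaic genome sets with ground truth.

Tailed-phage genomes evolve as an ordered sequence of functional
modules, each existing in several *variants* that do the same job with
possibly unrelated sequences; horizontal exchange shuffles which
genome carries which variant, while substitutions and small indels
accumulate on top.  The generator emulates exactly that: every module
has a pool of independently drawn variant sequences, each genome picks
one variant per module (picks independent across modules, so variant
groupings can switch from column to column), universal blocks planted
identically in every genome act as ground-truth anchors, and optional
transpositions and duplications exercise cycle detection and invalid-
column splitting.  Everything is deterministic given the seed.

Planted universal, transposed and duplicated blocks are never mutated,
so their ground-truth intervals stay exact.  The bases flanking
transposed/duplicated blocks are forced to differ between the
rearranged genome and the rest, so planted matches have exactly the
planted length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import InfeasibleSpecError
from .genome_io import Genome, GenomeSet

_BASES = "ACGT"
_MAX_TOTAL = 200_000_000  # bp across the whole set


@dataclass
class MosaicSpec:
    """Parameters of one synthetic mosaic genome set.

    Defaults are the study conditions used throughout the test-suite:
    6 genomes, 8 modules with 2 variants each of 300-800 bp, short
    unalignable linkers, 1 % substitutions, 0.1 % indels, and three
    300 bp universal blocks planted as anchors.
    """

    n_genomes: int = 6
    n_modules: int = 8
    variants_per_module: int = 2
    module_length_range: Tuple[int, int] = (300, 800)
    linker_length_range: Tuple[int, int] = (20, 100)
    substitution_rate: float = 0.01
    indel_rate: float = 0.001
    universal_block_lengths: Sequence[int] = (300, 300, 300)
    transpositions: Sequence[Tuple[int, int]] = ()  # (genome_index, block_length)
    duplication: Optional[Tuple[int, int, int]] = None  # (genome, seg_len, copies)
    seed: int = 0
    # explicit variant assignment [genome][module]; random when None
    variant_choices: Optional[Sequence[Sequence[int]]] = None

    def validate(self) -> None:
        if self.n_genomes < 1 or self.n_modules < 1:
            raise InfeasibleSpecError("need at least one genome and one module")
        if self.variants_per_module < 1:
            raise InfeasibleSpecError("variants_per_module must be >= 1")
        for rate in (self.substitution_rate, self.indel_rate):
            if not 0 <= rate < 1:
                raise InfeasibleSpecError("rates must be in [0, 1)")
        if self.module_length_range[0] < 1 or \
                self.module_length_range[0] > self.module_length_range[1]:
            raise InfeasibleSpecError("bad module_length_range")
        if self.linker_length_range[0] < 0 or \
                self.linker_length_range[0] > self.linker_length_range[1]:
            raise InfeasibleSpecError("bad linker_length_range")
        if any(b < 1 for b in self.universal_block_lengths):
            raise InfeasibleSpecError("universal block lengths must be >= 1")
        for g, k in self.transpositions:
            if not (0 <= g < self.n_genomes) or k < 1:
                raise InfeasibleSpecError(f"bad transposition ({g}, {k})")
        if self.duplication is not None:
            g, seg, copies = self.duplication
            if not (0 <= g < self.n_genomes) or seg < 1 or copies < 1:
                raise InfeasibleSpecError(f"bad duplication {self.duplication}")
        if self.variant_choices is not None:
            if len(self.variant_choices) != self.n_genomes or any(
                    len(row) != self.n_modules for row in self.variant_choices):
                raise InfeasibleSpecError("variant_choices must be n_genomes x n_modules")
        upper = self.n_genomes * (
            self.n_modules * (self.module_length_range[1] + self.linker_length_range[1])
            + sum(self.universal_block_lengths)
            + sum(3 * (k + self.linker_length_range[1]) for _g, k in self.transpositions)
            + (self.duplication[1] * (self.duplication[2] + 1)
               + 3 * self.linker_length_range[1] if self.duplication else 0)
            + 2 * self.linker_length_range[1])
        if upper > _MAX_TOTAL:
            raise InfeasibleSpecError(f"spec would generate ~{upper} bp (> {_MAX_TOTAL})")


@dataclass
class GroundTruth:
    """What was planted where.

    ``labels``: per genome id, the (start, end, label) tiling in 1-based
    inclusive coordinates; labels look like ``module3:variant1``,
    ``linker``, ``universal0``, ``transposed0``, ``dup0``.
    ``anchors``: per planted universal block, the per-genome interval.
    ``rearrangements``: per planted transposition, the per-genome
    interval covering both swapped blocks.
    """

    labels: Dict[str, List[Tuple[int, int, str]]]
    anchors: List[Dict[str, Tuple[int, int]]]
    rearrangements: List[Dict[str, Tuple[int, int]]]

    def label_at(self, genome_id: str, position: int) -> str:
        for start, end, label in self.labels[genome_id]:
            if start <= position <= end:
                return label
        raise KeyError(f"position {position} not tiled in genome {genome_id!r}")


def _rand_seq(rng: np.random.Generator, length: int) -> str:
    if length == 0:
        return ""
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def _mutate(rng: np.random.Generator, seq: str, sub_rate: float,
            indel_rate: float) -> str:
    chars = list(seq)
    if sub_rate > 0 and chars:
        mask = rng.random(len(chars)) < sub_rate
        for i in np.flatnonzero(mask):
            choices = [b for b in _BASES if b != chars[i]]
            chars[i] = choices[int(rng.integers(0, 3))]
    if indel_rate > 0 and chars:
        n_events = int(rng.binomial(len(chars), indel_rate))
        positions = sorted(rng.integers(0, len(chars), size=n_events), reverse=True)
        for pos in positions:
            length = int(rng.integers(1, 6))
            if rng.random() < 0.5:
                del chars[pos:pos + length]
            else:
                chars[pos:pos] = list(_rand_seq(rng, length))
    return "".join(chars)


def _force_flank(piece: str, boundary_char: str, at_end: bool) -> str:
    """Overwrite the first/last base of a linker so block junctions differ."""
    if not piece:
        return piece
    if at_end:
        return piece[:-1] + boundary_char
    return boundary_char + piece[1:]


def generate(spec: MosaicSpec) -> Tuple[GenomeSet, GroundTruth]:
    """Build the genome set and its ground truth; same spec+seed, same bytes."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    # variant pools: independent random sequences, no similarity by design
    variants: List[List[str]] = []
    for _mod in range(spec.n_modules):
        pool = []
        for _v in range(spec.variants_per_module):
            length = int(rng.integers(spec.module_length_range[0],
                                      spec.module_length_range[1] + 1))
            pool.append(_rand_seq(rng, length))
        variants.append(pool)

    blocks = [_rand_seq(rng, k) for k in spec.universal_block_lengths]
    n_blocks = len(blocks)
    # universal blocks at evenly spread module boundaries
    block_after = {
        max(1, ((j + 1) * spec.n_modules) // (n_blocks + 1)): j
        for j in range(n_blocks)
    } if n_blocks else {}
    if len(block_after) != n_blocks:
        raise InfeasibleSpecError(
            f"cannot spread {n_blocks} universal blocks over "
            f"{spec.n_modules} module boundaries")

    transposed_pairs = [(_rand_seq(rng, k), _rand_seq(rng, k))
                        for _g, k in spec.transpositions]
    dup_block = (_rand_seq(rng, spec.duplication[1])
                 if spec.duplication is not None else None)

    if spec.variant_choices is not None:
        picks = [list(row) for row in spec.variant_choices]
    else:
        picks = [
            [int(rng.integers(0, spec.variants_per_module))
             for _ in range(spec.n_modules)]
            for _ in range(spec.n_genomes)
        ]

    def linker(lo_hi=spec.linker_length_range):
        return _rand_seq(rng, int(rng.integers(lo_hi[0], lo_hi[1] + 1)))

    labels: Dict[str, List[Tuple[int, int, str]]] = {}
    anchors: List[Dict[str, Tuple[int, int]]] = [dict() for _ in blocks]
    rearrangements: List[Dict[str, Tuple[int, int]]] = [
        dict() for _ in spec.transpositions]
    genomes: List[Genome] = []

    for g in range(spec.n_genomes):
        gid = f"g{g}"
        # (label, sequence, mutable) pieces in genome order
        pieces: List[Tuple[str, str, bool]] = [("linker", linker(), True)]
        for mod in range(spec.n_modules):
            v = picks[g][mod]
            pieces.append((f"module{mod}:variant{v}", variants[mod][v], True))
            pieces.append(("linker", linker(), True))
            if mod + 1 in block_after:
                j = block_after[mod + 1]
                pieces.append((f"universal{j}", blocks[j], False))
                pieces.append(("linker", linker(), True))
        if dup_block is not None:
            dg, _seg, copies = spec.duplication
            reps = copies if g == dg else 1
            for _r in range(reps):
                pieces.append(("dup0", dup_block, False))
                pieces.append(("linker", linker(), True))
        for t, (gt, _k) in enumerate(spec.transpositions):
            x, y = transposed_pairs[t]
            first, second = (y, x) if g == gt else (x, y)
            pieces.append((f"transposed{t}", first, False))
            pieces.append(("linker", linker(), True))
            pieces.append((f"transposed{t}", second, False))
            pieces.append(("linker", linker(), True))

        # mutate the mutable pieces only
        mutated: List[Tuple[str, str]] = []
        for label, seq, mutable in pieces:
            if mutable:
                seq = _mutate(rng, seq, spec.substitution_rate, spec.indel_rate)
            mutated.append((label, seq))

        # force junction bases around planted immutable blocks to differ
        # between the rearranged genome and the others
        guard = "C" if any(g == gt for gt, _k in spec.transpositions) \
            or (spec.duplication is not None and g == spec.duplication[0]) else "A"
        for i, (label, seq) in enumerate(mutated):
            if label.startswith(("transposed", "dup")):
                if i > 0 and mutated[i - 1][0] == "linker":
                    plabel, pseq = mutated[i - 1]
                    mutated[i - 1] = (plabel, _force_flank(pseq, guard, at_end=True))
                if i + 1 < len(mutated) and mutated[i + 1][0] == "linker":
                    nlabel, nseq = mutated[i + 1]
                    mutated[i + 1] = (nlabel, _force_flank(nseq, guard, at_end=False))

        tiling: List[Tuple[int, int, str]] = []
        cursor = 1
        trans_bounds: Dict[int, Tuple[int, int]] = {}
        parts: List[str] = []
        for label, seq in mutated:
            if not seq:
                continue
            start, end = cursor, cursor + len(seq) - 1
            tiling.append((start, end, label))
            if label.startswith("universal"):
                anchors[int(label[len("universal"):])][gid] = (start, end)
            if label.startswith("transposed"):
                t = int(label[len("transposed"):])
                lo, hi = trans_bounds.get(t, (start, end))
                trans_bounds[t] = (min(lo, start), max(hi, end))
            parts.append(seq)
            cursor = end + 1
        for t, bounds in trans_bounds.items():
            rearrangements[t][gid] = bounds
        labels[gid] = tiling
        genomes.append(Genome(gid, "".join(parts)))

    return GenomeSet(genomes), GroundTruth(labels, anchors, rearrangements)


def write_truth_tsv(truth: GroundTruth, path) -> None:
    """BED-like dump: genome<TAB>start<TAB>end<TAB>label (1-based inclusive)."""
    with open(path, "w") as handle:
        for gid in truth.labels:
            for start, end, label in truth.labels[gid]:
                handle.write(f"{gid}\t{start}\t{end}\t{label}\n")


@dataclass
class RecoveryReport:
    """How well the pipeline recovered what the generator planted."""

    anchors_total: int
    anchors_recovered: int
    cross_variant_merges: int
    rearrangements_expected: int
    rearrangements_detected: int

    @property
    def anchor_recovery(self) -> Fraction:
        if self.anchors_total == 0:
            return Fraction(1)
        return Fraction(self.anchors_recovered, self.anchors_total)


def _label_arrays(truth: GroundTruth, genomes) -> Dict[int, Tuple[np.ndarray, np.ndarray]]:
    """Per genome index: (module_id, variant_id) per position; -1 = not a module."""
    arrays = {}
    for gi, g in enumerate(genomes):
        mods = np.full(g.length, -1, dtype=np.int32)
        var = np.full(g.length, -1, dtype=np.int32)
        for start, end, label in truth.labels[g.id]:
            if label.startswith("module"):
                mod_s, var_s = label.split(":")
                mods[start - 1:end] = int(mod_s[len("module"):])
                var[start - 1:end] = int(var_s[len("variant"):])
        arrays[gi] = (mods, var)
    return arrays


def _overlaps(a: Tuple[int, int], b: Tuple[int, int]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def recover_check(result, truth: GroundTruth, sccs=None) -> RecoveryReport:
    """Compare an AlignmentGraph against the generator's ground truth.

    Checks (a) the fraction of planted universal blocks contained in an
    anchor vertex, (b) that no alignment column ever joins two different
    variants of one module, (c) agreement between reported strongly
    connected components (``sccs``, from a collinearity report) and the
    planted rearrangement intervals.  ``result`` may be None when the
    input was non-collinear (then only (c) is meaningful).
    """
    n_trans = len(truth.rearrangements)
    detected = 0
    for planted in truth.rearrangements:
        hit = False
        for scc in (sccs or []):
            if any(gid in scc and _overlaps(scc[gid], planted[gid])
                   for gid in planted):
                hit = True
                break
        if hit:
            detected += 1

    if result is None:
        return RecoveryReport(len(truth.anchors), 0, 0, n_trans, detected)

    genomes = result.genomes
    full = frozenset(range(len(genomes.genomes)))
    anchor_vertices = [v for v in result.vertices if v.support == full]
    recovered = 0
    for per_genome in truth.anchors:
        for v in anchor_vertices:
            if all(v.segments[genomes.index(gid)][0] <= s
                   and e <= v.segments[genomes.index(gid)][1]
                   for gid, (s, e) in per_genome.items()):
                recovered += 1
                break

    arrays = _label_arrays(truth, genomes)
    merges = 0
    for v in result.vertices:
        if len(v.segments) < 2:
            continue
        rows_mod = []
        rows_var = []
        for gi, (s, e) in sorted(v.segments.items()):
            mods, var = arrays[gi]
            rows_mod.append(mods[s - 1:e])
            rows_var.append(var[s - 1:e])
        mod_m = np.stack(rows_mod)
        var_m = np.stack(rows_var)
        offending = np.zeros(v.length, dtype=bool)
        for i in range(len(rows_mod)):
            for j in range(i + 1, len(rows_mod)):
                both = (mod_m[i] >= 0) & (mod_m[j] >= 0)
                offending |= both & (mod_m[i] == mod_m[j]) & (var_m[i] != var_m[j])
        merges += int(offending.sum())

    return RecoveryReport(len(truth.anchors), recovered, merges, n_trans, detected)
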