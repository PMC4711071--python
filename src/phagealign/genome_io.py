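"""Genome reading, trimming, circular rotation and start normalization.

Bacteriophage genomes are circular in (part of) their life cycle but
deposited as linear sequences with arbitrary start points.  Functional
collinearity is only defined up to a circular permutation, so a set of
genomes sequenced by different projects may need to be *normalized*:
rotated so that all of them begin at the largest sequence they all
share.  This module holds the Genome/GenomeSet containers, FASTA and
region-TSV I/O, rotation, and that normalization procedure.

Coordinates are 1-based inclusive in all user-facing values; internal
indexing is 0-based half-open.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import match_engine
from .errors import (
    DuplicateIdError,
    NoCommonAnchorError,
    RegionError,
    RotationError,
    SequenceAlphabetError,
    TooFewGenomesError,
)

_VALID = re.compile(r"^[ACGTN]+$")


@dataclass(frozen=True)
class Genome:
    """A named DNA sequence, optionally trimmed and/or circularly rotated.

    ``region`` records the 1-based inclusive (start, end) window of the
    source record that ``seq`` was cut from; ``rotation_offset`` is the
    number of base pairs by which the original circular sequence was
    rotated during normalization.
    """

    id: str
    seq: str
    region: Optional[Tuple[int, int]] = None
    rotation_offset: int = 0

    def __post_init__(self):
        if len(self.seq) < 1:
            raise SequenceAlphabetError(f"genome {self.id!r}: empty sequence")
        if not _VALID.match(self.seq):
            bad = sorted(set(self.seq) - set("ACGTN"))
            raise SequenceAlphabetError(
                f"genome {self.id!r}: characters outside ACGTN: {bad}")
        if self.region is not None:
            start, end = self.region
            if len(self.seq) != end - start + 1:
                raise RegionError(
                    f"genome {self.id!r}: sequence length {len(self.seq)} does not "
                    f"match region [{start}, {end}]")
        if not 0 <= self.rotation_offset < len(self.seq):
            raise RotationError(
                f"genome {self.id!r}: rotation offset {self.rotation_offset} "
                f"out of range for length {len(self.seq)}")

    @property
    def length(self) -> int:
        return len(self.seq)

    def base(self, position: int) -> str:
        """Nucleotide at a 1-based position."""
        return self.seq[position - 1]


class GenomeSet:
    """An ordered collection of genomes with unique ids."""

    def __init__(self, genomes: Sequence[Genome]):
        self.genomes: List[Genome] = list(genomes)
        self._index: Dict[str, int] = {}
        for i, g in enumerate(self.genomes):
            if g.id in self._index:
                raise DuplicateIdError(f"duplicate genome id {g.id!r}")
            self._index[g.id] = i

    @property
    def n(self) -> int:
        return len(self.genomes)

    @property
    def total_length(self) -> int:
        """Total length of genomes in bp (N_l)."""
        return sum(g.length for g in self.genomes)

    def __len__(self) -> int:
        return len(self.genomes)

    def __iter__(self):
        return iter(self.genomes)

    def __getitem__(self, i: int) -> Genome:
        return self.genomes[i]

    def index(self, genome_id: str) -> int:
        return self._index[genome_id]

    def by_id(self, genome_id: str) -> Genome:
        return self.genomes[self._index[genome_id]]


def load_genomes(fasta_path, regions: Optional[Mapping[str, Tuple[int, int]]] = None) -> GenomeSet:
    """Read a multi-FASTA file, applying optional per-record trimming regions.

    ``regions`` maps record id to a 1-based inclusive (start, end)
    window; every region id must name a record and fit inside it.
    """
    path = Path(fasta_path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    regions = dict(regions or {})
    genomes: List[Genome] = []
    seen = set()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seen:
            raise DuplicateIdError(f"duplicate genome id {record.id!r} in {path}")
        seen.add(record.id)
        seq = str(record.seq).upper()
        region = regions.pop(record.id, None)
        if region is not None:
            start, end = region
            if not (1 <= start <= end <= len(seq)):
                raise RegionError(
                    f"region [{start}, {end}] out of bounds for record "
                    f"{record.id!r} of length {len(seq)}")
            seq = seq[start - 1:end]
        genomes.append(Genome(record.id, seq, region=region))
    if regions:
        raise RegionError(f"region ids with no matching record: {sorted(regions)}")
    return GenomeSet(genomes)


def write_fasta(genomes: GenomeSet, path) -> None:
    records = [SeqRecord(Seq(g.seq), id=g.id, description="") for g in genomes]
    SeqIO.write(records, str(path), "fasta")


def read_regions_tsv(path) -> Dict[str, Tuple[int, int]]:
    """Read ``id<TAB>start<TAB>end`` trimming coordinates."""
    regions: Dict[str, Tuple[int, int]] = {}
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            gid, start, end = line.split("\t")
            regions[gid] = (int(start), int(end))
    return regions


def write_offsets_tsv(offsets: Mapping[str, int], path) -> None:
    with open(path, "w") as handle:
        for gid, off in offsets.items():
            handle.write(f"{gid}\t{off}\n")


def rotate(genome: Genome, offset: int) -> Genome:
    """Circularly rotate so the (1-based) position offset+1 becomes position 1."""
    if not 0 <= offset < genome.length:
        raise RotationError(
            f"rotation offset {offset} out of range for length {genome.length}")
    if offset == 0:
        return genome
    seq = genome.seq[offset:] + genome.seq[:offset]
    return replace(genome, seq=seq,
                   rotation_offset=(genome.rotation_offset + offset) % genome.length)


def _doubled(genome: Genome) -> str:
    # seq ++ seq[1..L-1]: every circular substring of length <= L is linear here
    return genome.seq + genome.seq[:-1]


def find_common_anchor(genomes: GenomeSet, m: int) -> Tuple[str, List[int]]:
    """Longest substring shared by all genomes, each treated as circular.

    Returns the substring and, per genome, the 0-based circular start of
    one occurrence (the smallest in the first genome; smallest per
    genome otherwise).  Raises NoCommonAnchorError when no common
    substring of length >= m exists.  Match length is capped at the
    shortest genome length.
    """
    if genomes.n < 2:
        raise TooFewGenomesError("normalization requires at least two genomes")
    lmin = min(g.length for g in genomes)
    first = genomes[0]
    doubled = [_doubled(g) for g in genomes]
    # every all-genome common substring is inside a pairwise maximal match
    # between the first two (circularised) genomes
    candidates = match_engine._pair_mems(doubled[0], doubled[1], min(m, lmin))
    # keep one representative per circular start in genome 0
    windows = []
    for sa, _sb, length in candidates:
        if sa >= first.length:
            continue  # same circular substring as one starting < L
        windows.append((sa, min(length, lmin, first.length)))
    if not windows:
        raise NoCommonAnchorError(
            "no common anchor for normalization: the first two genomes share "
            f"no circular substring of length >= {m}")

    def best_at(length: int) -> Optional[int]:
        """Smallest circular start in genome 0 of a length-`length` substring
        present in every genome, or None."""
        best = None
        for start, cand_len in windows:
            if cand_len < length:
                continue
            for off in range(cand_len - length + 1):
                pos = start + off
                if pos >= first.length:
                    break
                if best is not None and pos >= best:
                    continue
                word = doubled[0][pos:pos + length]
                if all(word in d for d in doubled[2:]):
                    best = pos if best is None else min(best, pos)
        return best

    lo, hi = m, min(lmin, max(c for _s, c in windows))
    if best_at(lo) is None:
        raise NoCommonAnchorError(
            f"no common anchor for normalization: no substring of length >= {m} "
            "is shared by all genomes")
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if best_at(mid) is None:
            hi = mid - 1
        else:
            lo = mid
    start0 = best_at(lo)
    word = doubled[0][start0:start0 + lo]
    starts = [start0]
    for g, d in zip(genomes.genomes[1:], doubled[1:]):
        starts.append(d.find(word) % g.length)
    return word, starts


def normalize(genomes: GenomeSet, m: int) -> Tuple[GenomeSet, Dict[str, int]]:
    """Rotate every genome so the longest all-genome shared substring starts at 1.

    Returns the rotated set and the applied per-genome offsets.  Ties
    between equally long substrings are broken by the smallest start in
    the first genome, so the procedure is deterministic and idempotent.
    """
    for g in genomes:
        if g.length < m:
            raise NoCommonAnchorError(
                f"no common anchor for normalization: genome {g.id!r} is "
                f"shorter than m={m}")
    _word, starts = find_common_anchor(genomes, m)
    rotated = [rotate(g, off) for g, off in zip(genomes, starts)]
    return GenomeSet(rotated), {g.id: off for g, off in zip(genomes, starts)}


def needs_normalization(genomes: GenomeSet, m: int, max_start: int = 1000) -> bool:
    """Heuristic half of the 'auto' normalization trigger.

    True when the longest all-genome common substring does not start
    within ``max_start`` bp of position 1 in every genome.  (The other
    trigger — a cyclic column graph at the requested m — is evaluated by
    the caller, which has the column graph at hand.)  False when the
    genomes share no anchor at all, since normalization could not help.
    """
    try:
        _word, starts = find_common_anchor(genomes, m)
    except (NoCommonAnchorError, TooFewGenomesError):
        return False
    return any(off > max_start for off in starts)
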