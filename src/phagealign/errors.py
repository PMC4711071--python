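"""Named exceptions raised by the alignment pipeline."""


class AlignmentError(Exception):
    """Base class for all package-specific errors."""


class DuplicateIdError(AlignmentError):
    """Two FASTA records share the same identifier."""


class RegionError(AlignmentError):
    """A trimming region does not fit the record it refers to."""


class SequenceAlphabetError(AlignmentError):
    """A sequence contains characters outside {A, C, G, T, N}."""


class RotationError(AlignmentError):
    """A circular rotation offset is out of range."""


class NoCommonAnchorError(AlignmentError):
    """Raised when normalization finds no common anchor.

    Message is always "no common anchor for normalization" plus detail.
    """


class TooFewGenomesError(AlignmentError):
    """An operation requiring at least two genomes got fewer."""


class MatchBoundsError(AlignmentError):
    """A match refers to coordinates outside its genomes."""


class CyclicGraphError(AlignmentError):
    """The column graph contains a cycle (non-collinear input).

    Carries the offending strongly connected components in ``sccs``:
    a list of dicts mapping genome id to the (min, max) 1-based
    positions involved in the cycle.
    """

    def __init__(self, message, sccs=None):
        super().__init__(message)
        self.sccs = sccs or []


class AutoMCeilingError(CyclicGraphError):
    """auto_m hit its ceiling while the column graph was still cyclic.

    The remaining SCCs are rearrangement evidence.
    """


class AnchorOrderError(AlignmentError):
    """The two anchors given to a sub-region re-alignment are not ordered."""


class InfeasibleSpecError(AlignmentError):
    """A synthetic-genome specification cannot be realised."""
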