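"""Replication-fork geometry at a directionally replicated reporter locus.

A locus sitting next to a highly efficient replication origin is replicated
by a single fork whose direction is fixed by which side of the origin the
locus lies on.  Because nascent DNA grows 5'->3', fork direction determines
which genome strand is copied continuously (leading) and which is copied as
Okazaki fragments (lagging):

* leftward-moving fork (locus left of the origin): the nascent leading
  strand elongates right-to-left, i.e. it is the *bottom* strand of the
  published sequence;
* rightward-moving fork (locus right of the origin): the nascent leading
  strand is the *top* strand.

"Top" is the strand written 5'->3' left-to-right in the reference FASTA.

The same reporter cassette can be integrated in two orientations (forward
and reverse).  Flipping the cassette swaps which genome strand carries the
reporter's sense sequence and mirrors reporter coordinates within the
locus, which is what lets strand-biased error signatures be read out as
orientation-dependent mutation spectra.

All coordinates are 0-based, half-open.  File readers convert from 1-based
input (see :mod:`forkasym.io`).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

__all__ = [
    "GenomeStrand",
    "Orientation",
    "ReporterStrand",
    "ForkDirection",
    "LocusGeometry",
    "StrandRoleMap",
    "AmbiguousGeometryError",
    "nascent_strand_roles",
    "sense_carrier",
    "reporter_to_genome",
    "genome_to_reporter",
]


class GenomeStrand(str, Enum):
    """One of the two antiparallel genome strands."""

    TOP = "top"
    BOTTOM = "bottom"

    @property
    def other(self) -> "GenomeStrand":
        """Complementary strand; an involution."""
        return GenomeStrand.BOTTOM if self is GenomeStrand.TOP else GenomeStrand.TOP


class Orientation(str, Enum):
    """Reporter-cassette orientation relative to the reference sequence."""

    FORWARD = "forward"
    REVERSE = "reverse"


class ReporterStrand(str, Enum):
    """Strand of the reporter itself: sense (mRNA-like) or antisense."""

    SENSE = "sense"
    ANTISENSE = "antisense"


class ForkDirection(str, Enum):
    LEFTWARD = "leftward"
    RIGHTWARD = "rightward"


class AmbiguousGeometryError(ValueError):
    """The locus straddles or contains the origin: no single fork direction."""


@dataclass(frozen=True)
class LocusGeometry:
    """Half-open genomic interval [start, end) plus the origin it is replicated from.

    Parameters
    ----------
    start, end
        0-based half-open bounds of the locus.
    origin_pos
        Coordinate of the (cluster of) replication origin(s).  For a
        single-fork locus the origin lies outside ``[start, end)``; models
        that span both flanks of an origin (ribonucleotide fragmentation)
        may place it inside, in which case per-side roles apply.
    sense_carrier_forward
        Genome strand carrying the reporter sense sequence in the forward
        construct.  Defaults to top: in the forward construct the reference
        FASTA *is* the sense sequence.
    """

    start: int
    end: int
    origin_pos: int
    sense_carrier_forward: GenomeStrand = GenomeStrand.TOP

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty locus region [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def contains_origin(self) -> bool:
        return self.start <= self.origin_pos < self.end

    @property
    def fork_direction(self) -> ForkDirection:
        """Direction of the fork replicating the locus.

        Raises
        ------
        AmbiguousGeometryError
            If the origin lies inside the locus.
        """
        if self.contains_origin:
            raise AmbiguousGeometryError(
                f"origin at {self.origin_pos} lies inside locus "
                f"[{self.start}, {self.end}); fork direction is ambiguous"
            )
        # Origin to the right -> the fork travels right-to-left across the locus.
        return ForkDirection.LEFTWARD if self.origin_pos >= self.end else ForkDirection.RIGHTWARD


@dataclass(frozen=True)
class StrandRoleMap:
    """Which genome strand is the nascent leading vs lagging strand."""

    leading_nascent: GenomeStrand
    lagging_nascent: GenomeStrand

    def __post_init__(self) -> None:
        if self.leading_nascent is self.lagging_nascent:
            raise ValueError("leading and lagging nascent strands must differ")

    def role_of(self, strand: GenomeStrand) -> str:
        return "leading" if strand is self.leading_nascent else "lagging"

    def strand_for(self, role: str) -> GenomeStrand:
        if role == "leading":
            return self.leading_nascent
        if role == "lagging":
            return self.lagging_nascent
        raise ValueError(f"unknown strand role {role!r}")

    def swapped(self) -> "StrandRoleMap":
        return StrandRoleMap(self.lagging_nascent, self.leading_nascent)


def nascent_strand_roles(geometry: LocusGeometry) -> StrandRoleMap:
    """Assign leading/lagging roles to the genome strands at a locus.

    A leftward fork synthesizes its leading strand 5'->3' right-to-left,
    which is the bottom strand; a rightward fork's leading strand is the
    top strand.

    Raises
    ------
    AmbiguousGeometryError
        If the locus contains the origin.
    """
    direction = geometry.fork_direction
    leading = GenomeStrand.BOTTOM if direction is ForkDirection.LEFTWARD else GenomeStrand.TOP
    return StrandRoleMap(leading_nascent=leading, lagging_nascent=leading.other)


def sense_carrier(orientation: Orientation, locus: LocusGeometry) -> GenomeStrand:
    """Genome strand carrying the reporter sense sequence in ``orientation``."""
    carrier = locus.sense_carrier_forward
    return carrier if orientation is Orientation.FORWARD else carrier.other


def reporter_to_genome(
    orientation: Orientation,
    reporter_pos: int,
    reporter_strand: ReporterStrand,
    locus: LocusGeometry,
) -> tuple[int, GenomeStrand]:
    """Map a reporter coordinate/strand onto genome coordinate/strand.

    The forward construct embeds the reporter co-linearly; the reverse
    construct mirrors coordinates within the locus and swaps strands.
    """
    if not 0 <= reporter_pos < locus.length:
        raise IndexError(
            f"reporter position {reporter_pos} outside [0, {locus.length})"
        )
    carrier = sense_carrier(orientation, locus)
    strand = carrier if reporter_strand is ReporterStrand.SENSE else carrier.other
    if orientation is Orientation.FORWARD:
        pos = locus.start + reporter_pos
    else:
        pos = locus.end - 1 - reporter_pos
    return pos, strand


def genome_to_reporter(
    orientation: Orientation,
    genome_pos: int,
    genome_strand: GenomeStrand,
    locus: LocusGeometry,
) -> tuple[int, ReporterStrand]:
    """Inverse of :func:`reporter_to_genome`."""
    if not locus.start <= genome_pos < locus.end:
        raise IndexError(
            f"genome position {genome_pos} outside [{locus.start}, {locus.end})"
        )
    carrier = sense_carrier(orientation, locus)
    strand = ReporterStrand.SENSE if genome_strand is carrier else ReporterStrand.ANTISENSE
    if orientation is Orientation.FORWARD:
        pos = genome_pos - locus.start
    else:
        pos = locus.end - 1 - genome_pos
    return pos, strand
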