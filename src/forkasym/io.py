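"""Readers and writers for the plain-text formats the pipeline consumes.

All on-disk coordinates default to 1-based (the convention of published
reporter maps); everything in memory is 0-based half-open.  Parse errors
carry file and line numbers.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd
from Bio import SeqIO

from .geometry import GenomeStrand, LocusGeometry, Orientation
from .mispair import MUTATION_CLASSES, MutationRecord
from .rnmp import ProbeWindow

__all__ = [
    "ParseError",
    "CATALOG_COLUMNS",
    "read_catalog",
    "write_catalog",
    "records_from_frame",
    "read_fasta",
    "read_geometry_bed",
    "read_probes_bed",
    "read_fluctuation_counts",
]

CATALOG_COLUMNS = ["locus_id", "position", "ref", "alt", "mclass", "orientation", "strain"]

_STRAND_TOKENS = {
    "top": GenomeStrand.TOP,
    "bottom": GenomeStrand.BOTTOM,
    "+": GenomeStrand.TOP,
    "-": GenomeStrand.BOTTOM,
}


class ParseError(ValueError):
    """Malformed input file; message carries path and line number."""


def _data_lines(path) -> Iterable[tuple[int, list[str]]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split("\t")


def read_catalog(path, coordinate_base: int = 1) -> pd.DataFrame:
    """Read a mutation catalog TSV into a frame with 0-based positions.

    Expected columns: ``locus_id, position, ref, alt, mclass,
    orientation, strain`` with a ``#``-prefixed header line and gap token
    ``-``.
    """
    if coordinate_base not in (0, 1):
        raise ValueError("coordinate_base must be 0 or 1")
    rows = []
    for lineno, fields in _data_lines(path):
        if len(fields) != len(CATALOG_COLUMNS):
            raise ParseError(
                f"{path}:{lineno}: expected {len(CATALOG_COLUMNS)} tab-separated "
                f"fields, got {len(fields)}"
            )
        locus_id, position, ref, alt, mclass, orientation, strain = fields
        try:
            pos = int(position) - coordinate_base
        except ValueError:
            raise ParseError(f"{path}:{lineno}: bad position {position!r}") from None
        if pos < 0:
            raise ParseError(f"{path}:{lineno}: position below coordinate base")
        if mclass not in MUTATION_CLASSES:
            raise ParseError(f"{path}:{lineno}: unknown mutation class {mclass!r}")
        try:
            Orientation(orientation)
        except ValueError:
            raise ParseError(f"{path}:{lineno}: unknown orientation {orientation!r}") from None
        rows.append(
            {
                "locus_id": locus_id,
                "position": pos,
                "ref": ref,
                "alt": alt,
                "mclass": mclass,
                "orientation": orientation,
                "strain": strain,
            }
        )
    return pd.DataFrame(rows, columns=CATALOG_COLUMNS)


def write_catalog(catalog: pd.DataFrame, path, coordinate_base: int = 1) -> None:
    """Write a catalog frame (0-based positions) to TSV."""
    if coordinate_base not in (0, 1):
        raise ValueError("coordinate_base must be 0 or 1")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#" + "\t".join(CATALOG_COLUMNS) + "\n")
        for row in catalog.itertuples(index=False):
            fh.write(
                f"{row.locus_id}\t{row.position + coordinate_base}\t{row.ref}\t"
                f"{row.alt}\t{row.mclass}\t{row.orientation}\t{row.strain}\n"
            )


def records_from_frame(catalog: pd.DataFrame) -> list[MutationRecord]:
    """Convert a catalog frame into validated :class:`MutationRecord` objects."""
    return [
        MutationRecord(
            locus_id=row.locus_id,
            position=int(row.position),
            ref=row.ref,
            alt=row.alt,
            mclass=row.mclass,
            orientation=Orientation(row.orientation),
            strain=row.strain,
        )
        for row in catalog.itertuples(index=False)
    ]


def read_fasta(path) -> tuple[str, str]:
    """(id, uppercase sequence) of the single record in a FASTA file."""
    with open(path, encoding="utf-8") as fh:
        records = list(SeqIO.parse(fh, "fasta"))
    if len(records) != 1:
        raise ParseError(f"{path}: expected exactly one FASTA record, found {len(records)}")
    return records[0].id, str(records[0].seq).upper()


def read_geometry_bed(
    path,
    origin_pos: int,
    sense_carrier_forward: GenomeStrand = GenomeStrand.TOP,
) -> LocusGeometry:
    """Locus geometry from a single-interval BED file plus an origin coordinate.

    BED intervals are already 0-based half-open; the origin coordinate is
    a configuration datum (e.g. the 2-D-gel-derived fork direction enters
    as origin placement relative to the locus).
    """
    intervals = list(_data_lines(path))
    if len(intervals) != 1:
        raise ParseError(f"{path}: expected exactly one locus interval, found {len(intervals)}")
    lineno, fields = intervals[0]
    if len(fields) < 3:
        raise ParseError(f"{path}:{lineno}: BED needs chrom, start, end")
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError:
        raise ParseError(f"{path}:{lineno}: bad interval bounds") from None
    return LocusGeometry(
        start=start,
        end=end,
        origin_pos=origin_pos,
        sense_carrier_forward=sense_carrier_forward,
    )


def read_probes_bed(path) -> list[ProbeWindow]:
    """Probe windows from a BED-like file: chrom start end label strand.

    Strand tokens: ``top``/``+`` for the top strand, ``bottom``/``-`` for
    the bottom strand.
    """
    probes = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 5:
            raise ParseError(f"{path}:{lineno}: expected chrom, start, end, label, strand")
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError:
            raise ParseError(f"{path}:{lineno}: bad interval bounds") from None
        token = fields[4].strip().lower()
        if token not in _STRAND_TOKENS:
            raise ParseError(f"{path}:{lineno}: unknown strand token {fields[4]!r}")
        probes.append(ProbeWindow(start=start, end=end, strand=_STRAND_TOKENS[token], label=fields[3]))
    if not probes:
        raise ParseError(f"{path}: no probe windows found")
    return probes


def read_fluctuation_counts(path) -> dict[str, list[int]]:
    """Per-assay culture counts from a TSV with columns ``assay_id, count``."""
    assays: dict[str, list[int]] = {}
    for lineno, fields in _data_lines(path):
        if len(fields) != 2:
            raise ParseError(f"{path}:{lineno}: expected 'assay_id<TAB>count'")
        try:
            count = int(fields[1])
        except ValueError:
            raise ParseError(f"{path}:{lineno}: bad count {fields[1]!r}") from None
        if count < 0:
            raise ParseError(f"{path}:{lineno}: negative count")
        assays.setdefault(fields[0], []).append(count)
    if not assays:
        raise ParseError(f"{path}: no culture counts found")
    return assays
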