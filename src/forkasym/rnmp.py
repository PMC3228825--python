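"""Strand-specific rNMP incorporation, repair, and alkaline fragmentation.

Replicative polymerases occasionally incorporate ribonucleotides; RNase H2
normally excises them.  A polymerase variant with elevated rNMP
incorporation, combined with loss of RNase H2 (rnh201Δ), leaves a dense
track of alkali-labile positions specifically in the strand that
polymerase synthesizes.  Alkaline treatment cleaves at every retained
rNMP, so strand-specific probing of fragment sizes around an origin reads
out which nascent strand each polymerase made: for a leading-strand
polymerase the short-fragment (alkali-sensitive) strand is the bottom
strand left of the origin and the top strand right of it.

The forward model places rNMPs i.i.d. per nucleotide at a role-dependent
rate (leading vs lagging, role switching at the origin), removes each with
probability ``repair_efficiency``, and cuts every strand at retained rNMP
positions (plus optional restriction sites and the region boundaries).
Gel physics is not modelled: "sensitivity" is defined on fragment-length
summaries within probe windows, not on migration distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .geometry import GenomeStrand, LocusGeometry, nascent_strand_roles

__all__ = [
    "RnmpModel",
    "RnmpStrandProfile",
    "ProbeWindow",
    "ProbeSignal",
    "MissingProbeCoverageError",
    "default_probe_windows",
    "simulate_rnmp",
    "probe_signal",
    "call_sensitive_strand",
    "DEFAULT_RATE_LEADING_MUTANT",
    "DEFAULT_RATE_BACKGROUND",
    "DEFAULT_RATE_WILDTYPE",
]

#: Retained rNMP density (per nucleotide) on the strand made by the
#: rNMP-promiscuous polymerase variant when RNase H2 is absent; order of
#: magnitude borrowed from the budding-yeast M644G work (~1 rNMP/kb).
DEFAULT_RATE_LEADING_MUTANT = 1e-3
#: Background incorporation on the strand made by the other replicase.
DEFAULT_RATE_BACKGROUND = 1e-4
#: Wild-type polymerase incorporation (both strands alike).
DEFAULT_RATE_WILDTYPE = 2.5e-4


class MissingProbeCoverageError(ValueError):
    """A flank of the origin lacks a probe for one of the strands."""


def default_probe_windows(geometry: LocusGeometry) -> list["ProbeWindow"]:
    """Two probe pairs flanking the origin, one per strand per flank (A-D).

    Windows keep a 10%-of-region margin from both the origin and the
    region boundaries so edge fragments do not dominate the summaries.
    """
    margin = geometry.length // 10
    left = (geometry.start + margin, geometry.origin_pos - margin)
    right = (geometry.origin_pos + margin, geometry.end - margin)
    return [
        ProbeWindow(left[0], left[1], GenomeStrand.TOP, "A"),
        ProbeWindow(left[0], left[1], GenomeStrand.BOTTOM, "B"),
        ProbeWindow(right[0], right[1], GenomeStrand.TOP, "C"),
        ProbeWindow(right[0], right[1], GenomeStrand.BOTTOM, "D"),
    ]


@dataclass(frozen=True)
class RnmpModel:
    """Incorporation/repair parameters over a region around an origin.

    ``rate_leading``/``rate_lagging`` are per-nucleotide incorporation
    probabilities on the nascent leading/lagging strand; each incorporated
    rNMP is removed with probability ``repair_efficiency`` (1 ≈ RNase H2
    proficient, 0 = rnh201Δ).
    """

    geometry: LocusGeometry
    rate_leading: float
    rate_lagging: float
    repair_efficiency: float

    def __post_init__(self) -> None:
        for name in ("rate_leading", "rate_lagging", "repair_efficiency"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class ProbeWindow:
    """Half-open genome interval hybridizing to one specific strand."""

    start: int
    end: int
    strand: GenomeStrand
    label: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty probe window [{self.start}, {self.end})")


@dataclass
class RnmpStrandProfile:
    """Retained rNMP positions and alkaline-cleavage fragments per strand."""

    geometry: LocusGeometry
    positions: dict[GenomeStrand, np.ndarray]
    cut_sites: tuple[int, ...] = ()

    def fragment_bounds(self, strand: GenomeStrand) -> np.ndarray:
        """(n_fragments, 2) array of half-open fragment intervals.

        Cleavage at an rNMP leaves the labile nucleotide at the start of
        the downstream fragment, so fragment lengths always sum to the
        region length.
        """
        start, end = self.geometry.start, self.geometry.end
        cuts = np.unique(
            np.concatenate(
                [
                    np.asarray([start, end]),
                    np.asarray(self.positions[strand], dtype=int),
                    np.asarray(self.cut_sites, dtype=int),
                ]
            )
        )
        cuts = cuts[(cuts >= start) & (cuts <= end)]
        return np.column_stack([cuts[:-1], cuts[1:]])

    def fragment_lengths(self, strand: GenomeStrand) -> np.ndarray:
        bounds = self.fragment_bounds(strand)
        return bounds[:, 1] - bounds[:, 0]


def _per_position_rate(model: RnmpModel, strand: GenomeStrand) -> np.ndarray:
    """Retained-rNMP probability per nucleotide of ``strand`` across the region."""
    geom = model.geometry
    length = geom.length
    retain = 1.0 - model.repair_efficiency
    rates = {"leading": model.rate_leading * retain, "lagging": model.rate_lagging * retain}
    out = np.empty(length)
    if geom.contains_origin:
        split = geom.origin_pos - geom.start
        # Left flank: leftward fork, leading nascent strand = bottom.
        left_role = "leading" if strand is GenomeStrand.BOTTOM else "lagging"
        right_role = "leading" if strand is GenomeStrand.TOP else "lagging"
        out[:split] = rates[left_role]
        out[split:] = rates[right_role]
    else:
        roles = nascent_strand_roles(geom)
        out[:] = rates[roles.role_of(strand)]
    return out


def simulate_rnmp(
    model: RnmpModel,
    seed: int | np.random.Generator = 0,
    cut_sites: Sequence[int] = (),
) -> RnmpStrandProfile:
    """Draw one rNMP realization for both strands of the region.

    Each nucleotide of each nascent strand independently carries a
    retained rNMP with probability rate(role) x (1 - repair_efficiency).
    Optional ``cut_sites`` model restriction digestion before alkali.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    geom = model.geometry
    positions: dict[GenomeStrand, np.ndarray] = {}
    for strand in (GenomeStrand.TOP, GenomeStrand.BOTTOM):
        p = _per_position_rate(model, strand)
        hits = rng.random(geom.length) < p
        positions[strand] = geom.start + np.flatnonzero(hits)
    return RnmpStrandProfile(geometry=geom, positions=positions, cut_sites=tuple(cut_sites))


@dataclass(frozen=True)
class ProbeSignal:
    """Fragment-length summary on one strand within one probe window."""

    probe: ProbeWindow
    median_detected_length: float
    fraction_below_threshold: float
    n_fragments: int
    length_threshold: int


def probe_signal(
    profile: RnmpStrandProfile,
    probe: ProbeWindow,
    length_threshold: int = 5000,
) -> ProbeSignal:
    """Summarize the fragments that a strand-specific probe would light up.

    Considers every fragment on the probe's strand overlapping the probe
    interval.  Hybridization signal is proportional to the length a
    fragment shares with the probe window, so summaries are weighted by
    that overlap: ``median_detected_length`` is the fragment length at
    which half the probe-detected signal mass lies in shorter fragments,
    and ``fraction_below_threshold`` is the signal-mass fraction in
    fragments shorter than ``length_threshold`` (a proxy for smearing
    low on an alkaline gel).
    """
    geom = profile.geometry
    if not (geom.start <= probe.start and probe.end <= geom.end):
        raise ValueError("probe window outside the simulated region")
    if probe.strand not in profile.positions:
        raise MissingProbeCoverageError(f"strand {probe.strand.value} absent from profile")
    bounds = profile.fragment_bounds(probe.strand)
    overlap_len = np.minimum(bounds[:, 1], probe.end) - np.maximum(bounds[:, 0], probe.start)
    keep = overlap_len > 0
    lengths = (bounds[keep, 1] - bounds[keep, 0]).astype(float)
    weights = overlap_len[keep].astype(float)
    order = np.argsort(lengths)
    lengths, weights = lengths[order], weights[order]
    cum = np.cumsum(weights)
    median_detected = float(lengths[np.searchsorted(cum, 0.5 * cum[-1])])
    below = float(weights[lengths < length_threshold].sum() / cum[-1])
    return ProbeSignal(
        probe=probe,
        median_detected_length=median_detected,
        fraction_below_threshold=below,
        n_fragments=int(lengths.size),
        length_threshold=length_threshold,
    )


def call_sensitive_strand(
    signals: Iterable[ProbeSignal],
    origin_pos: int,
    threshold_ratio: float = 0.25,
    short_threshold: float | None = None,
) -> dict[str, str]:
    """Call the alkali-sensitive strand on each side of the origin.

    A strand is called sensitive on a flank when the median detected
    fragment length of its probe(s) is below ``threshold_ratio`` times
    that of the opposite strand.  With an absolute ``short_threshold``
    both strands can be called ("both") when each median falls below it;
    otherwise calls are one of {top, bottom, none}.

    Parameters
    ----------
    signals
        Probe summaries covering both strands on each side of the origin.
    origin_pos
        Coordinate separating the left and right flanks.

    Returns
    -------
    dict
        ``{"left": call, "right": call}`` with call in
        {"top", "bottom", "none", "both"}.
    """
    if not 0 < threshold_ratio < 1:
        raise ValueError("threshold_ratio must be in (0, 1)")
    by_side: dict[str, dict[GenomeStrand, list[float]]] = {"left": {}, "right": {}}
    for sig in signals:
        probe = sig.probe
        if probe.end <= origin_pos:
            side = "left"
        elif probe.start >= origin_pos:
            side = "right"
        else:
            raise ValueError(f"probe {probe.label!r} spans the origin")
        by_side[side].setdefault(probe.strand, []).append(sig.median_detected_length)
    calls: dict[str, str] = {}
    for side, medians in by_side.items():
        for strand in (GenomeStrand.TOP, GenomeStrand.BOTTOM):
            if strand not in medians:
                raise MissingProbeCoverageError(
                    f"no probe for the {strand.value} strand on the {side} flank"
                )
        med_top = float(np.median(medians[GenomeStrand.TOP]))
        med_bottom = float(np.median(medians[GenomeStrand.BOTTOM]))
        if short_threshold is not None and med_top < short_threshold and med_bottom < short_threshold:
            calls[side] = "both"
        elif med_top < threshold_ratio * med_bottom:
            calls[side] = "top"
        elif med_bottom < threshold_ratio * med_top:
            calls[side] = "bottom"
        else:
            calls[side] = "none"
    return calls
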