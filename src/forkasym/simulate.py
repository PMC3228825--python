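"""Synthetic-data generators with recorded ground truth.

Three generators emulate the inputs the analysis consumes:

* strand-biased mutator catalogs — each synthetic 5-FOA-resistant isolate
  carries exactly one causal mutation, drawn from a class mix and, for
  substitutions/single-base deletions, from per-mispair error rates of a
  mutator assigned to one nascent strand, then reported in the reporter
  sense-strand convention for the construct orientation it arose in;
* Luria-Delbrück fluctuation-assay colony counts under discrete-generation
  growth with jackpot clone expansion;
* (in :mod:`forkasym.rnmp`) per-strand rNMP position profiles.

Every generator takes an explicit seed, and catalog generation returns a
ground-truth table (true mispair, synthesized strand, genome position per
record) so recovery tests can close the loop against the classifier.

Selection is simplified: every generated mutation is assumed to confer
5-FOA resistance; no codon-level ura4/ura5 function model is attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import datafiles
from .geometry import (
    GenomeStrand,
    LocusGeometry,
    Orientation,
    genome_to_reporter,
    nascent_strand_roles,
    sense_carrier,
)
from .mispair import (
    BASES,
    COMPLEMENT,
    GAP,
    InVitroBiasPrior,
    Mispair,
)

__all__ = [
    "DEFAULT_CLASS_MIX",
    "MutatorSpec",
    "GroundTruth",
    "synthetic_reference",
    "load_reference",
    "generate_catalog",
    "simulate_fluctuation_assay",
]

#: Default event-class mix, mirroring the observed polδ-L591M class
#: proportions across both orientations (substitutions 168, 1-base
#: deletions 88, 1-base insertions 15, duplications 92, deletions 31,
#: other 71, of 465 isolates).
DEFAULT_CLASS_MIX = {
    "substitution": 168 / 465,
    "del1": 88 / 465,
    "ins1": 15 / 465,
    "duplication": 92 / 465,
    "deletion": 31 / 465,
    "other": 71 / 465,
}

#: Default isolates per orientation, on the scale of one sequenced
#: mutator campaign.
DEFAULT_N_MUTANTS = 233


@dataclass
class MutatorSpec:
    """Error profile of a simulated mutator polymerase.

    Parameters
    ----------
    assigned_role
        Which nascent strand the mutator synthesizes ("lagging" or
        "leading"); the generator converts this to a genome strand per
        orientation through the locus geometry.
    mispair_rates
        Relative error rates per mispair (substitutions and ΔN deletion
        intermediates).  Defaults to the shipped in-vitro prior.
    class_mix
        Probabilities over event classes; must sum to 1.
    n_mutants
        Isolates generated per orientation.
    """

    assigned_role: str
    mispair_rates: dict[str, float] = field(default_factory=dict)
    class_mix: dict[str, float] = field(default_factory=dict)
    n_mutants: int = DEFAULT_N_MUTANTS

    def __post_init__(self) -> None:
        if self.assigned_role not in ("lagging", "leading"):
            raise ValueError(f"assigned_role must be lagging/leading, not {self.assigned_role!r}")
        if not self.mispair_rates:
            self.mispair_rates = dict(InVitroBiasPrior.default().rates)
        if any(r < 0 for r in self.mispair_rates.values()):
            raise ValueError("mispair rates must be non-negative")
        if not self.class_mix:
            self.class_mix = dict(DEFAULT_CLASS_MIX)
        total = sum(self.class_mix.values())
        if not math.isclose(total, 1.0, rel_tol=1e-9):
            raise ValueError(f"class mix sums to {total}, expected 1")
        if self.n_mutants < 0:
            raise ValueError("n_mutants must be non-negative")


@dataclass
class GroundTruth:
    """Per-record generating truth: one row per emitted catalog record."""

    frame: pd.DataFrame
    spec: MutatorSpec
    seed: int


def synthetic_reference(length: int = 1600, gc: float = 0.36, seed: int = 7) -> str:
    """Deterministic synthetic reporter sequence (AT-rich like the real locus)."""
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    return "".join(rng.choice(list(BASES), size=length, p=p))


def load_reference() -> str:
    """Top-strand sequence of the shipped synthetic reporter reference."""
    with open(datafiles.reference_fasta_path(), encoding="utf-8") as fh:
        record = next(SeqIO.parse(fh, "fasta"))
    return str(record.seq).upper()


def _mispair_site_bases(mp: Mispair, synth: GenomeStrand) -> str:
    """Top-strand base at which ``mp`` can occur during synthesis of ``synth``.

    Synthesis of a strand copies its complementary (template) strand, so a
    mispair with template base X requires the template strand to read X
    there: top-strand base complement(X) when the top strand is being
    made, X when the bottom strand is.
    """
    return COMPLEMENT[mp.template] if synth is GenomeStrand.TOP else mp.template


def generate_catalog(
    reference: str,
    geometry: LocusGeometry,
    spec: MutatorSpec,
    orientations: tuple[Orientation, ...] = (Orientation.FORWARD, Orientation.REVERSE),
    seed: int = 0,
    locus_id: str = "reporter",
    strain: str = "sim-mutator",
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a mutation catalog plus its ground truth.

    Returns
    -------
    catalog : pandas.DataFrame
        Columns ``locus_id, position, ref, alt, mclass, orientation,
        strain`` with 0-based reporter-sense positions (the TSV writer
        converts on output).
    truth : GroundTruth
        One row per record: orientation, class, true mispair, synthesized
        genome strand, genome position.
    """
    reference = reference.upper()
    if len(reference) != geometry.length:
        raise ValueError(
            f"reference length {len(reference)} != locus length {geometry.length}"
        )
    seq = np.frombuffer(reference.encode(), dtype="S1")
    sites_by_top_base = {
        b: geometry.start + np.flatnonzero(seq == b.encode()) for b in BASES
    }
    roles = nascent_strand_roles(geometry)
    rng = np.random.default_rng(seed)

    classes = sorted(spec.class_mix)
    class_p = np.array([spec.class_mix[c] for c in classes])
    mispairs = [Mispair.parse(k) for k in sorted(spec.mispair_rates)]
    sub_mispairs = [m for m in mispairs if not m.is_deletion and spec.mispair_rates[str(m)] > 0]
    del_mispairs = [m for m in mispairs if m.is_deletion and spec.mispair_rates[str(m)] > 0]

    records: list[dict] = []
    truth_rows: list[dict] = []
    for orientation in orientations:
        synth = roles.strand_for(spec.assigned_role)
        carrier = sense_carrier(orientation, geometry)
        drawn = rng.choice(len(classes), size=spec.n_mutants, p=class_p)
        for k in drawn:
            mclass = classes[int(k)]
            true_mispair: Mispair | None = None
            if mclass in ("substitution", "del1"):
                pool = sub_mispairs if mclass == "substitution" else del_mispairs
                if not pool:
                    raise ValueError(f"no nonzero mispair rates for class {mclass}")
                weights = np.array([spec.mispair_rates[str(m)] for m in pool])
                mp = pool[int(rng.choice(len(pool), p=weights / weights.sum()))]
                sites = sites_by_top_base[_mispair_site_bases(mp, synth)]
                if sites.size == 0:
                    raise ValueError(
                        f"reference has no site compatible with mispair {mp} "
                        f"on the {synth.value} strand"
                    )
                genome_pos = int(sites[rng.integers(sites.size)])
                true_mispair = mp
                if mclass == "substitution":
                    if synth is GenomeStrand.TOP:
                        ref_top, alt_top = COMPLEMENT[mp.template], mp.incoming
                    else:
                        ref_top, alt_top = mp.template, COMPLEMENT[mp.incoming]
                    if carrier is GenomeStrand.TOP:
                        ref, alt = ref_top, alt_top
                    else:
                        ref, alt = COMPLEMENT[ref_top], COMPLEMENT[alt_top]
                else:
                    top_base = reference[genome_pos - geometry.start]
                    ref = top_base if carrier is GenomeStrand.TOP else COMPLEMENT[top_base]
                    alt = GAP
            elif mclass == "ins1":
                genome_pos = int(geometry.start + rng.integers(geometry.length))
                ref, alt = GAP, BASES[int(rng.integers(4))]
            else:  # duplication, deletion, other: position only
                genome_pos = int(geometry.start + rng.integers(geometry.length))
                ref = alt = "."
            reporter_pos, _ = genome_to_reporter(
                orientation, genome_pos, carrier, geometry
            )
            records.append(
                {
                    "locus_id": locus_id,
                    "position": reporter_pos,
                    "ref": ref,
                    "alt": alt,
                    "mclass": mclass,
                    "orientation": orientation.value,
                    "strain": strain,
                }
            )
            truth_rows.append(
                {
                    "orientation": orientation.value,
                    "mclass": mclass,
                    "mispair": str(true_mispair) if true_mispair is not None else "NA",
                    "synthesized_strand": synth.value if true_mispair is not None else "NA",
                    "genome_pos": genome_pos,
                }
            )
    catalog = pd.DataFrame(
        records,
        columns=["locus_id", "position", "ref", "alt", "mclass", "orientation", "strain"],
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["orientation", "mclass", "mispair", "synthesized_strand", "genome_pos"],
    )
    truth.insert(0, "record_index", range(len(truth)))
    return catalog, GroundTruth(frame=truth, spec=spec, seed=seed)


def simulate_fluctuation_assay(
    mu: float,
    N0: float,
    Nt: float,
    n_cultures: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Simulate final mutant counts of parallel cultures (Luria-Delbrück).

    Discrete-generation growth: each generation every cell divides; new
    mutations arise Poisson(mu x wild-type divisions that generation) and
    the resulting mutant lineages double in every subsequent generation.
    When Nt/N0 is not a power of two the last partial generation is
    pro-rated: pre-existing mutants grow by the fractional factor 2^f and
    new mutations arise in proportion to the wild-type divisions of that
    partial step.

    For power-of-two growth through G generations the expected final
    mutant count is mu * Nt * G / 2 (a clone born in generation g doubles
    G-1-g times), while the expected number of mutation events — the
    quantity the Lea-Coulson estimator targets — is mu * (Nt - N0).
    """
    if not 0 <= mu < 1e-3:
        raise ValueError("mu must be in [0, 1e-3)")
    if not 0 < N0 < Nt:
        raise ValueError("need 0 < N0 < Nt")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    generations = math.log2(Nt / N0)
    g_full = int(math.floor(generations))
    frac = generations - g_full
    wt = np.full(n_cultures, float(N0))
    mutants = np.zeros(n_cultures)
    for _ in range(g_full):
        new = rng.poisson(mu * wt)
        mutants = 2.0 * mutants + new
        wt = 2.0 * wt - new
    if frac > 1e-12:
        growth = 2.0 ** frac
        new = rng.poisson(mu * wt * (growth - 1.0))
        mutants = np.rint(mutants * growth) + new
    return mutants.astype(np.int64)
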