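"""Template:dNTP mispair classification of reporter mutation spectra.

Every base-pair substitution observed in duplex DNA is compatible with
exactly two polymerase errors, one per synthesized strand.  An A:T -> G:C
change, written with A on the top strand, arises either from a T:dG
mispair made while synthesizing the top strand (template T on the bottom
strand, incoming dGTP) or from an A:dC mispair made while synthesizing the
bottom strand.  A mutator polymerase with asymmetric error rates between
the two members of such a pair therefore leaves an orientation-dependent
signature once a reporter is replicated in both directions: attributing
every substitution to synthesis of one declared strand (the reporter's
"transcribed" strand) and counting mispairs per orientation exposes the
strand the mutator actually copies.

This module enumerates the two hypotheses per substitution, tabulates
catalogs under the transcribed-strand-synthesis attribution, computes
complementary-mispair bias ratios and orientation contingency tests, and
scores the lagging-vs-leading assignment against in-vitro error-rate
priors.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from .geometry import (
    LocusGeometry,
    Orientation,
    StrandRoleMap,
    sense_carrier,
)

__all__ = [
    "COMPLEMENT",
    "GAP",
    "Mispair",
    "MispairHypothesisPair",
    "MutationRecord",
    "ClassifiedMutation",
    "MispairCountTable",
    "InVitroBiasPrior",
    "BiasRatio",
    "OrientationTestResult",
    "StrandAssignment",
    "NotClassifiableError",
    "DegenerateTableError",
    "MUTATION_CLASSES",
    "SUBSTITUTION_ROWS",
    "DELETION_ROWS",
    "ROW_MISPAIRS",
    "substitution_row",
    "enumerate_mispairs",
    "classify_transcribed_strand",
    "tabulate",
    "bias_ratio",
    "orientation_test",
    "assign_strand",
]

BASES = "ACGT"
COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}
GAP = "-"

#: Event classes of a 5-FOA-resistance catalog.  Only substitutions and
#: single-base deletions carry strand information; the rest are counted
#: but never strand-classified.
MUTATION_CLASSES = ("substitution", "del1", "ins1", "duplication", "deletion", "other")
CLASSIFIABLE = frozenset({"substitution", "del1"})


class NotClassifiableError(ValueError):
    """Record class carries no template:dNTP strand information."""


class DegenerateTableError(ValueError):
    """A 2x2 orientation table has an all-zero row or column."""


@dataclass(frozen=True, order=True)
class Mispair:
    """A template base paired with an incoming dNMP, or a skipped template base.

    ``incoming=None`` denotes a single-base deletion intermediate: the
    template base was skipped during synthesis (displayed ΔA..ΔC).
    """

    template: str
    incoming: str | None = None

    def __post_init__(self) -> None:
        if self.template not in BASES:
            raise ValueError(f"invalid template base {self.template!r}")
        if self.incoming is not None:
            if self.incoming not in BASES:
                raise ValueError(f"invalid incoming base {self.incoming!r}")
            if COMPLEMENT[self.template] == self.incoming:
                raise ValueError(
                    f"{self.template}:d{self.incoming} is a Watson-Crick pair, not a mispair"
                )

    @property
    def is_deletion(self) -> bool:
        return self.incoming is None

    def complement(self) -> "Mispair":
        """Mispair produced by the same event on the opposite strand."""
        if self.is_deletion:
            return Mispair(COMPLEMENT[self.template])
        return Mispair(COMPLEMENT[self.template], COMPLEMENT[self.incoming])

    def __str__(self) -> str:
        if self.is_deletion:
            return f"Δ{self.template}"
        return f"{self.template}:d{self.incoming}"

    @classmethod
    def parse(cls, text: str) -> "Mispair":
        text = text.strip()
        if text.startswith("Δ"):
            return cls(text[1:])
        if ":d" in text:
            template, incoming = text.split(":d", 1)
            return cls(template, incoming)
        raise ValueError(f"cannot parse mispair {text!r}")


#: Spectrum rows: six base-pair substitution classes (purine-first label)
#: and two single-base-deletion classes, each with its two complementary
#: mispairs in conventional display order.
SUBSTITUTION_ROWS = ("AT>GC", "GC>AT", "GC>TA", "AT>TA", "AT>CG", "GC>CG")
DELETION_ROWS = ("ΔAT", "ΔGC")
ALL_ROWS = SUBSTITUTION_ROWS + DELETION_ROWS

ROW_MISPAIRS: dict[str, tuple[Mispair, Mispair]] = {
    "AT>GC": (Mispair("A", "C"), Mispair("T", "G")),
    "GC>AT": (Mispair("G", "T"), Mispair("C", "A")),
    "GC>TA": (Mispair("G", "A"), Mispair("C", "T")),
    "AT>TA": (Mispair("A", "A"), Mispair("T", "T")),
    "AT>CG": (Mispair("A", "G"), Mispair("T", "C")),
    "GC>CG": (Mispair("G", "G"), Mispair("C", "C")),
    "ΔAT": (Mispair("A"), Mispair("T")),
    "ΔGC": (Mispair("G"), Mispair("C")),
}

_MISPAIR_ROW = {str(m): row for row, pair in ROW_MISPAIRS.items() for m in pair}


def substitution_row(ref: str, alt: str) -> str:
    """Canonical purine-first row label for a base-pair substitution.

    The label is strand-symmetric: (T->C) and (A->G) both map to AT>GC.
    """
    if ref not in BASES or alt not in BASES:
        raise ValueError(f"invalid substitution {ref!r}->{alt!r}")
    if ref == alt:
        raise ValueError(f"{ref}->{alt} is not a mutation")
    if ref in "AG":
        return f"{ref}{COMPLEMENT[ref]}>{alt}{COMPLEMENT[alt]}"
    return f"{COMPLEMENT[ref]}{ref}>{COMPLEMENT[alt]}{alt}"


@dataclass(frozen=True)
class MispairHypothesisPair:
    """The two candidate errors behind one base-pair substitution."""

    via_top: Mispair
    via_bottom: Mispair


def enumerate_mispairs(ref_top: str, alt_top: str) -> MispairHypothesisPair:
    """Enumerate both mispair hypotheses for a substitution given on the top strand.

    An error made while synthesizing the top strand copies the bottom
    strand, so its mispair is (bottom ref base):(d top alt base); the
    bottom-synthesis hypothesis is the complementary mispair.
    """
    if ref_top not in BASES or alt_top not in BASES:
        raise ValueError(f"invalid substitution {ref_top!r}->{alt_top!r}")
    if ref_top == alt_top:
        raise ValueError(f"{ref_top}->{alt_top} is not a mutation")
    via_top = Mispair(COMPLEMENT[ref_top], alt_top)
    return MispairHypothesisPair(via_top=via_top, via_bottom=via_top.complement())


@dataclass(frozen=True)
class MutationRecord:
    """One observed reporter mutation, reported on the reporter sense strand."""

    locus_id: str
    position: int  # 0-based reporter coordinate
    ref: str
    alt: str
    mclass: str
    orientation: Orientation
    strain: str = ""

    def __post_init__(self) -> None:
        if self.mclass not in MUTATION_CLASSES:
            raise ValueError(f"unknown mutation class {self.mclass!r}")
        if self.mclass == "substitution":
            if self.ref not in BASES or self.alt not in BASES:
                raise ValueError(
                    f"substitution requires ACGT ref/alt, got {self.ref!r}->{self.alt!r}"
                )
            if self.ref == self.alt:
                raise ValueError("substitution with ref == alt")
        elif self.mclass == "del1":
            if self.ref not in BASES or self.alt != GAP:
                raise ValueError(
                    f"del1 requires ACGT ref and gap alt, got {self.ref!r}->{self.alt!r}"
                )


@dataclass(frozen=True)
class ClassifiedMutation:
    """Attribution of a record under transcribed-strand synthesis."""

    row: str
    mispair: Mispair
    role: str  # "leading" | "lagging"


def classify_transcribed_strand(
    record: MutationRecord,
    roles: StrandRoleMap,
    locus: LocusGeometry,
    convention: str = "sense",
) -> ClassifiedMutation:
    """Attribute a record to an error during synthesis of the transcribed strand.

    Parameters
    ----------
    record
        Substitution or single-base deletion with ref/alt on the reporter
        sense strand.
    roles
        Genome-level leading/lagging assignment at the locus.
    convention
        What "transcribed strand" denotes.  ``"sense"`` (default): the
        hypothesis strand is the reporter sense strand, so the mispair is
        complement(ref):d(alt) — the convention that reproduces the
        observed T:dG excess for sense-strand A->G changes.
        ``"template"``: the strand used as the template for transcription,
        which flips both the mispair and the role.

    Returns
    -------
    ClassifiedMutation
        Row label, attributed mispair, and the replication role (leading
        or lagging) of the hypothesis strand in this orientation.

    Raises
    ------
    NotClassifiableError
        For insertions, duplications, larger deletions and complex events.
    """
    if convention not in ("sense", "template"):
        raise ValueError(f"unknown transcribed-strand convention {convention!r}")
    if record.mclass not in CLASSIFIABLE:
        raise NotClassifiableError(
            f"{record.mclass} records carry no mispair strand information"
        )
    carrier = sense_carrier(record.orientation, locus)
    synth = carrier if convention == "sense" else carrier.other
    role = roles.role_of(synth)
    if record.mclass == "substitution":
        if convention == "sense":
            mp = Mispair(COMPLEMENT[record.ref], record.alt)
        else:
            mp = Mispair(record.ref, COMPLEMENT[record.alt])
        row = substitution_row(record.ref, record.alt)
    else:  # del1
        template = COMPLEMENT[record.ref] if convention == "sense" else record.ref
        mp = Mispair(template)
        row = "ΔAT" if record.ref in "AT" else "ΔGC"
    return ClassifiedMutation(row=row, mispair=mp, role=role)


class MispairCountTable:
    """Counts per (spectrum row, mispair, orientation) plus unclassifiable events.

    ``orientation_role`` records the replication role of the hypothesis
    (transcribed) strand in each orientation, which downstream scoring
    needs to interpret the columns.
    """

    def __init__(
        self,
        hypothesis: str = "transcribed-strand synthesis",
        orientation_role: Mapping[str, str] | None = None,
    ) -> None:
        self.hypothesis = hypothesis
        self.orientation_role: dict[str, str] = dict(
            orientation_role or {"forward": "lagging", "reverse": "leading"}
        )
        self._counts: Counter = Counter()
        self.unclassified: Counter = Counter()  # (mclass, orientation) -> n

    @staticmethod
    def _okey(orientation: Orientation | str) -> str:
        return orientation.value if isinstance(orientation, Orientation) else str(orientation)

    def add(self, row: str, mispair: Mispair | str, orientation: Orientation | str, n: int = 1) -> None:
        if n < 0:
            raise ValueError("counts must be non-negative")
        self._counts[(row, str(mispair), self._okey(orientation))] += n

    def add_unclassified(self, mclass: str, orientation: Orientation | str, n: int = 1) -> None:
        self.unclassified[(mclass, self._okey(orientation))] += n

    def count(self, row: str, mispair: Mispair | str, orientation: Orientation | str) -> int:
        return self._counts[(row, str(mispair), self._okey(orientation))]

    def classified_total(self, orientation: Orientation | str) -> int:
        okey = self._okey(orientation)
        return sum(n for (_, _, o), n in self._counts.items() if o == okey)

    def unclassified_total(self, orientation: Orientation | str) -> int:
        okey = self._okey(orientation)
        return sum(n for (_, o), n in self.unclassified.items() if o == okey)

    @property
    def total_records(self) -> int:
        return sum(self._counts.values()) + sum(self.unclassified.values())

    def orientations(self) -> list[str]:
        return sorted({o for (_, _, o) in self._counts})

    def swapped_orientations(self) -> "MispairCountTable":
        """Mirror table with forward and reverse columns exchanged."""
        flip = {"forward": "reverse", "reverse": "forward"}
        out = MispairCountTable(self.hypothesis, self.orientation_role)
        for (row, mp, o), n in self._counts.items():
            out._counts[(row, mp, flip.get(o, o))] = n
        for (mclass, o), n in self.unclassified.items():
            out.unclassified[(mclass, flip.get(o, o))] = n
        return out

    def to_frame(self) -> pd.DataFrame:
        """Wide spectrum table: one line per (row, mispair), orientation columns."""
        lines = []
        for row in ALL_ROWS:
            for mp in ROW_MISPAIRS[row]:
                entry = {"mclass": row, "mispair": str(mp)}
                for o in ("forward", "reverse"):
                    entry[o] = self.count(row, mp, o)
                lines.append(entry)
        return pd.DataFrame(lines)

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# hypothesis: {self.hypothesis}\n")
            role = ",".join(f"{o}={r}" for o, r in sorted(self.orientation_role.items()))
            fh.write(f"# orientation_role: {role}\n")
            fh.write("# mclass\tmispair\torientation\tcount\n")
            for row in ALL_ROWS:
                for mp in ROW_MISPAIRS[row]:
                    for o in ("forward", "reverse"):
                        fh.write(f"{row}\t{mp}\t{o}\t{self.count(row, mp, o)}\n")
            for (mclass, o), n in sorted(self.unclassified.items()):
                fh.write(f"{mclass}\tNA\t{o}\t{n}\n")

    @classmethod
    def from_tsv(cls, path) -> "MispairCountTable":
        table = cls()
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#"):
                    body = line.lstrip("#").strip()
                    if body.startswith("hypothesis:"):
                        table.hypothesis = body.split(":", 1)[1].strip()
                    elif body.startswith("orientation_role:"):
                        table.orientation_role = dict(
                            kv.split("=") for kv in body.split(":", 1)[1].strip().split(",")
                        )
                    continue
                fields = line.split("\t")
                if len(fields) != 4:
                    raise ValueError(f"{path}:{lineno}: expected 4 tab-separated fields")
                row, mp, orientation, count = fields
                try:
                    n = int(count)
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: bad count {count!r}") from exc
                if mp == "NA":
                    table.add_unclassified(row, orientation, n)
                else:
                    if row not in ROW_MISPAIRS:
                        raise ValueError(f"{path}:{lineno}: unknown spectrum row {row!r}")
                    table.add(row, Mispair.parse(mp), orientation, n)
        return table


def tabulate(
    records: Iterable[MutationRecord],
    roles: StrandRoleMap,
    locus: LocusGeometry,
    convention: str = "sense",
) -> MispairCountTable:
    """Tabulate a catalog under transcribed-strand-synthesis attribution.

    Count conservation holds: classified + unclassifiable = catalog size.
    """
    records = list(records)
    orientation_role = {
        o.value: roles.role_of(
            sense_carrier(o, locus) if convention == "sense" else sense_carrier(o, locus).other
        )
        for o in Orientation
    }
    table = MispairCountTable(orientation_role=orientation_role)
    for record in records:
        try:
            cm = classify_transcribed_strand(record, roles, locus, convention)
        except NotClassifiableError:
            table.add_unclassified(record.mclass, record.orientation)
        else:
            table.add(cm.row, cm.mispair, record.orientation)
    return table


@dataclass(frozen=True)
class BiasRatio:
    """Fold ratio between the two complementary mispair counts of one row."""

    row: str
    orientation: str
    numerator: str
    denominator: str
    numerator_count: int
    denominator_count: int
    value: float  # inf when denominator 0 < numerator; nan when 0/0
    flag: str | None = None  # None | "infinite" | "undefined"


#: Complementary-pair member with the larger in-vitro error rate for the
#: polδ L612M-style prior; used as the default bias-ratio numerator.
DEFAULT_FAVORED = {
    "AT>GC": "T:dG",
    "GC>AT": "G:dT",
    "GC>TA": "C:dT",
    "AT>TA": "T:dT",
    "ΔAT": "ΔT",
    "ΔGC": "ΔG",
}


def bias_ratio(
    table: MispairCountTable,
    row: str,
    orientation: Orientation | str,
    numerator: Mispair | str | None = None,
) -> BiasRatio:
    """Fold ratio of one mispair count over its complement within a row.

    With ``numerator=None`` the member favored by the shipped in-vitro
    prior is used; rows with no prior preference require an explicit
    numerator.
    """
    if row not in ROW_MISPAIRS:
        raise ValueError(f"unknown spectrum row {row!r}")
    if numerator is None:
        try:
            numerator = DEFAULT_FAVORED[row]
        except KeyError:
            raise ValueError(
                f"no default numerator for row {row!r}; pass one explicitly"
            ) from None
    numerator = str(numerator)
    pair = {str(m) for m in ROW_MISPAIRS[row]}
    if numerator not in pair:
        raise ValueError(f"{numerator} is not a mispair of row {row}")
    (denominator,) = pair - {numerator}
    num = table.count(row, numerator, orientation)
    den = table.count(row, denominator, orientation)
    if den == 0:
        if num == 0:
            value, flag = math.nan, "undefined"
        else:
            value, flag = math.inf, "infinite"
    else:
        value, flag = num / den, None
    okey = orientation.value if isinstance(orientation, Orientation) else str(orientation)
    return BiasRatio(row, okey, numerator, denominator, num, den, value, flag)


@dataclass(frozen=True)
class OrientationTestResult:
    """Exact-conditional test of mispair attribution against orientation."""

    row: str
    table2x2: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_value: float
    haldane_corrected: bool
    degenerate: bool


def orientation_test(table: MispairCountTable, row: str) -> OrientationTestResult:
    """Two-sided exact conditional test on the 2x2 orientation x mispair table.

    Rows are orientations (forward, reverse); columns the two
    complementary mispairs.  The odds ratio is the sample odds ratio,
    with a Haldane-Anscombe +0.5 correction applied (and flagged) only
    when a zero cell is present.  An all-zero row or column yields a
    degenerate result (p = 1, odds ratio NaN).
    """
    if row not in ROW_MISPAIRS:
        raise ValueError(f"unknown spectrum row {row!r}")
    m1, m2 = ROW_MISPAIRS[row]
    a = table.count(row, m1, "forward")
    b = table.count(row, m2, "forward")
    c = table.count(row, m1, "reverse")
    d = table.count(row, m2, "reverse")
    cells = ((a, b), (c, d))
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        return OrientationTestResult(row, cells, math.nan, 1.0, False, True)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if 0 in (a, b, c, d):
        odds = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
        corrected = True
    else:
        odds = (a * d) / (b * c)
        corrected = False
    return OrientationTestResult(row, cells, odds, float(p), corrected, False)


@dataclass
class InVitroBiasPrior:
    """Relative error rates per mispair from in-vitro work on the orthologous mutant.

    Rates are dimensionless and only their within-pair ratios matter.  A
    prior with all complementary pairs equal carries no assignment power
    (``informative`` is False) and forces an indeterminate decision.
    """

    rates: dict[str, float]
    source: str = ""

    def __post_init__(self) -> None:
        clean = {}
        for key, rate in self.rates.items():
            rate = float(rate)
            if rate < 0:
                raise ValueError(f"negative prior rate for {key}")
            clean[str(Mispair.parse(key)) if isinstance(key, str) else str(key)] = rate
        self.rates = clean

    @property
    def informative(self) -> bool:
        for pair in ROW_MISPAIRS.values():
            r1, r2 = self.rates.get(str(pair[0])), self.rates.get(str(pair[1]))
            if r1 is not None and r2 is not None and r1 != r2:
                return True
        return False

    @classmethod
    def from_tsv(cls, path) -> "InVitroBiasPrior":
        rates: dict[str, float] = {}
        source = ""
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#"):
                    body = line.lstrip("#").strip()
                    if body.startswith("source:"):
                        source = body.split(":", 1)[1].strip()
                    continue
                fields = line.split("\t")
                if len(fields) != 2:
                    raise ValueError(f"{path}:{lineno}: expected 'mispair<TAB>rate'")
                try:
                    rates[fields[0]] = float(fields[1])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: bad rate {fields[1]!r}") from exc
        return cls(rates=rates, source=source)

    @classmethod
    def default(cls) -> "InVitroBiasPrior":
        from . import datafiles

        return cls.from_tsv(datafiles.invitro_prior_path())


@dataclass(frozen=True)
class StrandAssignment:
    """Log-odds score for 'mutator synthesizes the lagging strand'."""

    log_odds: float
    contributions: dict[str, float] = field(default_factory=dict)
    decision: str = "indeterminate"  # "lagging" | "leading" | "indeterminate"
    indeterminate_band: float = 2.0


def assign_strand(
    table: MispairCountTable,
    prior: InVitroBiasPrior,
    indeterminate_band: float = 2.0,
) -> StrandAssignment:
    """Score lagging- vs leading-strand synthesis by the mutator.

    For each spectrum row with complementary mispairs (m1, m2) and prior
    rates (r1, r2), the probability that a true mutator error is m1 is
    p = r1/(r1+r2).  If the mutator copies the strand whose role matches
    the hypothesis strand of an orientation, attributed counts follow
    Binomial(n, p) on m1; otherwise attribution flips the labels and they
    follow Binomial(n, 1-p).  The per-row log-likelihood difference
    reduces to

        contribution = log(p/(1-p)) * sum_o s_o * (k_o(m1) - k_o(m2)),

    where s_o is +1 for orientations whose hypothesis strand is lagging
    and -1 otherwise.  Positive total log-odds favor a lagging-strand
    mutator.  Decisions inside ``|log_odds| < indeterminate_band``
    (default 2, about 7.4:1 odds) are reported indeterminate.
    """
    eps = 1e-6
    log_odds = 0.0
    contributions: dict[str, float] = {}
    for row in ALL_ROWS:
        m1, m2 = ROW_MISPAIRS[row]
        r1 = prior.rates.get(str(m1))
        r2 = prior.rates.get(str(m2))
        if r1 is None or r2 is None or (r1 == 0 and r2 == 0):
            continue
        p = min(max(r1 / (r1 + r2), eps), 1 - eps)
        weight = math.log(p / (1 - p))
        if weight == 0.0:
            continue
        diff = 0.0
        for o, role in table.orientation_role.items():
            sign = 1.0 if role == "lagging" else -1.0
            diff += sign * (table.count(row, m1, o) - table.count(row, m2, o))
        contribution = weight * diff
        if contribution != 0.0 or diff != 0.0:
            contributions[row] = contribution
        log_odds += contribution
    if log_odds > indeterminate_band:
        decision = "lagging"
    elif log_odds < -indeterminate_band:
        decision = "leading"
    else:
        decision = "indeterminate"
    return StrandAssignment(
        log_odds=log_odds,
        contributions=contributions,
        decision=decision,
        indeterminate_band=indeterminate_band,
    )
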