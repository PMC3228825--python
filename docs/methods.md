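# Methods

`forkasym` infers which nascent strand of the replication fork a
replicative DNA polymerase synthesizes, from three kinds of evidence
available in fission-yeast reporter experiments: orientation-dependent
mutation spectra of a mutator polymerase, fluctuation-assay mutation
rates, and strand-specific ribonucleotide (rNMP) incorporation profiles.
This note records the models, the parameters that matter, the numerical
choices, and what the synthetic data do and do not establish.

## Replication geometry

A reporter locus adjacent to a highly efficient origin is replicated by a
single fork whose direction follows from which side of the origin the
locus lies on; origin firing on the declared side is treated as 100%
efficient (forks arriving from other origins are neglected; the fraction
of such forks at an efficient-origin locus is not quantified
experimentally and is taken as zero).  "Top" strand means the strand
written 5'→3' left-to-right in the reference FASTA.  Because nascent DNA
grows 5'→3', a leftward fork's nascent leading strand is the bottom
strand and a rightward fork's is the top strand; this single rule drives
both the mispair attribution and the rNMP model.  The fork direction at
the modelled locus (leftward, origin to the right) enters as one
configuration datum — the package does not process gel evidence.

Coordinates are 0-based half-open internally; TSV readers accept a
`coordinate_base` flag (default 1) because published reporter maps are
1-based.

## Mispair classification

Each base-pair substitution is compatible with exactly two template:dNTP
errors, one per synthesized strand: for a change whose top-strand reading
is ref→alt, the top-synthesis hypothesis is complement(ref):d(alt) and
the bottom-synthesis hypothesis is its full complement.  Catalogs are
tabulated under the *transcribed-strand-synthesis* attribution: every
substitution (and single-base deletion, as a skipped-template ΔN) is
assigned the mispair it would represent had the error occurred while the
reporter's transcribed strand was synthesized.  In the forward construct
that strand is replicated as the lagging strand, in the reverse construct
as the leading strand, so a strand-biased mutator shows complementary
count asymmetries in the two orientations.

Which physical strand "transcribed strand" denotes (the mRNA-like sense
strand or its template) is a convention; the package defaults to the
sense strand because that convention reproduces the anchoring 12.5-fold
T:dG excess for sense-strand A→G records, and a `convention="template"`
flag flips mispair labels and roles exactly.

Downstream statistics:

* **Bias ratios** — within a mutation class, the count of one mispair
  over its complement.  Zero denominators are reported as
  infinite/undefined flags; no pseudo-counts are applied.
* **Orientation tests** — two-sided exact conditional (Fisher) test on
  the 2×2 orientation × mispair table, via `scipy.stats.fisher_exact`;
  the sample odds ratio gets a Haldane–Anscombe +0.5 correction only
  when a zero cell exists, and is then flagged.  Degenerate tables
  (all-zero row or column) return p = 1 with an explicit flag.
* **Strand assignment score** — for each class with complementary
  mispairs (m₁, m₂) and in-vitro prior rates (r₁, r₂), a true mutator
  error is m₁ with probability p = r₁/(r₁+r₂).  Under
  "mutator-on-lagging", attributed counts in an orientation whose
  transcribed strand is lagging follow Binomial(n, p) on m₁, and the
  mirrored law under "mutator-on-leading".  The log-likelihood ratio
  reduces to log(p/(1−p)) · Σ_o s_o (k_o(m₁) − k_o(m₂)) with s_o = ±1 by
  the orientation's role.  Positive totals favor a lagging-strand
  mutator.  Calls inside |log-odds| < 2 (≈7.4:1 odds) are reported
  indeterminate; the band is configurable and deliberately conservative.
  Prior rates are clipped to p ∈ [10⁻⁶, 1−10⁻⁶] so a zero rate cannot
  produce an infinite single-class weight.  The score assumes the
  catalog is mutator-dominated; applied to a non-mutator spectrum it can
  produce weak spurious calls and should be read only alongside the
  orientation tests.

The shipped in-vitro prior (polδ L612M relative error rates) is a
user-editable TSV, not hard-coded truth: the published values are
approximate and only within-pair ratios enter the score.

## Fluctuation analysis

Mutation rates are estimated by the Lea–Coulson method of the median:
the expected mutations per culture m solves r̃/m − ln m = 1.24, where r̃
is the median mutant count divided by the plating fraction.  The left
side is strictly decreasing in m, so the root is unique; it is found by
log-expanding bracketing plus Brent's method to relative tolerance
1e-10.  The rate per cell division is m/Nt under the standard
approximation (cumulative divisions ≈ Nt).  Nt is not part of the count
data and must be supplied; simulation work uses 2×10⁷ viable cells per
5 ml culture as a stated assumption.  Edge cases: a median of zero with
some positive cultures falls back to the P₀ method
(m = −ln fraction-of-mutant-free-cultures); all-zero assays are censored
and carry only an upper bound (ln 2 / Nt scale), never a point estimate.
Confidence intervals are percentile bootstrap over cultures (10⁴
resamples by default); a standard-deviation-across-assays mode is not
needed because replicate assays are first-class in the analysis scripts.

The synthetic generator uses discrete-generation growth: every cell
divides each generation, new mutations are Poisson(μ × wild-type
divisions that generation), and each new mutant lineage doubles in every
*subsequent* generation (a replication error makes one mutant daughter).
Non-power-of-two Nt/N0 is handled by pro-rating a final partial
generation.  For power-of-two growth the expected mutant count is
μ·Nt·G/2 (G = log₂(Nt/N0)) while the expected number of mutation events
is μ·(Nt−N0), the quantity the estimator targets.  Quantizing clone
sizes to powers of two places the birth of each clone at a generation
boundary — the floor of the continuous-growth clone size — so the median
count runs ~20% below the continuous Luria–Delbrück value the 1.24
constant is calibrated to.  Consequences, all computed by the tests and
scripts rather than asserted: single-rate recovery at μ = 4.5×10⁻⁶ is
within ±30% (factor ≈0.82); the median estimated mutant/wild-type fold
at true rates 4.5×10⁻⁶ vs 4.5×10⁻⁸ is ≈78 against a true 100, within the
±25% acceptance band.  On counts drawn from the continuous
Luria–Delbrück model itself the estimator is nearly unbiased, which the
suite checks separately.

## rNMP incorporation and alkaline fragmentation

Each nucleotide of each nascent strand independently carries an rNMP
with a role-dependent rate (leading vs lagging, the role switching at
the origin), and each rNMP survives repair with probability
1 − repair_efficiency (repair_efficiency 1 ≈ RNase-H2-proficient, 0 =
rnh201Δ).  Alkaline treatment cuts at every retained rNMP; optional
restriction sites add fixed cuts.  Fragment lengths per strand always
sum to the region length (the labile nucleotide starts the downstream
fragment), and fragment count equals retained rNMPs + 1 + fixed cuts.

Gel physics is not modelled.  A strand-specific probe is summarized by
the lengths of fragments overlapping its window, weighted by the overlap
(hybridization signal is proportional to shared length): the
length-weighted median and the signal fraction below a size threshold.
The alkali-sensitive strand on a flank is the one whose weighted median
is below `threshold_ratio` (default 0.25, i.e. a 4-fold difference) times
the other strand's; the call is therefore invariant under uniform
scaling of both rates.  A "both" call requires an absolute shortness
threshold and is off by default.

Absolute incorporation rates for the fission-yeast mutant are not
published; defaults borrow order of magnitude from budding-yeast work:
retained density 10⁻³/nt on the mutant polymerase's strand in the
repair-null, 10⁻⁴/nt background on the other strand, and 2.5×10⁻⁴/nt on
both strands for a wild-type polymerase.  The default study region is
400 kb centred on the origin with one probe pair per strand per flank
(windows keep a 10%-of-region margin from origin and edges).  At these
densities each window overlaps enough fragments that the 4-fold ratio
rule neither misses the 10-fold mutant asymmetry nor fires on equal-rate
profiles across seeds; smaller regions (tens of kb) leave so few
fragments per window that the median ratio becomes noisy.

## Synthetic catalogs

Each synthetic 5-FOA-resistant isolate carries exactly one causal
mutation.  Classes are drawn from a mix defaulting to the observed
mutator class proportions (substitutions 36%, 1-base deletions 19%,
1-base insertions 3%, duplications 20%, deletions 7%, other 15%);
substitutions and single-base deletions draw a mispair proportional to
the mutator's rates and are placed uniformly over compatible template
sites on the strand the mutator synthesizes, then reported in the
reporter sense-strand convention of their orientation.  Ground truth
(true mispair, synthesized strand, genome position) is recorded per
record, and identical seeds give byte-identical TSVs.

What the generator does *not* emulate, hence what passing recovery tests
do not show about real data: codon-level selection for loss of reporter
function (every mutation is assumed resistance-conferring), sequence-
context (nearest-neighbour) error modulation, mutational hotspots, and
mismatch-repair spectrum distortion (the classifier never models repair;
an escape-probability hook exists only in the generator's rates, and
real spectra in repair-proficient cells are filtered by MutS-affinity
differences that can mask bias).  Duplication/deletion mechanisms are
carried as counts only.

## Numerical and interface choices

* Root solving: Brent on a monotone function, bracket [10⁻⁶, 10⁶]
  expanded ×10³ per side as needed.
* Exact-test ties: delegated to `scipy.stats.fisher_exact`; the suite
  cross-checks every 2×2 table with total ≤ 50 against an
  integer-arithmetic enumeration oracle, where tie detection is exact.
* Zero handling is explicit everywhere: flags (infinite/undefined,
  Haldane-corrected, censored, degenerate) rather than silent
  pseudo-counts.
* All generators take explicit seeds; CLI runs write a JSON manifest
  echoing configuration and seeds.
* Problem sizes in the shipped analyses (500 replicate assays, 200
  catalogs per role, 20 rNMP seeds over 400 kb) were chosen so sampling
  error is small relative to the effects being measured.

## Known limitations

* The strand-assignment score treats classes independently and ignores
  overdispersion between isolates; its log-odds are well separated from
  zero in simulations but should not be read as calibrated posterior
  odds for real catalogs.
* The fluctuation generator's generation-quantized clone sizes bias the
  median method ~20% low at mutator-scale m (see above); comparisons of
  two rates estimated the same way are affected much less than absolute
  rates.
* The rNMP model is i.i.d. per nucleotide with no hotspots, no
  topoisomerase-1-dependent processing, and no Okazaki-fragment
  structure on the lagging strand.
* The in-vitro prior values are approximate transcriptions; analyses
  that depend on more than within-pair rank order should re-derive them
  from primary data.
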