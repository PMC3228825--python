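import numpy as np
import pytest

import forkasym as fa
from forkasym.geometry import GenomeStrand
from forkasym.rnmp import (
    DEFAULT_RATE_BACKGROUND,
    DEFAULT_RATE_LEADING_MUTANT,
    DEFAULT_RATE_WILDTYPE,
    MissingProbeCoverageError,
    ProbeWindow,
    RnmpModel,
    default_probe_windows,
)

STRANDS = (GenomeStrand.TOP, GenomeStrand.BOTTOM)


@pytest.fixture(scope="module")
def origin_region() -> fa.LocusGeometry:
    """Region spanning both flanks of the origin (probe layout of the assay)."""
    return fa.LocusGeometry(0, 400_000, 200_000)


@pytest.fixture(scope="module")
def one_sided_region() -> fa.LocusGeometry:
    """Region entirely left of the origin: single leftward fork, leading = bottom."""
    return fa.LocusGeometry(0, 100_000, 150_000)


def _calls(geom, rate_leading, rate_lagging, repair, seed):
    model = RnmpModel(geom, rate_leading, rate_lagging, repair)
    profile = fa.simulate_rnmp(model, seed=seed)
    signals = [fa.probe_signal(profile, p) for p in default_probe_windows(geom)]
    return fa.call_sensitive_strand(signals, origin_pos=geom.origin_pos)


class TestSimulateRnmp:
    def test_zero_rates_leave_one_full_length_fragment_per_strand(self, origin_region):
        profile = fa.simulate_rnmp(RnmpModel(origin_region, 0.0, 0.0, 0.0), seed=1)
        for strand in STRANDS:
            assert profile.positions[strand].size == 0
            assert list(profile.fragment_lengths(strand)) == [origin_region.length]

    def test_complete_repair_equals_zero_rate_outcome(self, origin_region):
        profile = fa.simulate_rnmp(
            RnmpModel(origin_region, 1e-3, 1e-3, 1.0), seed=1
        )
        for strand in STRANDS:
            assert profile.positions[strand].size == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_fragment_lengths_conserve_region_length(self, origin_region, seed):
        profile = fa.simulate_rnmp(
            RnmpModel(origin_region, 1e-3, 1e-4, 0.0), seed=seed
        )
        for strand in STRANDS:
            assert profile.fragment_lengths(strand).sum() == origin_region.length

    @pytest.mark.parametrize("seed", range(5))
    def test_fragment_count_is_retained_rnmps_plus_one(self, origin_region, seed):
        profile = fa.simulate_rnmp(
            RnmpModel(origin_region, 5e-4, 5e-5, 0.0), seed=seed
        )
        for strand in STRANDS:
            assert (
                profile.fragment_lengths(strand).size
                == profile.positions[strand].size + 1
            )

    def test_restriction_cut_sites_add_fragments(self, origin_region):
        cuts = (100_000, 300_000)
        profile = fa.simulate_rnmp(
            RnmpModel(origin_region, 0.0, 0.0, 0.0), seed=0, cut_sites=cuts
        )
        for strand in STRANDS:
            assert profile.fragment_lengths(strand).size == len(cuts) + 1
            assert profile.fragment_lengths(strand).sum() == origin_region.length

    def test_mean_fragment_length_matches_geometric_spacing(self, one_sided_region):
        """At per-nucleotide nick rate p, inter-nick spacing is geometric with
        mean 1/p; the realized mean fragment length agrees within 5%."""
        rate = 1e-3
        model = RnmpModel(one_sided_region, rate_leading=rate, rate_lagging=0.0, repair_efficiency=0.0)
        means = []
        for seed in range(20):
            profile = fa.simulate_rnmp(model, seed=seed)
            means.append(profile.fragment_lengths(GenomeStrand.BOTTOM).mean())
        assert np.mean(means) == pytest.approx(1 / rate, rel=0.05)

    def test_same_seed_reproduces_positions(self, origin_region):
        model = RnmpModel(origin_region, 1e-3, 1e-4, 0.0)
        p1 = fa.simulate_rnmp(model, seed=9)
        p2 = fa.simulate_rnmp(model, seed=9)
        for strand in STRANDS:
            assert np.array_equal(p1.positions[strand], p2.positions[strand])

    def test_invalid_rates_rejected(self, origin_region):
        with pytest.raises(ValueError):
            RnmpModel(origin_region, 1.5, 0.0, 0.0)


class TestProbeSignal:
    def test_null_profile_reports_region_length(self, origin_region):
        profile = fa.simulate_rnmp(RnmpModel(origin_region, 0.0, 0.0, 0.0), seed=0)
        probe = default_probe_windows(origin_region)[0]
        sig = fa.probe_signal(profile, probe)
        assert sig.median_detected_length == origin_region.length
        assert sig.fraction_below_threshold == 0.0

    def test_heavily_nicked_strand_reads_short(self, one_sided_region):
        rate = 1e-3
        profile = fa.simulate_rnmp(
            RnmpModel(one_sided_region, rate, 0.0, 0.0), seed=4
        )
        probe_short = ProbeWindow(20_000, 80_000, GenomeStrand.BOTTOM, "B")
        probe_long = ProbeWindow(20_000, 80_000, GenomeStrand.TOP, "A")
        short = fa.probe_signal(profile, probe_short)
        long = fa.probe_signal(profile, probe_long)
        # length-weighted median of 1/p-scale fragments vs intact strand
        assert short.median_detected_length < 5 / rate
        assert long.median_detected_length == one_sided_region.length
        assert short.fraction_below_threshold > 0.9

    def test_opposite_strand_probes_at_same_interval_are_independent(self, origin_region):
        profile = fa.simulate_rnmp(RnmpModel(origin_region, 1e-3, 0.0, 0.0), seed=2)
        a = fa.probe_signal(profile, ProbeWindow(40_000, 160_000, GenomeStrand.TOP, "A"))
        b = fa.probe_signal(profile, ProbeWindow(40_000, 160_000, GenomeStrand.BOTTOM, "B"))
        assert a.median_detected_length != b.median_detected_length

    def test_probe_outside_region_rejected(self, origin_region):
        profile = fa.simulate_rnmp(RnmpModel(origin_region, 0.0, 0.0, 0.0), seed=0)
        with pytest.raises(ValueError):
            fa.probe_signal(profile, ProbeWindow(390_000, 410_000, GenomeStrand.TOP, "X"))


class TestCallSensitiveStrand:
    @pytest.mark.parametrize("seed", range(10))
    def test_leading_strand_mutant_without_repair_calls_bottom_left_top_right(
        self, origin_region, seed
    ):
        calls = _calls(
            origin_region,
            DEFAULT_RATE_LEADING_MUTANT,
            DEFAULT_RATE_BACKGROUND,
            0.0,
            seed,
        )
        assert calls == {"left": "bottom", "right": "top"}

    @pytest.mark.parametrize("seed", range(5))
    def test_equal_rates_call_nothing(self, origin_region, seed):
        calls = _calls(
            origin_region, DEFAULT_RATE_WILDTYPE, DEFAULT_RATE_WILDTYPE, 0.0, seed
        )
        assert calls == {"left": "none", "right": "none"}

    def test_complete_repair_calls_nothing(self, origin_region):
        calls = _calls(
            origin_region, DEFAULT_RATE_LEADING_MUTANT, DEFAULT_RATE_BACKGROUND, 1.0, 3
        )
        assert calls == {"left": "none", "right": "none"}

    @pytest.mark.parametrize("seed", range(5))
    def test_lagging_elevation_mirrors_the_call(self, origin_region, seed):
        calls = _calls(
            origin_region,
            DEFAULT_RATE_BACKGROUND,
            DEFAULT_RATE_LEADING_MUTANT,
            0.0,
            seed,
        )
        assert calls == {"left": "top", "right": "bottom"}

    def test_call_invariant_under_uniform_rate_scaling(self, origin_region):
        for scale in (0.5, 2.0):
            calls = _calls(
                origin_region,
                DEFAULT_RATE_LEADING_MUTANT * scale,
                DEFAULT_RATE_BACKGROUND * scale,
                0.0,
                7,
            )
            assert calls == {"left": "bottom", "right": "top"}

    def test_missing_strand_probe_raises(self, origin_region):
        profile = fa.simulate_rnmp(
            RnmpModel(origin_region, 1e-3, 1e-4, 0.0), seed=0
        )
        probes = [p for p in default_probe_windows(origin_region) if p.label != "B"]
        signals = [fa.probe_signal(profile, p) for p in probes]
        with pytest.raises(MissingProbeCoverageError):
            fa.call_sensitive_strand(signals, origin_pos=origin_region.origin_pos)
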