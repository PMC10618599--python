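import pytest
from scipy import stats

import strngs
from strngs import mixture, profiler, repeat_caller, simulate
from strngs.repeats import RepeatLength as RL


@pytest.fixture(scope="module")
def mix_locus():
    return simulate.make_locus("MIX1", "TATC", seed=31, reference_repeat_count=14)


@pytest.fixture(scope="module")
def mix_panel(mix_locus):
    return strngs.Panel(species="mix", loci=(mix_locus,))


def reference_profile(name, alleles, locus, panel, seed, n=20000, stutter=None):
    spec = simulate.single_sample(
        [locus],
        {locus.name: [(RL.coerce(a), 1) for a in alleles]},
        n,
        stutter=stutter or simulate.StutterModel(),
        seed=seed,
    )
    reads = simulate.simulate_reads(spec)
    result = repeat_caller.process_records((r.sequence for r in reads), panel)
    return profiler.build_sample_profile(name, result.calls_by_locus, panel)


def mixed_profiles_for(locus, panel, dilution, n, stutter, seed):
    spec = simulate.two_component_mixture(locus, [13, 14], [15, 16], dilution, n, stutter, seed)
    reads = simulate.simulate_reads(spec)
    result = repeat_caller.process_records((r.sequence for r in reads), panel)
    return {locus.name: profiler.tabulate(locus.name, result.calls_by_locus[locus.name])}


class TestInformativeAlleles:
    def test_longer_minor_alleles_with_repeat_offsets(self, mix_locus, mix_panel):
        major = reference_profile("major", [13, 14], mix_locus, mix_panel, 1)
        minor = reference_profile("minor", [15, 16], mix_locus, mix_panel, 2)
        informative = mixture.informative_alleles(major, minor, mix_panel)
        assert [(str(i.length), i.offset_bp) for i in informative] == [("15", 4), ("16", 8)]
        assert all(not i.stutter_colliding for i in informative)
        assert all(i.dose == pytest.approx(0.5, abs=0.02) for i in informative)

    def test_identical_profiles_yield_empty_list(self, mix_locus, mix_panel):
        major = reference_profile("major", [13, 14], mix_locus, mix_panel, 1)
        twin = reference_profile("twin", [13, 14], mix_locus, mix_panel, 3)
        assert mixture.informative_alleles(major, twin, mix_panel) == []

    def test_minor_allele_at_minus_one_repeat_is_stutter_colliding(self, mix_locus, mix_panel):
        major = reference_profile("major", [13, 14], mix_locus, mix_panel, 1)
        minor = reference_profile("minor", [12, 16], mix_locus, mix_panel, 4)
        informative = mixture.informative_alleles(major, minor, mix_panel)
        by_length = {str(i.length): i for i in informative}
        assert by_length["12"].stutter_colliding and by_length["12"].offset_bp == -4
        assert not by_length["16"].stutter_colliding


class TestEstimateMinorFraction:
    def test_one_to_one_mixture_estimates_half(self, mix_locus, mix_panel):
        major = reference_profile("major", [13, 14], mix_locus, mix_panel, 1)
        minor = reference_profile("minor", [15, 16], mix_locus, mix_panel, 2)
        informative = mixture.informative_alleles(major, minor, mix_panel)
        mixed = mixed_profiles_for(mix_locus, mix_panel, 1, 40000, simulate.StutterModel(), 7)
        result = mixture.estimate_minor_fraction(mixed, informative)
        lo, hi = result.confidence_interval
        assert lo <= 0.5 <= hi
        assert result.minor_fraction_estimate == pytest.approx(0.5, abs=0.02)

    def test_pure_major_sample_not_detected(self, mix_locus, mix_panel):
        major = reference_profile("major", [13, 14], mix_locus, mix_panel, 1)
        minor = reference_profile("minor", [15, 16], mix_locus, mix_panel, 2)
        informative = mixture.informative_alleles(major, minor, mix_panel)
        spec = simulate.single_sample(
            [mix_locus], {mix_locus.name: [(RL(13), 1), (RL(14), 1)]}, 20000, seed=9
        )
        reads = simulate.simulate_reads(spec)
        result = repeat_caller.process_records((r.sequence for r in reads), mix_panel)
        mixed = {mix_locus.name: profiler.tabulate(mix_locus.name, result.calls_by_locus[mix_locus.name])}
        est = mixture.estimate_minor_fraction(mixed, informative)
        assert est.pooled_fraction == 0.0
        assert mixture.detect_contamination(est) == "not-detected"

    def test_deep_dilution_within_binomial_ci(self, mix_locus, mix_panel):
        """1:200 mixture at high depth: the pooled estimate's CI covers the
        true minor fraction (binomial sampling oracle)."""
        major = reference_profile("major", [13, 14], mix_locus, mix_panel, 1)
        minor = reference_profile("minor", [15, 16], mix_locus, mix_panel, 2)
        informative = mixture.informative_alleles(major, minor, mix_panel)
        mixed = mixed_profiles_for(mix_locus, mix_panel, 200, 100_000, simulate.StutterModel(), 11)
        result = mixture.estimate_minor_fraction(mixed, informative)
        lo, hi = result.confidence_interval
        assert lo <= 1 / 201 <= hi

    def test_zero_informative_alleles_is_undetermined(self):
        result = mixture.estimate_minor_fraction({}, [])
        assert result.undetermined
        assert result.warnings


class TestDetection:
    def test_zero_informative_reads_not_detected(self):
        result = mixture.estimate_minor_fraction({}, [])
        assert mixture.detect_contamination(result) == "not-detected"

    def test_rule_thresholds_are_echoed(self, mix_locus, mix_panel):
        major = reference_profile("major", [13, 14], mix_locus, mix_panel, 1)
        minor = reference_profile("minor", [15, 16], mix_locus, mix_panel, 2)
        informative = mixture.informative_alleles(major, minor, mix_panel)
        mixed = mixed_profiles_for(mix_locus, mix_panel, 10, 5000, simulate.StutterModel(), 5)
        result = mixture.estimate_minor_fraction(mixed, informative)
        rule = mixture.DetectionRule(min_frac=0.01, min_reads=5)
        assert mixture.detect_contamination(result, rule) == "detected"
        assert result.rule == rule
        assert result.supporting

    def test_observed_fractions_track_expected_across_dilution_series(
        self, mix_locus, mix_panel
    ):
        """Across the 1:1 .. 1:1000 dilution series, pooled minor-fraction
        estimates regress on the expected fractions with slope ~1."""
        stutter = simulate.StutterModel(0.04, 1.0, 0.0005, 0.0)
        major = reference_profile("major", [13, 14], mix_locus, mix_panel, 1)
        minor = reference_profile("minor", [15, 16], mix_locus, mix_panel, 2)
        informative = mixture.informative_alleles(major, minor, mix_panel)
        dilutions = [1, 5, 10, 20, 100, 200, 1000]
        expected, observed = [], []
        for seed, dilution in enumerate(dilutions):
            mixed = mixed_profiles_for(mix_locus, mix_panel, dilution, 50_000, stutter, 100 + seed)
            result = mixture.estimate_minor_fraction(mixed, informative)
            expected.append(1 / (1 + dilution))
            observed.append(result.minor_fraction_estimate)
        slope = stats.linregress(expected, observed).slope
        assert 0.9 <= slope <= 1.1

    def test_detection_is_monotone_in_dilution(self, mix_locus, mix_panel):
        """If a 1:200 mixture is detected, every less dilute mixture is too
        (same depth, default rule); checked over seeds with <=1 violation
        tolerated for sampling noise."""
        stutter = simulate.StutterModel(0.04, 1.0, 0.0005, 0.0)
        major = reference_profile("major", [13, 14], mix_locus, mix_panel, 1)
        minor = reference_profile("minor", [15, 16], mix_locus, mix_panel, 2)
        informative = mixture.informative_alleles(major, minor, mix_panel)
        dilutions = [20, 100, 200]
        violations = 0
        for seed in range(10):
            decisions = []
            for dilution in dilutions:
                mixed = mixed_profiles_for(
                    mix_locus, mix_panel, dilution, 30_000, stutter, 200 + 10 * seed + dilution
                )
                result = mixture.estimate_minor_fraction(mixed, informative)
                decisions.append(mixture.detect_contamination(result) == "detected")
            # once detection is lost at some dilution it must not reappear deeper
            violations += any(
                later and not earlier
                for earlier, later in zip(decisions, decisions[1:])
            )
        assert violations <= 1
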