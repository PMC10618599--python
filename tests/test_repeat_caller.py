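import random
from dataclasses import replace

import pytest

import strngs
from strngs import simulate
from strngs.repeat_caller import (
    RepeatCall,
    ScanFailure,
    assign_read,
    process_records,
    scan_read,
)
from strngs.repeats import RepeatLength, reverse_complement

from conftest import clean_read


def motif_count_oracle(span, motif):
    """Brute force: longest run of the motif (whole units + leftover bases)
    by exhaustive scan of every start offset in the span."""
    best = (0, 0)
    for start in range(len(span) + 1):
        i, whole = start, 0
        while span[i : i + len(motif)] == motif:
            i += len(motif)
            whole += 1
        rem = 0
        while rem < len(motif) - 1 and span[i + rem : i + rem + 1] == motif[rem]:
            rem += 1
        best = max(best, (whole, rem))
    return RepeatLength(*best)


class TestScanRead:
    def test_exact_multiple_of_the_motif(self, tatc_locus):
        call = scan_read(clean_read(tatc_locus, 10), tatc_locus)
        assert isinstance(call, RepeatCall)
        assert call.repeat_length == RepeatLength(10)
        assert call.orientation == "forward"

    def test_partial_repeat_called_as_microvariant(self, tatc_locus):
        # corrected inter-anchor distance 46 at a 4-bp motif -> 11.2
        call = scan_read(clean_read(tatc_locus, "11.2"), tatc_locus)
        assert call.repeat_length == RepeatLength(11, 2)
        assert str(call.repeat_length) == "11.2"

    def test_snp_trigger_adds_exactly_the_increment(self, panels):
        spec = panels["human"]["D13S317"]
        parts = simulate.locus_building_blocks(spec)
        base = parts.left + parts.unit * 11
        ref_read = base + "AATCAATCATC" + parts.right
        var_read = base + "TATCAATCATC" + parts.right
        ref_call = scan_read(ref_read, spec)
        var_call = scan_read(var_read, spec)
        assert not ref_call.snp_applied and var_call.snp_applied
        assert var_call.repeat_length.whole - ref_call.repeat_length.whole == 1

    def test_reverse_complement_read_gives_same_length(self, tatc_locus):
        fwd = scan_read(clean_read(tatc_locus, 10), tatc_locus)
        rev = scan_read(clean_read(tatc_locus, 10, "reverse-complement"), tatc_locus)
        assert rev.repeat_length == fwd.repeat_length
        assert rev.orientation == "reverse-complement"

    def test_missing_end_anchor_is_a_no_call(self, tatc_locus):
        parts = simulate.locus_building_blocks(tatc_locus)
        read = parts.left + parts.unit * 10  # no right flank at all
        assert scan_read(read, tatc_locus) is ScanFailure.NO_CALL

    def test_duplicated_anchor_discards_read_as_ambiguous(self, tatc_locus):
        read = clean_read(tatc_locus, 10) + tatc_locus.start_anchor
        assert scan_read(read, tatc_locus) is ScanFailure.AMBIGUOUS_ANCHORS

    def test_span_shorter_than_bp_modifier_is_malformed(self, tatc_locus):
        spec = replace(tatc_locus, reference_sequence="", bp_modifier=50)
        read = clean_read(tatc_locus, 2)  # 8 bp span < 50 bp modifier
        assert scan_read(read, spec) is ScanFailure.MALFORMED

    def test_n_bases_never_match_an_anchor(self, tatc_locus):
        read = clean_read(tatc_locus, 10)
        i = read.index(tatc_locus.start_anchor)
        broken = read[:i] + "N" + read[i + 1 :]
        assert scan_read(broken, tatc_locus) is ScanFailure.NO_CALL

    def test_strand_invariance_on_random_reads(self, tatc_locus):
        rng = random.Random(42)
        for _ in range(1000):
            length = RepeatLength(rng.randrange(0, 25), rng.randrange(0, 4))
            read = clean_read(tatc_locus, length)
            if rng.random() < 0.3:  # occasionally corrupt a random base
                j = rng.randrange(len(read))
                read = read[:j] + rng.choice("ACGT") + read[j + 1 :]
            fwd = scan_read(read, tatc_locus)
            rev = scan_read(reverse_complement(read), tatc_locus)
            if isinstance(fwd, RepeatCall):
                assert isinstance(rev, RepeatCall)
                assert rev.repeat_length == fwd.repeat_length
            else:
                assert rev is fwd

    def test_inserting_one_unit_increments_whole_by_one(self, tatc_locus):
        for n in range(0, 20):
            call = scan_read(clean_read(tatc_locus, n), tatc_locus)
            assert call.repeat_length == RepeatLength(n)

    def test_bp_modifier_shifts_corrected_distance_exactly(self, tatc_locus):
        read = clean_read(tatc_locus, 10)
        for extra in range(0, 8):
            spec = replace(
                tatc_locus, reference_sequence="", bp_modifier=tatc_locus.bp_modifier + extra
            )
            call = scan_read(read, spec)
            assert call.repeat_length.total_bp(4) == 40 - extra

    def test_oracle_equivalence_on_error_free_reads(self, tatc_locus):
        rng = random.Random(7)
        for _ in range(200):
            length = RepeatLength(rng.randrange(1, 30), rng.randrange(0, 4))
            call = scan_read(clean_read(tatc_locus, length), tatc_locus)
            assert call.repeat_length == motif_count_oracle(call.span_sequence, "TATC")
            assert call.repeat_length == length


class TestAssignRead:
    def test_multiplexed_read_assigned_to_its_locus(self, six_locus_panel):
        read = clean_read(six_locus_panel["D8S1179"], 13)
        assignment = assign_read(read, six_locus_panel)
        assert assignment.status == "assigned"
        assert assignment.call.locus == "D8S1179"

    def test_anchorless_sequence_is_unassigned(self, six_locus_panel):
        assert assign_read("ACGT" * 40, six_locus_panel).status == "unassigned"

    def test_read_matching_two_loci_is_ambiguous(self, six_locus_panel):
        chimera = clean_read(six_locus_panel["D8S1179"], 13) + clean_read(
            six_locus_panel["TH01"], 7
        )
        assert assign_read(chimera, six_locus_panel).status == "ambiguous"


class TestProcessReads:
    def test_error_free_reads_all_assigned(self, six_locus_panel):
        spec = simulate.single_sample(
            list(six_locus_panel),
            {name: [(RepeatLength(9), 1), (RepeatLength(11), 1)] for name in six_locus_panel.names},
            100,
            seed=3,
        )
        reads = simulate.simulate_reads(spec)
        result = process_records((r.sequence for r in reads), six_locus_panel)
        assert result.tally.total == 600
        assert result.tally.assigned == 600
        assert result.tally.unassigned == 0

    def test_per_locus_counts_match_simulator_truth(self, six_locus_panel):
        spec = simulate.single_sample(
            list(six_locus_panel),
            {name: [(RepeatLength(9), 1), (RepeatLength(11), 1)] for name in six_locus_panel.names},
            200,
            seed=9,
        )
        reads = simulate.simulate_reads(spec)
        truth_counts = {}
        for r in reads:
            truth_counts[r.locus] = truth_counts.get(r.locus, 0) + 1
        result = process_records((r.sequence for r in reads), six_locus_panel)
        called_counts = {l: len(c) for l, c in result.calls_by_locus.items() if c}
        assert called_counts == truth_counts

    def test_tally_classes_partition_total(self, six_locus_panel, tatc_locus):
        mixed = [
            clean_read(six_locus_panel["TH01"], 7),
            "ACGT" * 30,
            clean_read(six_locus_panel["D8S1179"], 13) + clean_read(six_locus_panel["TH01"], 7),
            clean_read(six_locus_panel["vWA"], 17) + six_locus_panel["vWA"].start_anchor,
        ]
        t = process_records(mixed, six_locus_panel).tally
        assert t.assigned + t.unassigned + t.ambiguous + t.malformed == t.total == 4

    def test_empty_fastq(self, six_locus_panel, tmp_path):
        empty = tmp_path / "empty.fastq"
        empty.write_text("")
        result = strngs.process_reads(empty, six_locus_panel)
        assert result.tally.total == 0
        assert all(not calls for calls in result.calls_by_locus.values())

    def test_fastq_gz_round_trip(self, tatc_locus, tmp_path):
        panel = strngs.Panel(species="one", loci=(tatc_locus,))
        spec = simulate.single_sample([tatc_locus], {"TATC1": [(RepeatLength(12), 1)]}, 50, seed=1)
        path = tmp_path / "reads.fastq.gz"
        simulate.simulate_sample(spec, path)
        result = strngs.process_reads(path, panel)
        assert result.tally.assigned == 50

    def test_truncated_fastq_raises_io_error_naming_file(self, six_locus_panel, tmp_path):
        bad = tmp_path / "truncated.fastq"
        bad.write_text("@read1\nACGT\n+\n")  # missing quality line
        with pytest.raises(IOError, match="truncated.fastq"):
            strngs.process_reads(bad, six_locus_panel)
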