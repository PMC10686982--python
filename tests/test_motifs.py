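import math

import numpy as np
import pytest

from regspot.io import Interval
from regspot.motifs import (
    BASES,
    PWM,
    SequenceWindow,
    consensus_counts,
    consensus_from_counts,
    extract_window,
    nearest_ets_offset,
    offset_histogram,
    pwm_from_consensus,
    revcomp,
    scan_pwm,
)
from regspot.regions import union


def random_window(rng, length=11):
    seq = "".join(rng.choice(list(BASES), size=length))
    return SequenceWindow("chr1", 0, seq, int(rng.integers(0, length)))


class TestExtractWindow:
    GENOME = {"chr1": "ACGTACGTACGTACGTACGT"}

    def test_substring_arithmetic(self):
        w = extract_window(self.GENOME, "chr1", 10, length=11, anchor_index=6)
        # 1-based bases 5..15, i.e. 0-based [4:15); variant (pos1=10) at index 5
        assert w.seq == self.GENOME["chr1"][4:15]
        assert w.variant_offset == 5
        assert w.window_start == 4

    def test_variant_centered_for_11bp(self):
        w = extract_window(self.GENOME, "chr1", 8, length=11, anchor_index=6)
        assert w.variant_offset == 5 == (11 - 1) // 2
        assert w.seq[w.variant_offset] == self.GENOME["chr1"][7]

    def test_20bp_anchor_10(self):
        w = extract_window(self.GENOME, "chr1", 10, length=20, anchor_index=10)
        assert w.variant_offset == 9
        assert len(w.seq) == 20

    def test_off_start_errors(self):
        with pytest.raises(ValueError):
            extract_window(self.GENOME, "chr1", 3, length=11, anchor_index=6)

    def test_off_end_errors(self):
        with pytest.raises(ValueError):
            extract_window(self.GENOME, "chr1", 18, length=11, anchor_index=6)

    def test_mut_window_substitutes_alt(self):
        w = extract_window(self.GENOME, "chr1", 10, length=11, anchor_index=6, alt="T")
        assert w.allele == "MUT"
        assert w.seq[5] == "T"
        wt = extract_window(self.GENOME, "chr1", 10, length=11, anchor_index=6)
        assert w.seq[:5] == wt.seq[:5] and w.seq[6:] == wt.seq[6:]


class TestNearestEtsOffset:
    def test_g528a_style_offset_plus_four(self):
        # wild-type 10-mer CCGGAAGGCC; the mutated base is index 6
        res = nearest_ets_offset(SequenceWindow("chr1", 0, "CCGGAAGGCC", 6))
        assert res.found and res.strand == "+"
        assert res.motif_start == 2
        assert res.offset == 4

    def test_reverse_complement_same_offset(self):
        res = nearest_ets_offset(SequenceWindow("chr1", 0, "GGCCTTCCGG", 3))
        assert res.found and res.strand == "-"
        assert res.offset == 4

    def test_no_motif(self):
        res = nearest_ets_offset(SequenceWindow("chr1", 0, "ACACACACACA", 5))
        assert not res.found

    def test_inside_core_offsets(self):
        for i in range(2, 6):
            res = nearest_ets_offset(SequenceWindow("chr1", 0, "CCGGAAGGCC", i))
            assert res.offset == i - 2
            assert 0 <= res.offset <= 3

    def test_offset_range_invariant(self, rng):
        for _ in range(2000):
            w = random_window(rng)
            res = nearest_ets_offset(w)
            if res.found:
                assert -(len(w.seq) - 4) <= res.offset <= len(w.seq) - 1

    def test_strand_involution(self, rng):
        for _ in range(2000):
            w = random_window(rng)
            rc = SequenceWindow(
                w.chrom, w.window_start, revcomp(w.seq),
                len(w.seq) - 1 - w.variant_offset,
            )
            a, b = nearest_ets_offset(w), nearest_ets_offset(rc)
            assert a.found == b.found
            if a.found:
                assert a.offset == b.offset

    def test_nearest_occurrence_wins(self):
        # GGAA at 0 and at 11; variant at 9 is nearer the second
        seq = "GGAACCCCCCCGGAA"
        res = nearest_ets_offset(SequenceWindow("chr1", 0, seq, 9))
        assert res.motif_start == 11
        assert res.offset == -2


class TestOffsetHistogram:
    def test_counts(self):
        windows = [SequenceWindow("chr1", 0, "CCGGAAGGCC", 6)] * 3
        counts, missing = offset_histogram(windows)
        assert counts == {4: 3}
        assert missing == 0

    def test_empty(self):
        counts, missing = offset_histogram([])
        assert counts == {} and missing == 0

    def test_no_motif_tallied_separately(self):
        windows = [
            SequenceWindow("chr1", 0, "CCGGAAGGCC", 6),
            SequenceWindow("chr1", 0, "ACACACACAC", 5),
        ]
        counts, missing = offset_histogram(windows)
        assert counts == {4: 1} and missing == 1

    def test_variants_inside_core_stay_in_0_3(self, rng):
        # windows whose variant always sits inside the GGAA core
        windows = []
        for _ in range(100):
            pad_left = int(rng.integers(0, 4))
            seq = ("C" * pad_left + "GGAA" + "C" * (7 - pad_left))
            windows.append(
                SequenceWindow("chr1", 0, seq, pad_left + int(rng.integers(0, 4)))
            )
        counts, missing = offset_histogram(windows)
        assert missing == 0
        assert set(counts) <= {0, 1, 2, 3}


class TestConsensusCounts:
    def test_single_window_placement(self):
        # GGAA starts at index 2; aligned so first G is 1-based position 5
        w = SequenceWindow("chr1", 0, "CCGGAAGGCCC", 6)
        counts = consensus_counts([w], align_g_at=5, length=11)
        g, a = BASES.index("G"), BASES.index("A")
        assert counts[g, 4] == 1 and counts[g, 5] == 1
        assert counts[a, 6] == 1 and counts[a, 7] == 1

    def test_linearity(self):
        w = SequenceWindow("chr1", 0, "CCGGAAGGCCC", 6)
        single = consensus_counts([w])
        double = consensus_counts([w, w])
        np.testing.assert_array_equal(double, 2 * single)

    def test_column_sums_bounded(self, rng):
        windows = [random_window(rng) for _ in range(50)]
        counts = consensus_counts(windows)
        assert (counts.sum(axis=0) <= len(windows)).all()

    def test_consensus_string(self):
        w = SequenceWindow("chr1", 0, "CCGGAAGGCCC", 6)
        counts = consensus_counts([w])
        assert consensus_from_counts(counts)[4:8] == "GGAA"


class TestPwmFromConsensus:
    FIVE_TEN_MERS = ["CCGGAAGGCC", "CCAGAAGGCC", "CCGGAAAGCC", "CCGGAAGACC", "CCGGAAAACC"]

    def test_wild_type_ten_mer(self):
        pwm = pwm_from_consensus("CCGGAAGGCC")
        assert len(pwm) == 10
        assert BASES[int(np.argmax(pwm.probs[:, 2]))] == "G"

    @pytest.mark.parametrize("consensus", FIVE_TEN_MERS)
    def test_columns_sum_to_one(self, consensus):
        pwm = pwm_from_consensus(consensus)
        np.testing.assert_allclose(pwm.probs.sum(axis=0), 1.0, atol=1e-12)

    def test_self_score_closed_form(self):
        pwm = pwm_from_consensus("CCGGAAGGCC", p_consensus=0.997)
        expected = 10 * math.log2(0.997 / 0.25)
        assert pwm.self_score == pytest.approx(expected)
        assert pwm.score("CCGGAAGGCC") == pytest.approx(expected)

    def test_self_score_is_maximum(self, rng):
        pwm = pwm_from_consensus("CCGGAAGGCC")
        for _ in range(200):
            seq = "".join(rng.choice(list(BASES), size=10))
            assert pwm.score(seq) <= pwm.self_score + 1e-9

    def test_ambiguity_codes_error(self):
        with pytest.raises(ValueError):
            pwm_from_consensus("CCGGAANGCC")

    def test_probabilities(self):
        pwm = pwm_from_consensus("A", p_consensus=0.997)
        assert pwm.probs[BASES.index("A"), 0] == pytest.approx(0.997)
        assert pwm.probs[BASES.index("C"), 0] == pytest.approx(0.001)


class TestScanPwm:
    CONSENSUS = "CCGGAAGGCC"

    def embed(self, insert, rng, length=200, at=77):
        seq = "".join(rng.choice(list("AT"), size=length))  # no GC -> no spurious hits
        return seq[:at] + insert + seq[at + len(insert):]

    def test_single_forward_hit(self, rng):
        pwm = pwm_from_consensus(self.CONSENSUS)
        seq = self.embed(self.CONSENSUS, rng)
        genome = {"chr1": seq}
        regions = union([Interval("chr1", 0, len(seq))])
        hits = scan_pwm(pwm, regions, genome)
        assert len(hits) == 1
        iv, strand, score = hits[0]
        assert (iv.start, iv.end, strand) == (77, 87, "+")
        assert score == pytest.approx(pwm.self_score)

    def test_reverse_hit_at_mirrored_coordinates(self, rng):
        pwm = pwm_from_consensus(self.CONSENSUS)
        seq = self.embed(self.CONSENSUS, rng)
        rc = revcomp(seq)
        genome = {"chr1": rc}
        regions = union([Interval("chr1", 0, len(rc))])
        hits = scan_pwm(pwm, regions, genome)
        assert len(hits) == 1
        iv, strand, score = hits[0]
        assert strand == "-"
        assert (iv.start, iv.end) == (len(seq) - 87, len(seq) - 77)
        assert score == pytest.approx(pwm.self_score)

    def test_threshold_above_self_score_no_hits(self, rng):
        pwm = pwm_from_consensus(self.CONSENSUS)
        seq = self.embed(self.CONSENSUS, rng)
        regions = union([Interval("chr1", 0, len(seq))])
        hits = scan_pwm(pwm, regions, {"chr1": seq},
                        threshold_bits=pwm.self_score + 0.1)
        assert hits == []

    def test_against_naive_rescoring_oracle(self, rng):
        pwm = pwm_from_consensus("GGAA")
        seq = "".join(rng.choice(list(BASES), size=300))
        regions = union([Interval("chr1", 0, len(seq))])
        threshold = 2.0
        hits = scan_pwm(pwm, regions, {"chr1": seq}, threshold_bits=threshold)
        expected = []
        for i in range(len(seq) - 3):
            sub = seq[i : i + 4]
            if pwm.score(sub) >= threshold:
                expected.append((i, "+"))
            if pwm.score(revcomp(sub)) >= threshold:
                expected.append((i, "-"))
        got = sorted((iv.start, strand) for iv, strand, _ in hits)
        assert got == sorted(expected)

    def test_downsampling_deterministic(self, rng):
        pwm = pwm_from_consensus("GG", p_consensus=0.6)
        seq = "G" * 500
        regions = union([Interval("chr1", 0, 500)])
        kw = dict(threshold_bits=0.0, max_instances=50, seed=7)
        hits1 = scan_pwm(pwm, regions, {"chr1": seq}, **kw)
        hits2 = scan_pwm(pwm, regions, {"chr1": seq}, **kw)
        assert len(hits1) == 50
        assert hits1 == hits2


class TestPwmValidation:
    def test_column_sum_enforced(self):
        probs = np.full((4, 2), 0.3)
        with pytest.raises(ValueError):
            PWM(probs=probs, consensus="AA", p_consensus=0.9)

    def test_argmax_consistency_enforced(self):
        probs = np.array([[0.1], [0.7], [0.1], [0.1]])
        with pytest.raises(ValueError):
            PWM(probs=probs, consensus="A", p_consensus=0.7)
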