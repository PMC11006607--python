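import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from locusforge.errors import ParameterError
from locusforge.io_formats import SequenceRecord
from locusforge.locus_design import reverse_sequence, scrub_cpg
from locusforge.seq_features import (
    CpGStats,
    DINUCLEOTIDES,
    cpg_stats,
    dinuc_profile,
    find_cpg_islands,
    gc_track,
    iupac_scan,
    oe_fold_enrichment,
    predict_reversed_profile,
    round_half_even,
)
from locusforge.synthetic_data import random_sequence

dna = st.text(alphabet="ACGT", min_size=2, max_size=200)


def brute_force_dinucs(seq: str) -> dict[str, int]:
    counts = dict.fromkeys(DINUCLEOTIDES, 0)
    for i in range(len(seq) - 1):
        pair = seq[i:i + 2]
        if "N" not in pair:
            counts[pair] += 1
    return counts


class TestDinucProfile:
    def test_homopolymer(self):
        p = dinuc_profile(SequenceRecord("x", "AAA"))
        assert p.dinuc["AA"] == 2 and p.length == 3

    def test_acgt_counts(self):
        p = dinuc_profile(SequenceRecord("x", "ACGT"))
        assert p.dinuc["AC"] == p.dinuc["CG"] == p.dinuc["GT"] == 1
        assert sum(p.dinuc.values()) == 3

    def test_sum_invariant_on_random_sequence(self, rng):
        seq = random_sequence(rng, 10_000, 0.45)
        p = dinuc_profile(SequenceRecord("x", seq))
        assert sum(p.dinuc.values()) == 9_999
        assert p.dinuc == brute_force_dinucs(seq)
        assert sum(v for b, v in p.mono.items()) == p.length

    def test_n_pairs_skipped_and_gc_denominator(self):
        p = dinuc_profile(SequenceRecord("x", "ACNGC"))
        assert sum(p.dinuc.values()) == 2  # AC and GC; CN/NG skipped
        assert p.mono["N"] == 1
        assert p.gc_fraction == pytest.approx(3 / 4)


class TestReversalIdentity:
    @given(dna)
    @settings(max_examples=200, derandomize=True)
    def test_profile_of_reversed_equals_prediction(self, seq):
        rec = SequenceRecord("x", seq)
        direct = dinuc_profile(reverse_sequence(rec))
        predicted = predict_reversed_profile(dinuc_profile(rec))
        assert direct.dinuc == predicted.dinuc
        assert direct.mono == predicted.mono

    def test_involution(self, random_record):
        p = dinuc_profile(random_record)
        assert predict_reversed_profile(predict_reversed_profile(p)).dinuc == p.dinuc

    def test_rejects_n(self):
        with pytest.raises(ParameterError):
            predict_reversed_profile(dinuc_profile(SequenceRecord("x", "ANA")))

    def test_expected_cpg_invariant_under_reversal(self, random_record):
        fwd = cpg_stats(dinuc_profile(random_record))
        rev = cpg_stats(dinuc_profile(reverse_sequence(random_record)))
        assert rev.expected == fwd.expected


class TestCpGStats:
    def test_printed_table_ratios(self):
        fwd = CpGStats(observed=1202, expected=4291.0, ratio=1202 / 4291)
        rev = CpGStats(observed=4499, expected=4291.0, ratio=4499 / 4291)
        assert round_half_even(fwd.ratio) == 0.28
        assert round_half_even(rev.ratio) == 1.05

    def test_all_a_sequence_zero_ratio(self):
        s = cpg_stats(dinuc_profile(SequenceRecord("x", "AAAA")))
        assert (s.observed, s.expected, s.ratio) == (0, 0.0, 0.0)

    def test_scrubbed_sequence_has_zero_observed(self, random_record):
        scrubbed = scrub_cpg(random_record, seed=5).scrubbed
        s = cpg_stats(dinuc_profile(scrubbed))
        assert s.observed == 0 and s.ratio == 0.0

    def test_fold_enrichment_identities(self):
        a = CpGStats(observed=10, expected=10.0, ratio=1.05)
        b = CpGStats(observed=10, expected=10.0, ratio=0.28)
        assert oe_fold_enrichment(a, b) == pytest.approx(3.75)
        assert oe_fold_enrichment(a, a) == 1.0
        zero = CpGStats(observed=0, expected=5.0, ratio=0.0)
        assert oe_fold_enrichment(zero, b) == 0.0
        with pytest.raises(ParameterError):
            oe_fold_enrichment(a, zero)


class TestGcTrack:
    def test_all_g_constant(self):
        t = gc_track(SequenceRecord("x", "G" * 50), window=10, step=10)
        assert np.all(t.data["x"] == 1.0)

    def test_two_block_sequence(self):
        t = gc_track(SequenceRecord("x", "AATTGGCC"), window=4, step=4)
        assert t.data["x"].tolist() == [0.0, 1.0]

    def test_window_mean_matches_global_gc(self, rng):
        seq = random_sequence(rng, 20_000, 0.37)
        rec = SequenceRecord("x", seq)
        t = gc_track(rec, window=1_000, step=1_000)
        global_gc = dinuc_profile(rec).gc_fraction
        assert abs(t.data["x"].mean() - global_gc) < 0.02

    def test_window_larger_than_sequence_rejected(self):
        with pytest.raises(ParameterError):
            gc_track(SequenceRecord("x", "ACGT"), window=10, step=1)


def window_qualifies(seq: str, start: int, window: int,
                     min_gc: float, min_oe: float) -> bool:
    """Independent per-window scorer used to cross-check island calls."""
    w = seq[start:start + window]
    n_c, n_g = w.count("C"), w.count("G")
    obs = sum(1 for i in range(len(w) - 1) if w[i:i + 2] == "CG")
    gc = (n_c + n_g) / window
    exp = n_c * n_g / window
    oe = obs / exp if exp > 0 else 0.0
    return gc >= min_gc and oe >= min_oe


class TestCpGIslands:
    def test_planted_island_found(self, rng):
        flank = "".join(rng.choice(list("AT"), 1000))
        island = "CG" * 150  # 300 bp, GC=1, O/E ~ 2
        seq = flank + island + flank
        calls = find_cpg_islands(SequenceRecord("x", seq))
        assert len(calls) == 1
        call = calls[0]
        assert call.interval.start <= 1000 and call.interval.end >= 1300
        assert call.mean_gc >= 0.5 and call.mean_oe >= 0.6
        # every window inside the qualifying run passes the thresholds
        assert window_qualifies(seq, 1050, 100, 0.5, 0.6)

    def test_all_a_sequence_empty(self):
        assert find_cpg_islands(SequenceRecord("x", "A" * 500)) == []

    def test_short_rich_run_below_min_len_dropped(self, rng):
        flank = "".join(rng.choice(list("AT"), 500))
        seq = flank + "CG" * 25 + flank  # 50-bp run << min_len 200
        assert find_cpg_islands(SequenceRecord("x", seq)) == []

    def test_scrubbed_sequence_has_no_islands_at_default_threshold(self, random_record):
        scrubbed = scrub_cpg(random_record, seed=2).scrubbed
        assert find_cpg_islands(scrubbed) == []

    def test_calls_match_independent_window_scorer(self, rng):
        # GC-rich mosaic likely to contain borderline windows
        parts = []
        for _ in range(20):
            gc = float(rng.uniform(0.2, 0.9))
            parts.append(random_sequence(rng, 200, gc))
        seq = "".join(parts)
        for call in find_cpg_islands(SequenceRecord("x", seq)):
            s, e = call.interval.start, call.interval.end
            assert e - s >= 200
            assert window_qualifies(seq, s, 100, 0.5, 0.6)
            assert window_qualifies(seq, e - 100, 100, 0.5, 0.6)


class TestIupacScan:
    def test_constructed_motif_position(self):
        hits = iupac_scan(SequenceRecord("x", "AACTCAGACTCAA"), "CTCNGNCTC")
        assert [(h.start, h.end) for h in hits] == [(2, 11)]

    def test_pattern_n_matches_everywhere(self):
        assert len(iupac_scan(SequenceRecord("x", "ACGTAC"), "N")) == 6

    def test_both_strands_reports_reverse_complement(self):
        # GAGNCNGAG is the reverse complement of CTCNGNCTC
        rec = SequenceRecord("x", "TTGAGACAGAGTT")
        hits = iupac_scan(rec, "CTCNGNCTC", both_strands=True)
        assert [(h.start, h.strand) for h in hits] == [(2, "-")]

    def test_illegal_code_rejected(self):
        with pytest.raises(ParameterError):
            iupac_scan(SequenceRecord("x", "ACGT"), "CXG")

    def test_matches_equal_naive_enumeration(self, rng):
        seq = random_sequence(rng, 3_000, 0.5)
        pattern = "RYSW"
        expand = {"R": "AG", "Y": "CT", "S": "CG", "W": "AT"}
        naive = [
            i for i in range(len(seq) - 3)
            if all(seq[i + j] in expand[c] for j, c in enumerate(pattern))
        ]
        hits = iupac_scan(SequenceRecord("x", seq), pattern)
        assert [h.start for h in hits] == naive
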