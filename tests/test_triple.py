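"""Triple alignment, segmentation statistics, and PP/PM/MP classification."""

import numpy as np
import pytest

from sineortho.simulate import mutate, random_dna
from sineortho.triple import align_triple, classify_locus_pair, classify_pair, segment_stats
from sineortho.types import InvalidInputError, SineConsensus, TripleAlignment


@pytest.fixture
def cons(rng):
    return SineConsensus("sine", random_dna(rng, 360))


class TestAlignTriple:
    def test_identical_loci_with_sine(self, rng, cons):
        lf, rf = random_dna(rng, 300), random_dna(rng, 300)
        seq = lf + cons.sequence + rf
        aln = align_triple(seq, seq, cons)
        assert "-" not in aln.row_a and "-" not in aln.row_b
        assert (aln.sine_start_col, aln.sine_end_col) == (300, 660)
        assert aln.row_cons[300:660] == cons.sequence
        assert set(aln.row_cons[:300]) == {"-"} and set(aln.row_cons[660:]) == {"-"}

    def test_missing_sine_gaps_other_row(self, rng, cons):
        lf, rf = random_dna(rng, 300), random_dna(rng, 300)
        seq_a = lf + cons.sequence + rf
        seq_b = lf + rf
        aln = align_triple(seq_a, seq_b, cons)
        s, e = aln.sine_start_col, aln.sine_end_col
        b_in_sine = sum(1 for ch in aln.row_b[s:e] if ch != "-")
        assert e - s >= 350
        assert b_in_sine < 30

    def test_unrelated_consensus_gives_no_anchor(self, rng):
        other = SineConsensus("other", random_dna(rng, 360))
        seq = random_dna(rng, 900)
        aln = align_triple(seq, seq, other)
        stats = segment_stats(aln)
        # either no anchor at all, or a short low-identity chance anchor
        if aln.sine_end_col > aln.sine_start_col:
            assert stats["SINE"].len_a < 100 or stats["SINE"].pct_a_cons < 65
        else:
            assert set(aln.row_cons) == {"-"}

    def test_empty_sequence_rejected(self, cons):
        with pytest.raises(InvalidInputError):
            align_triple("", "ACGT", cons)


class TestSegmentStats:
    def test_identical_flanks(self):
        aln = TripleAlignment("A" * 150 + "C" * 30 + "A" * 150,
                              "A" * 150 + "C" * 30 + "A" * 150,
                              "-" * 150 + "C" * 30 + "-" * 150, 150, 180)
        st = segment_stats(aln)
        assert st["LF"].len_a == st["LF"].len_b == 150
        assert st["LF"].pct_ab == 100.0

    def test_hand_counted_flank_identity(self):
        # LF rows differ at one position: 9/10 identical = 90%
        row_a = "ACGTACGTAC" + "CCCC"
        row_b = "ACGTACGAAC" + "CCCC"
        cons = "-" * 10 + "CCCC"
        st = segment_stats(TripleAlignment(row_a, row_b, cons, 10, 14))
        assert st["LF"].identical_ab == 9
        assert st["LF"].pct_ab == 90.0

    def test_five_percent_divergence_matches_binomial_expectation(self):
        """Pairwise flank identity at 5% simulated divergence follows the
        Binomial(300, 0.05) mismatch model: mean ~95%, and ~99% of draws
        inside the +/-2.5-sigma envelope [92, 98] over 100 seeds."""
        from sineortho.align import global_alignment

        pcts = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            fa = random_dna(rng, 300)
            fb = mutate(rng, fa, 0.05)
            aln = global_alignment(fa, fb)
            ta = TripleAlignment(str(aln[0]), str(aln[1]), "-" * aln.length, 0, 0)
            pcts.append(segment_stats(ta)["RF"].pct_ab)
        inside = sum(1 for p in pcts if 92.0 <= p <= 98.0)
        assert inside >= 95
        assert 94.0 <= float(np.mean(pcts)) <= 96.0

    def test_identity_conservation_across_segments(self, rng, cons):
        lf, rf = random_dna(rng, 300), random_dna(rng, 300)
        seq_a = lf + cons.sequence + rf
        seq_b = mutate(rng, lf, 0.05) + mutate(rng, cons.sequence, 0.05) + mutate(rng, rf, 0.05)
        aln = align_triple(seq_a, seq_b, cons)
        st = segment_stats(aln)
        whole = sum(1 for x, y in zip(aln.row_a, aln.row_b) if x == y and x != "-")
        parts = sum(st[r].identical_ab for r in ("LF", "SINE", "RF"))
        assert parts == whole  # segmentation is exhaustive


def _stats_aln(lf_len=300, sine_len=360, rf_len=300, lf_mm=0, rf_mm=0,
               sine_a=True, sine_b=True, sine_b_len=None):
    """Build a synthetic triple alignment with controlled segment shapes."""
    lf_a = "A" * lf_len
    lf_b = "C" * lf_mm + "A" * (lf_len - lf_mm)
    rf_a = "G" * rf_len
    rf_b = "T" * rf_mm + "G" * (rf_len - rf_mm)
    cons = "T" * sine_len
    row_a = lf_a + (cons if sine_a else "-" * sine_len) + rf_a
    if sine_b:
        blen = sine_b_len if sine_b_len is not None else sine_len
        row_b = lf_b + cons[:blen] + "-" * (sine_len - blen) + rf_b
    else:
        row_b = lf_b + "-" * sine_len + rf_b
    row_c = "-" * lf_len + cons + "-" * rf_len
    return TripleAlignment(row_a, row_b, row_c, lf_len, lf_len + sine_len)


class TestClassifyPair:
    def _verdict(self, aln):
        return classify_pair(segment_stats(aln), aln)

    def test_both_present_is_pp(self):
        assert self._verdict(_stats_aln()).status == "PP"

    def test_short_left_flank_sharp_at_150(self):
        assert self._verdict(_stats_aln(lf_len=150)).status == "PP"
        v = self._verdict(_stats_aln(lf_len=149))
        assert (v.status, v.discard_reason) == ("discarded", "shortLF")

    def test_short_right_flank(self):
        v = self._verdict(_stats_aln(rf_len=149))
        assert v.discard_reason == "shortRF"

    def test_sine_at_alignment_edge(self):
        v = self._verdict(_stats_aln(lf_len=0))
        assert v.discard_reason == "leftSINE"
        v = self._verdict(_stats_aln(rf_len=0))
        assert v.discard_reason == "rightSINE"

    def test_flank_identity_sharp_at_65(self):
        # 300-nt flank: 105 mismatches = 65.0%, 106 = 64.7%
        assert self._verdict(_stats_aln(lf_mm=105)).status == "PP"
        v = self._verdict(_stats_aln(lf_mm=106))
        assert v.discard_reason == "low_flank_identity"

    def test_sine_presence_sharp_at_100nt(self):
        assert self._verdict(_stats_aln(sine_b_len=100)).status == "PP"
        v = self._verdict(_stats_aln(sine_b_len=99))
        assert v.status == "PM"

    def test_one_sided_presence(self):
        assert self._verdict(_stats_aln(sine_b=False)).status == "PM"
        aln = _stats_aln(sine_a=False)
        assert self._verdict(aln).status == "MP"

    def test_neither_present_discarded_minus_minus(self):
        v = self._verdict(_stats_aln(sine_a=False, sine_b=False))
        assert (v.status, v.discard_reason) == ("discarded", "minus_minus")


class TestEndToEndClassification:
    def test_pm_with_unrelated_filler_flagged(self, rng, cons):
        lf, rf = random_dna(rng, 300), random_dna(rng, 300)
        seq_a = lf + mutate(rng, cons.sequence, 0.05) + rf
        filler = random_dna(rng, 340)
        seq_b = mutate(rng, lf, 0.05) + filler + mutate(rng, rf, 0.05)
        v = classify_locus_pair(seq_a, seq_b, cons)
        assert v.status == "PM"
        assert v.foreign_b
        assert v.stats["SINE"].pct_b_cons < 65

    def test_swap_symmetry(self, rng, cons):
        lf, rf = random_dna(rng, 300), random_dna(rng, 300)
        sine = mutate(rng, cons.sequence, 0.05)
        cases = {
            "PP": (lf + sine + rf, mutate(rng, lf, 0.04) + mutate(rng, sine, 0.04) + mutate(rng, rf, 0.04)),
            "PM": (lf + sine + rf, mutate(rng, lf, 0.04) + mutate(rng, rf, 0.04)),
        }
        flip = {"PP": "PP", "PM": "MP", "MP": "PM"}
        for expected, (sa, sb) in cases.items():
            v = classify_locus_pair(sa, sb, cons)
            w = classify_locus_pair(sb, sa, cons)
            assert v.status == expected
            assert w.status == flip[expected]
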