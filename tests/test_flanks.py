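"""Flank extraction arithmetic, flank mapping, extension and fetching."""

import pytest

from conftest import plant
from sineortho.align import revcomp
from sineortho.flanks import extend_right, extract_left_flanks, fetch_sequence, map_flanks
from sineortho.simulate import random_dna
from sineortho.types import CandidateLocus, Flank, InvalidInputError, SineHit


def _copy(start, end, strand="+", contig="c", genome="G", cid="copy1"):
    return SineHit(genome, contig, start, end, strand, 95.0, 1.0, hit_id=cid)


class TestExtractLeftFlanks:
    def test_plus_strand_flank_is_upstream_slice(self, rng):
        contig = random_dna(rng, 3000)
        (fl,) = extract_left_flanks([_copy(1000, 1180)], {"c": contig})
        assert (fl.start, fl.end, fl.strand) == (700, 1000, "+")
        assert fl.sequence == contig[700:1000]
        assert not fl.truncated

    def test_minus_strand_flank_is_downstream_revcomp(self, rng):
        contig = random_dna(rng, 3000)
        (fl,) = extract_left_flanks([_copy(1000, 1180, strand="-")], {"c": contig})
        assert (fl.start, fl.end, fl.strand) == (1180, 1480, "-")
        assert fl.sequence == revcomp(contig[1180:1480])

    def test_contig_edge_truncates_and_flags(self, rng):
        contig = random_dna(rng, 2000)
        (fl,) = extract_left_flanks([_copy(120, 400)], {"c": contig})
        assert (fl.start, fl.end) == (0, 120)
        assert fl.truncated
        assert len(fl.sequence) == 120

    def test_zero_length_flank_dropped(self, rng):
        contig = random_dna(rng, 2000)
        assert extract_left_flanks([_copy(0, 300)], {"c": contig}) == []


def _flank(seq, cid="f1", genome="Q"):
    return Flank(copy_id=cid, genome_id=genome, contig="qc", start=0,
                 end=len(seq), strand="+", sequence=seq)


class TestMapFlanks:
    def test_verbatim_flank_maps_once_full_length(self, rng):
        flank_seq = random_dna(rng, 300)
        target = plant(random_dna(rng, 10_000), flank_seq, 4000)
        hits = map_flanks([_flank(flank_seq)], {"t": target}, "T")
        assert len(hits) == 1
        h = hits[0]
        assert (h.contig, h.start, h.end, h.strand) == ("t", 4000, 4300, "+")
        assert h.aligned_length == 300

    def test_duplicated_flank_keeps_both_hits(self, rng):
        flank_seq = random_dna(rng, 300)
        target = plant(random_dna(rng, 12_000), flank_seq, 2000)
        target = plant(target, flank_seq, 8000)
        hits = map_flanks([_flank(flank_seq)], {"t": target}, "T")
        assert sorted(h.start for h in hits) == [2000, 8000]

    def test_reverse_strand_hit_found(self, rng):
        flank_seq = random_dna(rng, 300)
        target = plant(random_dna(rng, 10_000), revcomp(flank_seq), 5000)
        hits = map_flanks([_flank(flank_seq)], {"t": target}, "T")
        assert [(h.start, h.strand) for h in hits] == [(5000, "-")]

    def test_mapped_length_filter_sharp_at_100(self, rng):
        # 210 matching bp -> kept; 90 matching bp -> dropped.  The flank
        # remainder and target continuation are forced to mismatch at every
        # column so chance extension cannot blur the aligned length.
        matching = random_dna(rng, 210).replace("A", "C")
        tail = "A" * 90
        flank_seq = matching + tail
        target = plant("G" * 5000, matching, 2000)  # A-free continuation
        hits = map_flanks([_flank(flank_seq)], {"t": target}, "T")
        assert len(hits) == 1
        assert hits[0].aligned_length >= 100

        short = random_dna(rng, 90).replace("A", "C") + "A" * 210
        target2 = plant("G" * 5000, short[:90], 2000)
        assert map_flanks([_flank(short)], {"t": target2}, "T") == []

    def test_self_mapping_returns_own_coordinates(self, rng):
        contigs = {"c": random_dna(rng, 6000)}
        copies = [_copy(1000, 1300, cid="x"), _copy(4000, 4300, cid="y")]
        flanks = extract_left_flanks(copies, contigs)
        hits = map_flanks(flanks, contigs, "G2")  # same sequence, other id
        assert len(hits) == 2
        for fl, h in zip(flanks, sorted(hits, key=lambda m: m.start)):
            assert (h.start, h.end) == (fl.start, fl.end)
            assert h.aligned_length == len(fl.sequence)

    def test_exact_self_coordinate_hit_excluded(self, rng):
        contigs = {"c": random_dna(rng, 6000)}
        flanks = extract_left_flanks([_copy(1000, 1300)], contigs)
        flanks[0].contig = "c"
        assert map_flanks(flanks, contigs, "G") == []  # same genome id


class TestExtendRight:
    def test_plus_strand_grows_right(self):
        fl = _flank("A" * 300)
        fl.contig, fl.start, fl.end = "c", 700, 1000
        (locus,) = extend_right([fl], {"c": 5000}, sine_len=360)
        assert (locus.start, locus.end) == (700, 1660)

    def test_minus_strand_grows_left(self):
        fl = _flank("A" * 300)
        fl.contig, fl.start, fl.end, fl.strand = "c", 1180, 1480, "-"
        (locus,) = extend_right([fl], {"c": 5000}, sine_len=360)
        assert (locus.start, locus.end) == (520, 1480)

    def test_strand_naive_always_grows_right(self):
        fl = _flank("A" * 300)
        fl.contig, fl.start, fl.end, fl.strand = "c", 1180, 1480, "-"
        (locus,) = extend_right([fl], {"c": 5000}, sine_len=360, strand_naive=True)
        assert (locus.start, locus.end) == (1180, 2140)

    def test_clamped_to_contig(self):
        fl = _flank("A" * 300)
        fl.contig, fl.start, fl.end = "c", 700, 1000
        (locus,) = extend_right([fl], {"c": 1200}, sine_len=360)
        assert (locus.start, locus.end) == (700, 1200)


class TestFetchSequence:
    def test_whole_contig(self, rng):
        contig = random_dna(rng, 400)
        locus = CandidateLocus("G", "c", 0, 400)
        assert fetch_sequence(locus, {"c": contig}) == contig

    def test_minus_locus_reverse_complemented(self, rng):
        contig = random_dna(rng, 400)
        locus = CandidateLocus("G", "c", 100, 300, strand="-")
        assert fetch_sequence(locus, {"c": contig}) == revcomp(contig[100:300])

    def test_empty_interval_errors(self, rng):
        locus = CandidateLocus.__new__(CandidateLocus)
        locus.genome_id, locus.contig, locus.start, locus.end = "G", "c", 0, 0
        locus.strand = "+"
        with pytest.raises(InvalidInputError):
            fetch_sequence(locus, {"c": random_dna(rng, 100)})


def test_strand_round_trip(rng):
    """Extracting from the reverse-complemented genome yields the same
    flank sequences at mirrored coordinates with flipped strand."""
    contig = random_dna(rng, 3000)
    copies = [_copy(1000, 1360, "+")]
    (fwd,) = extract_left_flanks(copies, {"c": contig})
    n = len(contig)
    mirrored = [_copy(n - 1360, n - 1000, "-")]
    (rev,) = extract_left_flanks(mirrored, {"c": revcomp(contig)})
    assert rev.sequence == fwd.sequence
    assert (rev.start, rev.end) == (n - 1000, n - 700)
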