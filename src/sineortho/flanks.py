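"""Flank extraction, reciprocal flank mapping, and interval extension.

Each retained SINE copy is anchored by the 300 bp immediately upstream of
it in the SINE's own orientation (genomic left for plus-strand copies,
genomic right, reverse-complemented, for minus-strand copies).  Flanks are
mapped to the other genome on both strands and every alignment of at least
100 aligned bp is kept, multimappers included.  Mapped (and query-side)
flank intervals are then extended downstream by SINE length + 300 bp so
that the resulting candidate locus covers the putative insertion and its
right flank.
"""

from __future__ import annotations

import logging

from sineortho.align import DEFAULT_SCORING, Scoring, SeedMapper, revcomp
from sineortho.types import CandidateLocus, Flank, InvalidInputError, MappedFlank, SineHit

log = logging.getLogger(__name__)


def extract_left_flanks(copies: list[SineHit], contigs: dict[str, str],
                        flank_len: int = 300) -> list[Flank]:
    """One left flank per copy; contig-edge flanks are truncated and flagged.

    Zero-length flanks (copy starting at the very contig edge) are dropped
    with a warning.
    """
    flanks = []
    for copy in copies:
        seq = contigs[copy.contig]
        if copy.end > len(seq):
            raise InvalidInputError(
                f"copy {copy.hit_id} exceeds contig {copy.contig}")
        if copy.strand == "+":
            start, end = max(0, copy.start - flank_len), copy.start
            flank_seq = seq[start:end].upper()
        else:
            start, end = copy.end, min(len(seq), copy.end + flank_len)
            flank_seq = revcomp(seq[start:end].upper())
        if end - start == 0:
            log.warning("copy %s has a zero-length left flank; dropped", copy.hit_id)
            continue
        flanks.append(Flank(
            copy_id=copy.hit_id, genome_id=copy.genome_id, contig=copy.contig,
            start=start, end=end, strand=copy.strand, sequence=flank_seq,
            truncated=(end - start) < flank_len))
    return flanks


def map_flanks(flanks: list[Flank], target_contigs: dict[str, str],
               target_genome_id: str, min_mapped_len: int = 100,
               k: int = 19, min_score: float = 60.0, keep_frac: float = 0.8,
               scoring: Scoring = DEFAULT_SCORING,
               mapper: SeedMapper | None = None) -> list[MappedFlank]:
    """Map flanks to a target genome, keeping all sufficiently long hits.

    Both target strands are searched; secondary alignments down to
    ``keep_frac`` x the flank's best score are retained; alignments with
    fewer than ``min_mapped_len`` aligned flank bases are removed.  A hit
    at the flank's own coordinates in its own genome is excluded.
    """
    if mapper is None:
        mapper = SeedMapper(target_contigs, k=k, scoring=scoring)
    mapped = []
    for flank in flanks:
        if len(flank.sequence) < mapper.k:
            log.warning("flank %s shorter than seed length; unmapped", flank.copy_id)
            continue
        for hit in mapper.map_query(flank.sequence, min_score=min_score,
                                    keep_frac=keep_frac):
            if hit.q_span < min_mapped_len:
                continue
            contig = hit.contig  # type: ignore[attr-defined]
            if (flank.genome_id == target_genome_id and contig == flank.contig
                    and hit.t_start == flank.start and hit.t_end == flank.end):
                continue  # exact self-coordinate hit
            # flank sequence is given in SINE orientation, so a "+" hit puts
            # the SINE to the genomic right of the mapped interval, "-" left
            strand = hit.strand
            mapped.append(MappedFlank(
                flank=flank, target_genome_id=target_genome_id,
                contig=contig, start=hit.t_start, end=hit.t_end,
                strand=strand, aligned_length=hit.q_span, score=hit.score))
    return mapped


def _extend_one(contig_len: int, start: int, end: int, strand: str,
                grow: int, strand_naive: bool) -> tuple[int, int]:
    if strand == "+" or strand_naive:
        return start, min(contig_len, end + grow)
    return max(0, start - grow), end


def extend_right(intervals: list[MappedFlank] | list[Flank],
                 contig_lengths: dict[str, int], sine_len: int,
                 pad: int = 300, strand_naive: bool = False) -> list[CandidateLocus]:
    """Grow each flank interval downstream by ``sine_len + pad``.

    "Downstream" is in the flank's orientation (genomic right for "+",
    genomic left for "-"); ``strand_naive=True`` always grows to the
    genomic right, mirroring a coordinate-file-only extension.  Intervals
    are clamped to contig bounds.
    """
    grow = sine_len + pad
    out = []
    for iv in intervals:
        if isinstance(iv, MappedFlank):
            genome, origin = iv.target_genome_id, "mapped_flank"
            # unique id: the same copy's flank may map to several places,
            # and the bare copy id already names the query-side locus
            source = [f"map:{iv.flank.copy_id}:{iv.contig}:{iv.start}-{iv.end}{iv.strand}"]
        else:
            genome, origin = iv.genome_id, "query_copy"
            source = [iv.copy_id]
        clen = contig_lengths[iv.contig]
        start, end = _extend_one(clen, iv.start, iv.end, iv.strand, grow, strand_naive)
        out.append(CandidateLocus(
            genome_id=genome, contig=iv.contig, start=start, end=end,
            strand=iv.strand, origin=origin, source_ids=source))
    return out


def fetch_sequence(locus: CandidateLocus, contigs: dict[str, str]) -> str:
    """Locus sequence 5'->3' in the locus orientation (reverse-complemented
    for minus-strand loci)."""
    seq = contigs[locus.contig]
    if not (0 <= locus.start < locus.end <= len(seq)):
        raise InvalidInputError(
            f"locus [{locus.start},{locus.end}) out of bounds on {locus.contig}")
    s = seq[locus.start:locus.end].upper()
    return revcomp(s) if locus.strand == "-" else s
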