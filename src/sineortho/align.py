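"""Alignment primitives: scoring, local/global alignment, seed-and-extend mapper.

Pairwise alignment itself is delegated to Bio.Align.PairwiseAligner; this
module adds the identity bookkeeping used throughout (identities counted
over aligned columns, or over the shorter ungapped sequence) and a k-mer
seed-and-extend mapper used both for the iterative SINE search and for
flank mapping.  The mapper indexes exact k-mers of the target, groups seed
matches into diagonal bands, and runs an affine-gap local alignment of the
query against each candidate window, reporting every alignment above the
score threshold (secondary alignments are deliberately retained:
multimapping flanks are an analysis target, not noise).
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Align import PairwiseAligner
from Bio.Seq import reverse_complement as _rc

from sineortho.types import InvalidInputError

DNA_UPPER = set("ACGT")


def revcomp(seq: str) -> str:
    return _rc(seq)


@dataclass(frozen=True)
class Scoring:
    """Affine-gap DNA scoring; typical local-alignment defaults."""

    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = -12.0
    gap_extend: float = -4.0

    def aligner(self, mode: str, free_end_gaps: bool = False) -> PairwiseAligner:
        a = PairwiseAligner()
        a.mode = mode
        a.match_score = self.match
        a.mismatch_score = self.mismatch
        a.open_gap_score = self.gap_open
        a.extend_gap_score = self.gap_extend
        if free_end_gaps:
            try:
                a.end_insertion_score = 0.0
                a.end_deletion_score = 0.0
            except AttributeError:  # older Biopython naming
                a.target_end_gap_score = 0.0
                a.query_end_gap_score = 0.0
        return a


DEFAULT_SCORING = Scoring()

#: Scoring for whole-locus global alignment: a cheap gap extension so that a
#: missing SINE (a single ~300 nt indel) is represented as one long gap
#: rather than smeared across the other locus as mismatches.
LOCUS_SCORING = Scoring(match=5.0, mismatch=-4.0, gap_open=-12.0, gap_extend=-1.0)


@dataclass
class LocalHit:
    """A local alignment of a query against a target slice."""

    t_start: int
    t_end: int
    q_start: int
    q_end: int
    score: float
    identities: int
    columns: int
    strand: str = "+"

    @property
    def pct_identity(self) -> float:
        return 100.0 * self.identities / self.columns if self.columns else 0.0

    @property
    def q_span(self) -> int:
        return self.q_end - self.q_start


def _alignment_to_hit(aln) -> LocalHit:
    blocks_t, blocks_q = aln.aligned
    counts = aln.counts()
    return LocalHit(
        t_start=int(blocks_t[0][0]), t_end=int(blocks_t[-1][1]),
        q_start=int(blocks_q[0][0]), q_end=int(blocks_q[-1][1]),
        score=float(aln.score),
        identities=int(counts.identities),
        columns=int(counts.identities + counts.mismatches + counts.internal_gaps),
    )


def local_align(query: str, target: str,
                scoring: Scoring = DEFAULT_SCORING) -> LocalHit | None:
    """Best Smith-Waterman alignment of query within target, or None."""
    if not query or not target:
        return None
    aligner = scoring.aligner("local")
    alns = aligner.align(target.upper(), query.upper())
    if len(alns) == 0 or alns[0].score <= 0:
        return None
    aln = alns[0]
    if len(aln.aligned[0]) == 0:
        return None
    return _alignment_to_hit(aln)


def global_alignment(a: str, b: str, scoring: Scoring = DEFAULT_SCORING,
                     free_end_gaps: bool = False):
    """Needleman-Wunsch alignment; returns the Bio.Align.Alignment."""
    if not a or not b:
        raise InvalidInputError("cannot globally align an empty sequence")
    aligner = scoring.aligner("global", free_end_gaps=free_end_gaps)
    return aligner.align(a.upper(), b.upper())[0]


def global_identity(a: str, b: str, scoring: Scoring = DEFAULT_SCORING,
                    denominator: str = "min") -> tuple[float, int]:
    """Percent identity and identical-position count of a global alignment.

    denominator="min" divides by the shorter ungapped sequence length,
    "columns" by the number of aligned (non-terminal-gap) columns.
    """
    aln = global_alignment(a, b, scoring)
    counts = aln.counts()
    ident = int(counts.identities)
    if denominator == "min":
        denom = min(len(a), len(b))
    else:
        denom = int(counts.identities + counts.mismatches + counts.internal_gaps)
    return (100.0 * ident / denom if denom else 0.0), ident


# ---------------------------------------------------------------------------
# Seed-and-extend mapper
# ---------------------------------------------------------------------------

class SeedMapper:
    """Maps queries onto a set of contigs by exact k-mer seeding.

    Lowercase (soft-masked) or non-ACGT target positions never seed a
    match, so iterative search with masking converges; alignment itself
    still sees masked bases as mismatching 'N'.
    """

    def __init__(self, contigs: dict[str, str], k: int = 19,
                 scoring: Scoring = DEFAULT_SCORING,
                 band: int = 64, window_pad: int = 80):
        self.k = k
        self.scoring = scoring
        self.band = band
        self.window_pad = window_pad
        self.contigs = {name: seq for name, seq in contigs.items()}
        self._masks: dict[str, set[int]] = {name: set() for name in contigs}
        self._index: dict[str, list[tuple[str, int]]] = {}
        for name, seq in self.contigs.items():
            for i in range(len(seq) - k + 1):
                kmer = seq[i:i + k]
                if set(kmer) <= DNA_UPPER:  # uppercase ACGT only
                    self._index.setdefault(kmer, []).append((name, i))

    def mask(self, contig: str, start: int, end: int) -> None:
        """Soft-mask a region: excluded from seeding and from extension."""
        self._masks[contig].update(range(start, end))

    def masked_fraction(self, contig: str) -> float:
        return len(self._masks[contig]) / max(1, len(self.contigs[contig]))

    def _window_seq(self, contig: str, start: int, end: int) -> str:
        seq = self.contigs[contig][start:end].upper()
        masked = self._masks[contig]
        if masked:
            chars = list(seq)
            for i in range(start, end):
                if i in masked:
                    chars[i - start] = "N"
            seq = "".join(chars)
        return seq

    def _seed_positions(self, query: str) -> dict[str, list[tuple[int, int]]]:
        """contig -> [(t_pos, q_pos)] for every exact seed match."""
        out: dict[str, list[tuple[int, int]]] = {}
        k = self.k
        for qpos in range(len(query) - k + 1):
            kmer = query[qpos:qpos + k]
            if set(kmer) - DNA_UPPER:
                continue
            for contig, tpos in self._index.get(kmer, ()):  # exact matches
                out.setdefault(contig, []).append((tpos, qpos))
        for contig in out:
            masked = self._masks[contig]
            if masked:
                out[contig] = [(t, q) for t, q in out[contig]
                               if not any(p in masked for p in (t, t + k - 1))]
        return out

    def _windows(self, seeds: list[tuple[int, int]], qlen: int,
                 contig_len: int) -> list[tuple[int, int]]:
        """Group seeds into diagonal bands and emit merged target windows."""
        diag_sorted = sorted(seeds, key=lambda s: (s[0] - s[1], s[0]))
        clusters: list[list[tuple[int, int]]] = []
        for t, q in diag_sorted:
            d = t - q
            if clusters:
                lt, lq = clusters[-1][-1]
                if abs(d - (lt - lq)) <= self.band and abs(t - lt) <= qlen + self.band:
                    clusters[-1].append((t, q))
                    continue
            clusters.append([(t, q)])
        windows = []
        for cl in clusters:
            tmin = min(t - q for t, q in cl)
            tmax = max(t - q for t, q in cl) + qlen
            start = max(0, tmin - self.window_pad)
            end = min(contig_len, tmax + self.window_pad)
            windows.append((start, end))
        # merge overlapping windows
        windows.sort()
        merged = []
        for s, e in windows:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        return [(s, e) for s, e in merged]

    def _align_window(self, query: str, contig: str, w_start: int, w_end: int,
                      min_score: float, max_hits: int) -> list[LocalHit]:
        """All non-overlapping local alignments in a window above min_score."""
        window = list(self._window_seq(contig, w_start, w_end))
        hits: list[LocalHit] = []
        for _ in range(max_hits):
            hit = local_align(query, "".join(window), self.scoring)
            if hit is None or hit.score < min_score:
                break
            hits.append(LocalHit(
                t_start=w_start + hit.t_start, t_end=w_start + hit.t_end,
                q_start=hit.q_start, q_end=hit.q_end, score=hit.score,
                identities=hit.identities, columns=hit.columns))
            for i in range(hit.t_start, hit.t_end):  # blank out and re-align
                window[i] = "N"
        return hits

    def map_query(self, query: str, min_score: float = 60.0,
                  both_strands: bool = True, keep_frac: float = 0.0,
                  max_hits_per_window: int = 8) -> list[LocalHit]:
        """All alignments of the query above ``min_score``.

        With ``keep_frac`` > 0, hits scoring below keep_frac x the best hit
        of this query are dropped (secondary-alignment retention policy).
        Hits carry target-forward coordinates; strand "-" means the reverse
        complement of the query matched.  Each hit's ``contig`` is stored on
        the returned object as attribute ``contig``.
        """
        query = query.upper()
        results: list[LocalHit] = []
        strands = ["+", "-"] if both_strands else ["+"]
        for strand in strands:
            q = query if strand == "+" else revcomp(query)
            if len(q) < self.k:
                continue
            seeds_by_contig = self._seed_positions(q)
            for contig, seeds in seeds_by_contig.items():
                clen = len(self.contigs[contig])
                for w_start, w_end in self._windows(seeds, len(q), clen):
                    for hit in self._align_window(q, contig, w_start, w_end,
                                                  min_score, max_hits_per_window):
                        hit.strand = strand
                        if strand == "-":  # report query span on the + query
                            hit.q_start, hit.q_end = (len(q) - hit.q_end,
                                                      len(q) - hit.q_start)
                        hit.contig = contig  # type: ignore[attr-defined]
                        results.append(hit)
        results = _dedupe(results)
        if keep_frac > 0 and results:
            best = max(h.score for h in results)
            results = [h for h in results if h.score >= keep_frac * best]
        results.sort(key=lambda h: (h.contig, h.t_start, -h.score))  # type: ignore[attr-defined]
        return results


def _dedupe(hits: list[LocalHit]) -> list[LocalHit]:
    """Keep the best-scoring hit among heavily overlapping ones."""
    kept: list[LocalHit] = []
    for h in sorted(hits, key=lambda x: -x.score):
        redundant = False
        for k in kept:
            if k.contig != h.contig:  # type: ignore[attr-defined]
                continue
            ov = min(k.t_end, h.t_end) - max(k.t_start, h.t_start)
            if ov > 0.5 * (h.t_end - h.t_start):
                redundant = True
                break
        if not redundant:
            kept.append(h)
    return kept


def exhaustive_local_hits(query: str, target: str, min_score: float,
                          scoring: Scoring = DEFAULT_SCORING,
                          window: int | None = None,
                          step: int | None = None) -> list[LocalHit]:
    """Sliding-window exhaustive local-alignment reference.

    Independent of the seed-and-extend path: every window of the target is
    aligned, so no hit can be missed by seeding.  Quadratic; suitable for
    targets up to a few tens of kb.
    """
    query = query.upper()
    target = target.upper()
    if window is None:
        window = max(2 * len(query), 200)
    if step is None:
        step = max(window // 4, 1)
    hits: list[LocalHit] = []
    for strand in "+-":
        q = query if strand == "+" else revcomp(query)
        pos = 0
        while pos < len(target):
            sub = target[pos:pos + window]
            h = local_align(q, sub, scoring)
            if h is not None and h.score >= min_score:
                h = LocalHit(t_start=pos + h.t_start, t_end=pos + h.t_end,
                             q_start=h.q_start, q_end=h.q_end, score=h.score,
                             identities=h.identities, columns=h.columns,
                             strand=strand)
                h.contig = "target"  # type: ignore[attr-defined]
                hits.append(h)
            if pos + window >= len(target):
                break
            pos += step
    return _dedupe(hits)
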