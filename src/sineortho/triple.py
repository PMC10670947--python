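"""Triple alignment of a locus pair with the consensus, and PP/PM/MP calls.

For each double (one locus per genome), the two locus sequences are
globally aligned, then the consensus is threaded into that alignment: it
is locally aligned to whichever locus resembles it more, and the resulting
consensus-to-locus correspondence is composed through the pairwise
alignment's columns.  The consensus row's non-gap span defines the SINE
region; columns left and right of it form the left and right flank
segments (LF, RF).  Per segment, ungapped lengths, identical-position
counts and percent identities are computed, with the identity denominator
being the shorter ungapped sequence (the pairwise-identity convention of
alignment statistics tools; an aligned-columns denominator is available).

A pair is discarded when a flank is shorter than 150 nt, when the SINE
region touches either alignment end (no flank on that side), or when a
flank's cross-genome identity falls below 65%.  Otherwise each genome gets
a presence call in the SINE region -- "plus" iff its ungapped length there
is >= 100 nt and its identity to the consensus is >= 65% -- yielding PP,
PM or MP; pairs where neither locus supports the insertion are discarded
as minus_minus.
"""

from __future__ import annotations

from sineortho.align import DEFAULT_SCORING, LOCUS_SCORING, Scoring, global_alignment, local_align
from sineortho.types import (
    STATUS_DISCARDED, STATUS_MP, STATUS_PM, STATUS_PP,
    CandidateLocus, InvalidInputError, PairVerdict, SegmentStats,
    SineConsensus, TripleAlignment,
)


def align_triple(seq_a: str, seq_b: str, consensus: SineConsensus,
                 scoring: Scoring = DEFAULT_SCORING,
                 pair_scoring: Scoring = LOCUS_SCORING,
                 min_anchor_score: float = 60.0) -> TripleAlignment:
    """Build the three-row alignment (locus A, locus B, consensus).

    The consensus row is placed by local alignment against the better
    matching locus and carried into the A-B global alignment's columns;
    consensus bases absent from the anchor locus become insertion columns
    gapped in both loci.  If the consensus aligns to neither locus above
    ``min_anchor_score``, its row is all gaps (sine span of length 0 at
    column 0) and the pair can only be discarded downstream.
    """
    if not seq_a or not seq_b:
        raise InvalidInputError("empty locus sequence")
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    # free end gaps: extracted loci overshoot by construction (the interval
    # extension covers SINE + pad whether or not the SINE is there)
    aln = global_alignment(seq_a, seq_b, pair_scoring, free_end_gaps=True)
    row_a, row_b = str(aln[0]), str(aln[1])

    hit_a = local_align(consensus.sequence, seq_a, scoring)
    hit_b = local_align(consensus.sequence, seq_b, scoring)
    score_a = hit_a.score if hit_a else 0.0
    score_b = hit_b.score if hit_b else 0.0
    if max(score_a, score_b) < min_anchor_score:
        n = len(row_a)
        return TripleAlignment(row_a, row_b, "-" * n, 0, 0)
    anchor = "A" if score_a >= score_b else "B"
    anchor_seq = seq_a if anchor == "A" else seq_b

    # pairwise consensus<->anchor columns, as (anchor_pos, cons_char) plus
    # insertions keyed to the following anchor position
    cons_at: dict[int, str] = {}
    insertions: dict[int, str] = {}
    sub = local_align_full(consensus.sequence, anchor_seq, scoring)
    for a_pos, c_char in sub["matched"]:
        cons_at[a_pos] = c_char
    for a_pos, chars in sub["inserted"].items():
        insertions[a_pos] = chars

    anchor_row = row_a if anchor == "A" else row_b
    out_a, out_b, out_c = [], [], []
    a_pos = 0
    for col in range(len(anchor_row)):
        ca, cb = row_a[col], row_b[col]
        anchor_char = anchor_row[col]
        if anchor_char != "-":
            if a_pos in insertions:
                for ch in insertions[a_pos]:
                    out_a.append("-"); out_b.append("-"); out_c.append(ch)
            out_c.append(cons_at.get(a_pos, "-"))
            a_pos += 1
        else:
            out_c.append("-")
        out_a.append(ca)
        out_b.append(cb)
    if a_pos in insertions:  # trailing consensus insertion
        for ch in insertions[a_pos]:
            out_a.append("-"); out_b.append("-"); out_c.append(ch)

    row_c = "".join(out_c)
    row_a2, row_b2 = "".join(out_a), "".join(out_b)
    nongap = [i for i, ch in enumerate(row_c) if ch != "-"]
    if nongap:
        s, e = nongap[0], nongap[-1] + 1
    else:
        s = e = 0
    return TripleAlignment(row_a2, row_b2, row_c, s, e)


def local_align_full(query: str, target: str, scoring: Scoring):
    """Column-level detail of the consensus-vs-anchor local alignment.

    Returns matched (target_pos, query_char) pairs and query insertions
    (runs of query characters between consecutive target positions).
    """
    aligner = scoring.aligner("local")
    aln = aligner.align(target, query)[0]
    t_idx, q_idx = aln.indices
    matched = []
    inserted: dict[int, str] = {}
    pending = ""
    next_t = None
    for col in range(aln.length):
        t, q = int(t_idx[col]), int(q_idx[col])
        if t >= 0 and q >= 0:
            if pending:
                inserted[t] = inserted.get(t, "") + pending
                pending = ""
            matched.append((t, query[q]))
            next_t = t + 1
        elif q >= 0:  # consensus char not in anchor
            pending += query[q]
    if pending and next_t is not None:
        inserted[next_t] = inserted.get(next_t, "") + pending
    return {"matched": matched, "inserted": inserted}


def _region_stats(region: str, cols_a: str, cols_b: str, cols_c: str,
                  denominator: str = "min") -> SegmentStats:
    len_a = sum(1 for ch in cols_a if ch != "-")
    len_b = sum(1 for ch in cols_b if ch != "-")
    len_c = sum(1 for ch in cols_c if ch != "-")
    ident_ab = sum(1 for x, y in zip(cols_a, cols_b) if x == y and x != "-")
    ident_ac = sum(1 for x, y in zip(cols_a, cols_c) if x == y and x != "-")
    ident_bc = sum(1 for x, y in zip(cols_b, cols_c) if x == y and x != "-")

    def pct(ident: int, la: int, lb: int) -> float:
        if denominator == "min":
            denom = min(la, lb)
        else:
            denom = sum(1 for x, y in zip(cols_a, cols_b) if x != "-" or y != "-")
        return 100.0 * ident / denom if denom else 0.0

    return SegmentStats(
        region=region, len_a=len_a, len_b=len_b,
        identical_ab=ident_ab, pct_ab=pct(ident_ab, len_a, len_b),
        identical_a_cons=ident_ac, pct_a_cons=pct(ident_ac, len_a, len_c),
        identical_b_cons=ident_bc, pct_b_cons=pct(ident_bc, len_b, len_c))


def segment_stats(aln: TripleAlignment,
                  denominator: str = "min") -> dict[str, SegmentStats]:
    """Per-region (LF, SINE, RF) lengths and identities."""
    s, e = aln.sine_start_col, aln.sine_end_col
    out = {}
    for region, (lo, hi) in (("LF", (0, s)), ("SINE", (s, e)), ("RF", (e, aln.n_cols))):
        out[region] = _region_stats(region, aln.row_a[lo:hi], aln.row_b[lo:hi],
                                    aln.row_cons[lo:hi], denominator)
    return out


def classify_pair(stats: dict[str, SegmentStats], aln: TripleAlignment,
                  flank_min_len: int = 150, flank_min_ident: float = 65.0,
                  sine_min_len: int = 100,
                  sine_min_ident: float = 65.0) -> PairVerdict:
    """Apply the discard rules and presence calls to one pair's statistics.

    Boundary comparisons are inclusive: a flank of exactly 150 nt, or an
    identity of exactly 65%, passes.
    """
    lf, sine, rf = stats["LF"], stats["SINE"], stats["RF"]

    if aln.sine_end_col == aln.sine_start_col:
        return PairVerdict(STATUS_DISCARDED, "low_sine_support", stats)
    # a SINE span touching an alignment end means the flank is absent on
    # that side, which outranks the "present but short" reasons
    if aln.sine_start_col == 0:
        return PairVerdict(STATUS_DISCARDED, "leftSINE", stats)
    if aln.sine_end_col == aln.n_cols:
        return PairVerdict(STATUS_DISCARDED, "rightSINE", stats)
    if min(lf.len_a, lf.len_b) < flank_min_len:
        return PairVerdict(STATUS_DISCARDED, "shortLF", stats)
    if min(rf.len_a, rf.len_b) < flank_min_len:
        return PairVerdict(STATUS_DISCARDED, "shortRF", stats)
    if lf.pct_ab < flank_min_ident or rf.pct_ab < flank_min_ident:
        return PairVerdict(STATUS_DISCARDED, "low_flank_identity", stats)

    plus_a = sine.len_a >= sine_min_len and sine.pct_a_cons >= sine_min_ident
    plus_b = sine.len_b >= sine_min_len and sine.pct_b_cons >= sine_min_ident
    if plus_a and plus_b:
        return PairVerdict(STATUS_PP, "none", stats)
    if plus_a:
        # B carries something long but unlike the SINE: flag for export
        foreign = sine.len_b >= sine_min_len
        return PairVerdict(STATUS_PM, "none", stats, foreign_b=foreign)
    if plus_b:
        return PairVerdict(STATUS_MP, "none", stats)
    return PairVerdict(STATUS_DISCARDED, "minus_minus", stats)


def classify_locus_pair(seq_a: str, seq_b: str, consensus: SineConsensus,
                        scoring: Scoring = DEFAULT_SCORING,
                        **thresholds) -> PairVerdict:
    """Convenience wrapper: align, segment and classify in one call."""
    aln = align_triple(seq_a, seq_b, consensus, scoring)
    stats = segment_stats(aln)
    return classify_pair(stats, aln, **thresholds)
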