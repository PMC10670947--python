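"""Resolution of multiple (3-10 locus) cluster groups.

A multiple group usually mixes one true orthologous pair with paralogous
look-alikes pulled in by flank similarity.  The resolver finds the most
similar cross-genome pair by whole-locus global identity, classifies that
pair like an ordinary double, then drops remaining members whose identity
to the pair falls below a threshold.  If only the pair survives, the group
is promoted into the doubles stream; if several comparably similar loci
remain, the group is exported as a multilocus set and excluded from
pairwise statistics.  Poly groups (>10 loci) are never auto-resolved.
"""

from __future__ import annotations

from dataclasses import dataclass

from sineortho.align import DEFAULT_SCORING, Scoring, global_identity
from sineortho.triple import classify_locus_pair
from sineortho.types import (
    STATUS_DISCARDED, CandidateLocus, ClusterGroup, InvalidInputError,
    PairVerdict, SineConsensus,
)


class NoCrossPairError(InvalidInputError):
    """Group has loci from fewer than two genomes."""


def closest_cross_pair(group: ClusterGroup, sequences: dict[str, str],
                       scoring: Scoring = DEFAULT_SCORING,
                       ) -> tuple[CandidateLocus, CandidateLocus, float]:
    """Cross-genome pair maximizing whole-locus percent identity.

    Ties break on higher identical-nucleotide count, then on the
    lexicographically smaller (locus_a_id, locus_b_id), so the result is
    deterministic.
    """
    genomes = sorted({l.genome_id for l in group.loci})
    if len(genomes) < 2:
        raise NoCrossPairError(f"group {group.group_id} spans one genome only")
    ga, gb = genomes[0], genomes[1]
    side_a = sorted((l for l in group.loci if l.genome_id == ga),
                    key=lambda l: l.locus_id)
    side_b = sorted((l for l in group.loci if l.genome_id == gb),
                    key=lambda l: l.locus_id)
    best = None
    for la in side_a:
        for lb in side_b:
            pct, ident = global_identity(sequences[la.locus_id],
                                         sequences[lb.locus_id], scoring)
            key = (-pct, -ident, la.locus_id, lb.locus_id)
            if best is None or key < best[0]:
                best = (key, la, lb, pct)
    _, la, lb, pct = best
    return la, lb, pct


@dataclass
class Resolution:
    """Outcome of resolving one multiple group."""

    outcome: str  # promoted_double | multilocus_set | unresolved
    pair: tuple[CandidateLocus, CandidateLocus] | None = None
    verdict: PairVerdict | None = None
    members: list[CandidateLocus] | None = None


def resolve(group: ClusterGroup, sequences: dict[str, str],
            consensus: SineConsensus, member_sim_threshold: float = 65.0,
            scoring: Scoring = DEFAULT_SCORING) -> Resolution:
    """Resolve one multiple group; poly groups are exported unresolved."""
    if group.category == "poly":
        return Resolution("unresolved", members=group.loci)
    try:
        la, lb, _ = closest_cross_pair(group, sequences, scoring)
    except NoCrossPairError:
        return Resolution("unresolved", members=group.loci)

    verdict = classify_locus_pair(sequences[la.locus_id], sequences[lb.locus_id],
                                  consensus, scoring)
    verdict.locus_a, verdict.locus_b = la, lb
    if verdict.status == STATUS_DISCARDED:
        return Resolution("unresolved", pair=(la, lb), verdict=verdict,
                          members=group.loci)

    survivors = [la, lb]
    for locus in group.loci:
        if locus.locus_id in (la.locus_id, lb.locus_id):
            continue
        seq = sequences[locus.locus_id]
        sim = max(global_identity(seq, sequences[la.locus_id], scoring)[0],
                  global_identity(seq, sequences[lb.locus_id], scoring)[0])
        if sim >= member_sim_threshold:
            survivors.append(locus)
    if len(survivors) == 2:
        return Resolution("promoted_double", pair=(la, lb), verdict=verdict,
                          members=survivors)
    return Resolution("multilocus_set", pair=(la, lb), verdict=verdict,
                      members=survivors)
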