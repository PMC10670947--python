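"""Iterative SINE discovery with masking, plus the proximity filter.

A genome is scanned repeatedly with the family consensus: each pass
collects every local alignment passing the identity and consensus-coverage
thresholds, accepted regions are soft-masked, and the scan repeats until a
pass yields no new accepted copy.  Masked bases strictly increase each
pass, so termination is guaranteed.  Copies closer than 300 bp to another
copy are then removed before flank extraction, because tightly packed
repeats do not provide independent flanking anchors.
"""

from __future__ import annotations

import logging

from sineortho.align import DEFAULT_SCORING, Scoring, SeedMapper
from sineortho.types import IUPAC_DNA, InvalidInputError, SineConsensus, SineHit

log = logging.getLogger(__name__)


def _validate_contigs(contigs: dict[str, str]) -> None:
    for name, seq in contigs.items():
        bad = set(seq.upper()) - IUPAC_DNA
        if bad:
            raise InvalidInputError(
                f"contig {name!r} contains non-IUPAC characters: {sorted(bad)[:5]}")


def scan_genome(contigs: dict[str, str], consensus: SineConsensus,
                genome_id: str = "genome", min_identity: float = 65.0,
                min_coverage: float = 0.80, k: int = 12,
                min_score: float = 40.0,
                scoring: Scoring = DEFAULT_SCORING,
                max_passes: int = 50) -> list[SineHit]:
    """Find all accepted copies of the consensus on both strands.

    Acceptance requires percent identity over the aligned region >=
    ``min_identity`` and aligned consensus span / consensus length >=
    ``min_coverage``.  Returns non-overlapping hits sorted by
    (contig, start).  Lowercase input positions are treated as masked.
    """
    if not contigs:
        return []
    if not isinstance(consensus, SineConsensus):
        consensus = SineConsensus("consensus", consensus)
    _validate_contigs(contigs)

    mapper = SeedMapper(contigs, k=k, scoring=scoring)
    accepted: list[SineHit] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in contigs}

    for pass_no in range(1, max_passes + 1):
        new_hits = []
        for hit in mapper.map_query(consensus.sequence, min_score=min_score):
            coverage = hit.q_span / consensus.length
            if hit.pct_identity < min_identity or coverage < min_coverage:
                continue
            contig = hit.contig  # type: ignore[attr-defined]
            if any(hit.t_start < e and s < hit.t_end for s, e in occupied[contig]):
                continue
            new_hits.append((hit, contig, coverage))
        if not new_hits:
            break
        # greedy non-overlap selection within the pass, best score first
        new_hits.sort(key=lambda x: (-x[0].score, x[1], x[0].t_start))
        for hit, contig, coverage in new_hits:
            if any(hit.t_start < e and s < hit.t_end for s, e in occupied[contig]):
                continue
            occupied[contig].append((hit.t_start, hit.t_end))
            mapper.mask(contig, hit.t_start, hit.t_end)
            accepted.append(SineHit(
                genome_id=genome_id, contig=contig,
                start=hit.t_start, end=hit.t_end, strand=hit.strand,
                pct_identity=hit.pct_identity,
                consensus_coverage=min(1.0, coverage)))
        log.debug("pass %d: %d new copies", pass_no, len(new_hits))

    accepted.sort(key=lambda h: (h.contig, h.start))
    for i, h in enumerate(accepted):
        h.hit_id = f"{genome_id}.{i:05d}"
    return accepted


def filter_proximal(hits: list[SineHit], min_gap: int = 300,
                    keep: str = "none") -> list[SineHit]:
    """Drop copies lying closer than ``min_gap`` to any other copy.

    The gap between two copies on a contig is (later start - earlier end);
    overlapping copies have a negative gap.  By default BOTH members of a
    close pair are removed (``keep="none"``); ``keep="first"`` retains the
    leftmost member of each close pair for sensitivity analysis.
    """
    if min_gap < 0:
        raise InvalidInputError("min_gap must be >= 0")
    if not hits:
        return []
    order = {id(h): i for i, h in enumerate(hits)}
    by_contig: dict[tuple[str, str], list[SineHit]] = {}
    for h in hits:
        by_contig.setdefault((h.genome_id, h.contig), []).append(h)

    doomed: set[int] = set()
    for group in by_contig.values():
        group.sort(key=lambda h: (h.start, h.end))
        for i, a in enumerate(group):
            for b in group[i + 1:]:
                if b.start - a.end >= min_gap:
                    break  # starts only increase from here
                doomed.add(id(b))
                if keep != "first":
                    doomed.add(id(a))
    kept = [h for h in hits if id(h) not in doomed]
    kept.sort(key=lambda h: order[id(h)])
    return kept
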