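"""The pairwise pipeline driver: find -> flank -> map -> cluster -> classify.

``run_pairwise`` chains every stage for one genome pair and returns all
intermediates, so each stage remains inspectable and re-runnable.  The
workflow's standard thresholds are the defaults of :class:`PipelineConfig`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from sineortho import io as sio
from sineortho.align import DEFAULT_SCORING, Scoring
from sineortho.clustering import cluster_overlaps, link_groups
from sineortho.discovery import filter_proximal, scan_genome
from sineortho.flanks import extend_right, extract_left_flanks, fetch_sequence, map_flanks
from sineortho.resolve import resolve
from sineortho.triple import classify_locus_pair
from sineortho.types import (
    STATUS_DISCARDED, CandidateLocus, ClusterGroup, PairVerdict, SineConsensus,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Thresholds and knobs of the pairwise pipeline (printed defaults)."""

    min_identity: float = 65.0      # % identity for an accepted SINE copy
    min_coverage: float = 0.80      # consensus-length fraction for a copy
    min_gap: int = 300              # copies closer than this are excluded
    flank_len: int = 300            # left-flank length
    min_mapped_len: int = 100       # minimum aligned flank length
    pad: int = 300                  # extension beyond the SINE span
    flank_min_len: int = 150        # triple-alignment flank length cut-off
    flank_min_ident: float = 65.0   # flank identity cut-off
    sine_min_len: int = 100         # SINE-region presence length cut-off
    sine_min_ident: float = 65.0    # SINE-region identity cut-offs
    member_sim_threshold: float = 65.0
    discovery_k: int = 12
    mapper_k: int = 19
    mapper_min_score: float = 60.0
    mapper_keep_frac: float = 0.8
    strand_naive_extension: bool = False
    scoring: Scoring = field(default_factory=lambda: DEFAULT_SCORING)


@dataclass
class PairwiseResult:
    """Everything one pairwise comparison produced."""

    genome_a: str
    genome_b: str
    hits: dict[str, list]
    distant: dict[str, list]
    flanks: dict[str, list]
    mappings: list
    merged: dict[str, list[CandidateLocus]]
    groups: list[ClusterGroup]
    verdicts: list[PairVerdict]
    multilocus: list
    unresolved: list
    summary: dict

    def report(self):
        return sio.verdicts_to_frame(self.verdicts, self.genome_a, self.genome_b)


def run_pairwise(contigs_a: dict[str, str], contigs_b: dict[str, str],
                 consensus: SineConsensus, genome_a: str = "A",
                 genome_b: str = "B",
                 config: PipelineConfig | None = None,
                 outdir: str | Path | None = None) -> PairwiseResult:
    """Full pairwise comparison of two genomes against one SINE consensus."""
    cfg = config or PipelineConfig()
    contigs = {genome_a: contigs_a, genome_b: contigs_b}
    clens = {g: {c: len(s) for c, s in cs.items()} for g, cs in contigs.items()}

    hits, distant, flanks = {}, {}, {}
    for g in (genome_a, genome_b):
        found = scan_genome(contigs[g], consensus, genome_id=g,
                            min_identity=cfg.min_identity,
                            min_coverage=cfg.min_coverage,
                            k=cfg.discovery_k, scoring=cfg.scoring)
        hits[g] = found
        distant[g] = filter_proximal(found, cfg.min_gap)
        flanks[g] = extract_left_flanks(distant[g], contigs[g], cfg.flank_len)
        log.info("%s: %d copies, %d distant, %d flanks",
                 g, len(found), len(distant[g]), len(flanks[g]))

    map_ab = map_flanks(flanks[genome_a], contigs_b, genome_b,
                        min_mapped_len=cfg.min_mapped_len, k=cfg.mapper_k,
                        min_score=cfg.mapper_min_score,
                        keep_frac=cfg.mapper_keep_frac, scoring=cfg.scoring)
    map_ba = map_flanks(flanks[genome_b], contigs_a, genome_a,
                        min_mapped_len=cfg.min_mapped_len, k=cfg.mapper_k,
                        min_score=cfg.mapper_min_score,
                        keep_frac=cfg.mapper_keep_frac, scoring=cfg.scoring)
    mappings = map_ab + map_ba

    sine_len = consensus.length
    cand = {
        genome_a: (extend_right(flanks[genome_a], clens[genome_a], sine_len,
                                cfg.pad, cfg.strand_naive_extension)
                   + extend_right([m for m in map_ba], clens[genome_a], sine_len,
                                  cfg.pad, cfg.strand_naive_extension)),
        genome_b: (extend_right(flanks[genome_b], clens[genome_b], sine_len,
                                cfg.pad, cfg.strand_naive_extension)
                   + extend_right([m for m in map_ab], clens[genome_b], sine_len,
                                  cfg.pad, cfg.strand_naive_extension)),
    }
    merged = {g: cluster_overlaps(c) for g, c in cand.items()}
    groups = link_groups(merged[genome_a], merged[genome_b], mappings)

    sequences = {}
    for g in (genome_a, genome_b):
        for locus in merged[g]:
            sequences[locus.locus_id] = fetch_sequence(locus, contigs[g])

    verdicts: list[PairVerdict] = []
    multilocus, unresolved = [], []
    thresholds = dict(flank_min_len=cfg.flank_min_len,
                      flank_min_ident=cfg.flank_min_ident,
                      sine_min_len=cfg.sine_min_len,
                      sine_min_ident=cfg.sine_min_ident)
    n_unpaired = 0
    for group in groups:
        if group.category == "unpaired":
            n_unpaired += 1
            continue
        if group.category == "double":
            la = next(l for l in group.loci if l.genome_id == genome_a)
            lb = next(l for l in group.loci if l.genome_id == genome_b)
            v = classify_locus_pair(sequences[la.locus_id], sequences[lb.locus_id],
                                    consensus, cfg.scoring, **thresholds)
            v.locus_a, v.locus_b = la, lb
            verdicts.append(v)
        else:
            res = resolve(group, sequences, consensus,
                          member_sim_threshold=cfg.member_sim_threshold,
                          scoring=cfg.scoring)
            if res.outcome == "promoted_double" and res.verdict is not None:
                v = res.verdict
                if v.locus_a.genome_id != genome_a:
                    v.locus_a, v.locus_b = v.locus_b, v.locus_a
                verdicts.append(v)
            elif res.outcome == "multilocus_set":
                multilocus.append((group, res))
            else:
                unresolved.append((group, res))

    from sineortho.patterns import summarize_verdicts
    summary = {
        "copies_total": {g: len(hits[g]) for g in hits},
        "copies_distant": {g: len(distant[g]) for g in distant},
        "mappings": len(mappings),
        "merged_loci": {g: len(m) for g, m in merged.items()},
        "groups": _category_counts(groups),
        "unpaired": n_unpaired,
        "verdicts": summarize_verdicts(verdicts),
        "multilocus_sets": len(multilocus),
        "unresolved": len(unresolved),
    }
    result = PairwiseResult(genome_a, genome_b, hits, distant, flanks, mappings,
                            merged, groups, verdicts, multilocus, unresolved,
                            summary)
    if outdir is not None:
        _write_intermediates(result, Path(outdir))
    return result


def _category_counts(groups: list[ClusterGroup]) -> dict[str, int]:
    out: dict[str, int] = {}
    for g in groups:
        out[g.category] = out.get(g.category, 0) + 1
    return dict(sorted(out.items()))


def _write_intermediates(result: PairwiseResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for g in (result.genome_a, result.genome_b):
        sio.hits_to_bed(result.hits[g], outdir / f"{g}.copies.bed")
        sio.hits_to_bed(result.distant[g], outdir / f"{g}.distant.bed")
        sio.loci_to_bed(result.merged[g], outdir / f"{g}.merged.bed")
    sio.write_tsv(result.report(), outdir / "report.tsv")
    groups_rows = []
    for grp in result.groups:
        for locus in grp.loci:
            groups_rows.append({
                "group_id": grp.group_id, "category": grp.category,
                "genome": locus.genome_id, "contig": locus.contig,
                "start": locus.start, "end": locus.end,
            })
    import json

    import pandas as pd
    sio.write_tsv(pd.DataFrame(groups_rows), outdir / "groups.tsv")
    (outdir / "summary.json").write_text(json.dumps(result.summary, indent=2))
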