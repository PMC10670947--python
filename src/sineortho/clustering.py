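"""Overlap clustering of candidate loci and cross-genome group linking.

Within each genome, candidate loci with overlapping coordinates are merged
(transitively, >=1 bp overlap by default, as an interval-merge with default
settings would).  Merged loci of the two genomes are then linked through
the flank mappings that generated them, and connected components of the
link graph become groups, categorized by size: double (2 loci), multiple
(3-10), poly (>10).
"""

from __future__ import annotations

import networkx as nx

from sineortho.types import CandidateLocus, ClusterGroup, InvalidInputError, MappedFlank


def cluster_overlaps(loci: list[CandidateLocus],
                     min_overlap: int = 1) -> list[CandidateLocus]:
    """Merge same-genome, same-contig loci overlapping by >= min_overlap bp.

    Merging is transitive; the merged locus spans the union, carries the
    concatenated member source_ids, and takes the strand of the majority of
    members (ties resolve to '+').
    """
    by_key: dict[tuple[str, str], list[CandidateLocus]] = {}
    for locus in loci:
        by_key.setdefault((locus.genome_id, locus.contig), []).append(locus)

    merged_all: list[CandidateLocus] = []
    for (genome, contig), group in sorted(by_key.items()):
        group.sort(key=lambda l: (l.start, l.end))
        current: list[CandidateLocus] = []
        cur_end = None
        for locus in group:
            if current and locus.start <= cur_end - min_overlap:
                current.append(locus)
                cur_end = max(cur_end, locus.end)
            else:
                if current:
                    merged_all.append(_merge(genome, contig, current))
                current = [locus]
                cur_end = locus.end
        if current:
            merged_all.append(_merge(genome, contig, current))
    return merged_all


def _merge(genome: str, contig: str, members: list[CandidateLocus]) -> CandidateLocus:
    start = min(m.start for m in members)
    end = max(m.end for m in members)
    plus = sum(1 for m in members if m.strand == "+")
    strand = "+" if plus * 2 >= len(members) else "-"
    source_ids = []
    for m in members:
        source_ids.extend(m.source_ids)
    return CandidateLocus(genome_id=genome, contig=contig, start=start, end=end,
                          strand=strand, origin="merged", source_ids=source_ids)


def _locate(merged: list[CandidateLocus], genome: str, contig: str,
            start: int, end: int) -> CandidateLocus:
    for locus in merged:
        if (locus.genome_id == genome and locus.contig == contig
                and start < locus.end and locus.start < end):
            return locus
    raise InvalidInputError(
        f"mapping endpoint {genome}:{contig}:{start}-{end} not inside any merged locus")


def link_groups(merged_a: list[CandidateLocus], merged_b: list[CandidateLocus],
                mappings: list[MappedFlank],
                copy_locus: dict[str, CandidateLocus] | None = None) -> list[ClusterGroup]:
    """Connected components of the locus link graph.

    Every mapping links the merged locus containing its source copy's flank
    to the merged locus containing the mapped interval.  ``copy_locus``
    resolves copy ids to their (pre-merge) query-side candidate loci; when
    omitted, source copy ids are located through merged-locus membership.
    Singleton components (loci with no surviving link) get category
    "unpaired"; linked groups are categorized by size.
    """
    merged = list(merged_a) + list(merged_b)
    by_member: dict[str, CandidateLocus] = {}
    for locus in merged:
        for sid in locus.source_ids:
            by_member.setdefault(sid, locus)

    graph = nx.Graph()
    for locus in merged:
        graph.add_node(locus.locus_id)
    links: list[tuple[str, str]] = []
    for m in mappings:
        src = by_member.get(m.flank.copy_id)
        if src is None and copy_locus is not None:
            src = copy_locus.get(m.flank.copy_id)
        if src is None:
            raise InvalidInputError(f"copy {m.flank.copy_id} not in any merged locus")
        dst = _locate(merged, m.target_genome_id, m.contig, m.start, m.end)
        if src.locus_id == dst.locus_id:
            continue
        graph.add_edge(src.locus_id, dst.locus_id)
        links.append((src.locus_id, dst.locus_id))

    by_id = {l.locus_id: l for l in merged}
    groups = []
    for comp in nx.connected_components(graph):
        loci = sorted((by_id[i] for i in comp),
                      key=lambda l: (l.genome_id, l.contig, l.start))
        comp_links = sorted({(a, b) for a, b in links if a in comp and b in comp})
        groups.append(ClusterGroup(group_id="", loci=loci, links=comp_links,
                                   category=categorize_size(len(loci))))
    groups.sort(key=lambda g: (g.loci[0].genome_id, g.loci[0].contig,
                               g.loci[0].start, len(g.loci)))
    for i, g in enumerate(groups):
        g.group_id = f"G{i:05d}"
    return groups


def categorize_size(n: int) -> str:
    if n < 1:
        raise InvalidInputError("empty group")
    if n == 1:
        return "unpaired"
    if n == 2:
        return "double"
    if n <= 10:
        return "multiple"
    return "poly"


def categorize(group: ClusterGroup) -> str:
    """Category of a formed group: double (2), multiple (3-10), poly (>10)."""
    group.category = categorize_size(len(group.loci))
    return group.category
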