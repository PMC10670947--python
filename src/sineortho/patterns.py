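"""Multi-genome presence/absence patterns and their phylogenetic category.

Pairwise verdict tables that share an anchor genome are joined on
overlapping anchor-genome intervals into per-locus vectors of plus /
minus / unknown over all genomes.  Each vector is then scored against a
given tree topology: the insertion is phylogenetically informative when
the set of insertion-bearing genomes is exactly the leaf set of one clade,
and contradicts the topology when two or more genomes share the insertion
without forming a clade (SINE insertions are effectively homoplasy-free,
so a non-clade sharing pattern conflicts with the tree).
"""

from __future__ import annotations

from itertools import product

import dendropy

from sineortho.types import (
    STATUS_MP, STATUS_PM, STATUS_PP, InvalidInputError, PairVerdict,
    PresencePattern,
)

PLUS, MINUS, UNKNOWN = "plus", "minus", "unknown"


def _anchor_interval(verdict: PairVerdict, anchor_genome: str):
    for locus in (verdict.locus_a, verdict.locus_b):
        if locus is not None and locus.genome_id == anchor_genome:
            return locus.contig, locus.start, locus.end
    return None


def _statuses(verdict: PairVerdict, genome_a: str, genome_b: str) -> dict[str, str]:
    s = verdict.status
    if s == STATUS_PP:
        return {genome_a: PLUS, genome_b: PLUS}
    if s == STATUS_PM:
        return {genome_a: PLUS, genome_b: MINUS}
    if s == STATUS_MP:
        return {genome_a: MINUS, genome_b: PLUS}
    return {}


def join_pairwise(tables: dict[tuple[str, str], list[PairVerdict]],
                  anchor_genome: str | None = None) -> list[PresencePattern]:
    """Join verdict tables sharing one anchor genome into presence vectors.

    ``tables`` maps (genome_a, genome_b) -> verdicts; the anchor genome
    (default: first genome of the first table) must appear in every table.
    Loci are joined when their anchor-genome intervals overlap.  A genome
    reported both plus and minus for the same joined locus becomes unknown
    with the conflict flag set; genomes absent from a locus stay unknown.
    """
    if not tables:
        raise InvalidInputError("no verdict tables to join")
    pairs = list(tables)
    if anchor_genome is None:
        anchor_genome = pairs[0][0]
    for pair in pairs:
        if anchor_genome not in pair:
            raise InvalidInputError(
                f"anchor genome {anchor_genome!r} missing from table {pair}")
    genomes = sorted({g for pair in pairs for g in pair})

    records = []  # (contig, start, end, statuses)
    for (ga, gb), verdicts in tables.items():
        for v in verdicts:
            iv = _anchor_interval(v, anchor_genome)
            st = _statuses(v, ga, gb)
            if iv is None or not st:
                continue
            records.append((iv, st))

    # cluster anchor intervals transitively by overlap
    records.sort(key=lambda r: (r[0][0], r[0][1], r[0][2]))
    clusters: list[list] = []
    cur_contig, cur_end = None, None
    for rec in records:
        (contig, start, end), _ = rec
        if clusters and contig == cur_contig and start < cur_end:
            clusters[-1].append(rec)
            cur_end = max(cur_end, end)
        else:
            clusters.append([rec])
            cur_contig, cur_end = contig, end

    patterns = []
    for idx, cluster in enumerate(clusters):
        status: dict[str, str] = {g: UNKNOWN for g in genomes}
        conflict = False
        for _, st in cluster:
            for genome, call in st.items():
                if status[genome] == UNKNOWN:
                    status[genome] = call
                elif status[genome] != call:
                    status[genome] = UNKNOWN
                    conflict = True
        (contig, start, end), _ = cluster[0]
        patterns.append(PresencePattern(
            locus_id=f"{anchor_genome}:{contig}:{start}-{end}",
            status_by_genome=status, conflict=conflict))
    return patterns


def _clade_sets(topology: str) -> tuple[list[str], set[frozenset[str]]]:
    tree = dendropy.Tree.get(data=topology if topology.endswith(";")
                             else topology + ";", schema="newick")
    taxa = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    clades = set()
    for node in tree.preorder_node_iter():
        leaves = frozenset(l.taxon.label for l in node.leaf_iter())
        clades.add(leaves)
    return taxa, clades


def _category_of(plus_set: frozenset[str], all_taxa: frozenset[str],
                 clades: set[frozenset[str]]) -> str:
    if len(plus_set) == 0:
        return "absent"
    if plus_set == all_taxa:
        return "shared_all"
    if len(plus_set) == 1:
        return "unique"
    if plus_set in clades:
        return "informative"
    return "contradicting"


def classify_pattern(pattern: PresencePattern, topology: str) -> str:
    """Category of a presence vector against a newick topology.

    Categories: shared_all (insertion in every genome), unique (one
    genome), informative (plus-set is a clade), contradicting (non-clade
    plus-set of >=2), absent (no insertion anywhere).  Unknown statuses
    make the pattern "incomplete" unless every completion of the unknowns
    yields the same category.
    """
    taxa, clades = _clade_sets(topology)
    taxa_set = frozenset(taxa)
    for genome in pattern.status_by_genome:
        if genome not in taxa_set:
            raise InvalidInputError(f"genome {genome!r} not in topology")
    known = {g: s for g, s in pattern.status_by_genome.items() if s != UNKNOWN}
    unknown = [g for g, s in pattern.status_by_genome.items() if s == UNKNOWN]
    if len(known) < 2:
        pattern.category = "incomplete"
        return pattern.category

    cats = set()
    for completion in product((PLUS, MINUS), repeat=len(unknown)):
        status = dict(known)
        status.update(dict(zip(unknown, completion)))
        plus_set = frozenset(g for g, s in status.items() if s == PLUS)
        cats.add(_category_of(plus_set, taxa_set, clades))
        if len(cats) > 1:
            break
    pattern.category = cats.pop() if len(cats) == 1 else "incomplete"
    return pattern.category


def summarize_verdicts(verdicts: list[PairVerdict]) -> dict[str, int]:
    """PP/PM/MP/discarded counts for one genome pair."""
    out = {STATUS_PP: 0, STATUS_PM: 0, STATUS_MP: 0, "discarded": 0}
    for v in verdicts:
        key = v.status if v.status in out else "discarded"
        out[key] += 1
    return out


def summarize_patterns(patterns: list[PresencePattern]) -> dict[str, int]:
    """Counts of presence-vector categories (classify first)."""
    out: dict[str, int] = {}
    for p in patterns:
        out[p.category or "unclassified"] = out.get(p.category or "unclassified", 0) + 1
    return dict(sorted(out.items()))
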