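"""Interval merging, cross-genome linking, and group categories."""

import numpy as np
import pytest

from sineortho.clustering import categorize, categorize_size, cluster_overlaps, link_groups
from sineortho.types import CandidateLocus, ClusterGroup, Flank, InvalidInputError, MappedFlank


def _locus(start, end, genome="A", contig="c", src=None):
    return CandidateLocus(genome_id=genome, contig=contig, start=start, end=end,
                          source_ids=src or [f"{genome}:{start}"])


class TestClusterOverlaps:
    def test_one_bp_overlap_merges(self):
        merged = cluster_overlaps([_locus(100, 400), _locus(399, 700)])
        assert len(merged) == 1
        assert (merged[0].start, merged[0].end) == (100, 700)
        assert len(merged[0].source_ids) == 2

    def test_book_ended_intervals_stay_separate(self):
        merged = cluster_overlaps([_locus(100, 400), _locus(400, 700)])
        assert [(m.start, m.end) for m in merged] == [(100, 400), (400, 700)]

    def test_transitive_merge(self):
        merged = cluster_overlaps([_locus(0, 100), _locus(90, 200), _locus(190, 300)])
        assert [(m.start, m.end) for m in merged] == [(0, 300)]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_transitive_overlap_oracle(self, seed):
        rng = np.random.default_rng(seed)
        loci = []
        for i in range(100):
            start = int(rng.integers(0, 5_000))
            loci.append(_locus(start, start + int(rng.integers(1, 400)),
                               src=[f"s{i}"]))
        merged = cluster_overlaps(loci)
        # brute-force O(n^2) oracle: union-find over pairwise overlaps
        parent = list(range(len(loci)))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i, a in enumerate(loci):
            for j, b in enumerate(loci):
                if i < j and a.start < b.end and b.start < a.end:
                    parent[find(i)] = find(j)
        comps = {}
        for i, l in enumerate(loci):
            comps.setdefault(find(i), []).append(l)
        expected = sorted((min(c.start for c in comp), max(c.end for c in comp))
                          for comp in comps.values())
        assert sorted((m.start, m.end) for m in merged) == expected
        assert sum(len(m.source_ids) for m in merged) == len(loci)


def _mapping(copy_id, target_genome, start, end):
    fl = Flank(copy_id=copy_id, genome_id="A" if target_genome == "B" else "B",
               contig="c", start=0, end=300, strand="+", sequence="A" * 300)
    return MappedFlank(flank=fl, target_genome_id=target_genome, contig="c",
                       start=start, end=end, strand="+", aligned_length=300,
                       score=1000.0)


class TestLinkGroups:
    def test_single_link_forms_double(self):
        a = [CandidateLocus("A", "c", 0, 900, source_ids=["a1"])]
        b = [CandidateLocus("B", "c", 0, 900, source_ids=["m1"])]
        groups = link_groups(a, b, [_mapping("a1", "B", 100, 400)])
        assert len(groups) == 1
        assert groups[0].category == "double"

    def test_shared_nodes_connect_transitively(self):
        # A1<->B1, A1<->B2, B2<->A2: one group of four
        a = [CandidateLocus("A", "c", 0, 900, source_ids=["a1"]),
             CandidateLocus("A", "c", 5000, 5900, source_ids=["a2"])]
        b = [CandidateLocus("B", "c", 0, 900, source_ids=["b1"]),
             CandidateLocus("B", "c", 5000, 5900, source_ids=["b2"])]
        mappings = [_mapping("a1", "B", 100, 400),
                    _mapping("a1", "B", 5100, 5400),
                    _mapping("b2", "A", 5100, 5400)]
        groups = link_groups(a, b, mappings)
        assert len(groups) == 1
        assert len(groups[0].loci) == 4
        assert groups[0].category == "multiple"

    def test_twelve_linked_loci_form_poly_group(self):
        a = [CandidateLocus("A", "c", i * 1000, i * 1000 + 900,
                            source_ids=[f"a{i}"]) for i in range(6)]
        b = [CandidateLocus("B", "c", i * 1000, i * 1000 + 900,
                            source_ids=[f"b{i}"]) for i in range(6)]
        mappings = [_mapping(f"a{i}", "B", j * 1000 + 100, j * 1000 + 400)
                    for i in range(6) for j in range(6)]
        groups = link_groups(a, b, mappings)
        assert len(groups) == 1
        assert len(groups[0].loci) == 12
        assert groups[0].category == "poly"

    def test_unresolvable_endpoint_raises(self):
        a = [CandidateLocus("A", "c", 0, 900, source_ids=["a1"])]
        b = [CandidateLocus("B", "c", 0, 900, source_ids=["b1"])]
        with pytest.raises(InvalidInputError):
            link_groups(a, b, [_mapping("a1", "B", 5_000, 5_300)])

    def test_partition_and_determinism_under_permutation(self):
        rng = np.random.default_rng(3)
        a = [CandidateLocus("A", "c", i * 1000, i * 1000 + 900,
                            source_ids=[f"a{i}"]) for i in range(20)]
        b = [CandidateLocus("B", "c", i * 1000, i * 1000 + 900,
                            source_ids=[f"b{i}"]) for i in range(20)]
        mappings = [_mapping(f"a{i}", "B", int(j) * 1000 + 100, int(j) * 1000 + 400)
                    for i, j in zip(range(20), rng.integers(0, 20, 20))]
        groups = link_groups(a, b, mappings)
        n_loci = sum(len(g.loci) for g in groups)
        assert n_loci == 40  # every locus in exactly one component
        ids = {l.locus_id for g in groups for l in g.loci}
        assert len(ids) == 40

        perm = rng.permutation(20)
        groups2 = link_groups([a[i] for i in perm], [b[i] for i in perm],
                              [mappings[i] for i in perm])
        key = [(g.group_id, [l.locus_id for l in g.loci]) for g in groups]
        key2 = [(g.group_id, [l.locus_id for l in g.loci]) for g in groups2]
        assert key == key2

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_union_find_component_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = 50
        a = [CandidateLocus("A", "c", i * 1000, i * 1000 + 900,
                            source_ids=[f"a{i}"]) for i in range(n)]
        b = [CandidateLocus("B", "c", i * 1000, i * 1000 + 900,
                            source_ids=[f"b{i}"]) for i in range(n)]
        edges = [(int(i), int(j)) for i, j in
                 zip(rng.integers(0, n, 80), rng.integers(0, n, 80))]
        mappings = [_mapping(f"a{i}", "B", j * 1000 + 100, j * 1000 + 400)
                    for i, j in edges]
        groups = link_groups(a, b, mappings)
        # hand-rolled union-find oracle over the same bipartite edges
        parent = list(range(2 * n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i, j in edges:
            parent[find(i)] = find(n + j)
        comps = {}
        for i in range(2 * n):
            comps.setdefault(find(i), set()).add(i)
        expected = sorted(tuple(sorted(c)) for c in comps.values())
        got = []
        for g in groups:
            members = set()
            for l in g.loci:
                idx = int(l.source_ids[0][1:])
                members.add(idx if l.genome_id == "A" else n + idx)
            got.append(tuple(sorted(members)))
        assert sorted(got) == expected


def test_categorize_size_boundaries():
    assert categorize_size(2) == "double"
    assert categorize_size(3) == "multiple"
    assert categorize_size(10) == "multiple"
    assert categorize_size(11) == "poly"
    group = ClusterGroup("g", [_locus(0, 10), _locus(20, 30)], [])
    assert categorize(group) == "double"
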