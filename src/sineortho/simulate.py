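"""Synthetic genome sets with planted SINE loci and a ground-truth table.

Each planted locus starts as an ancestral left flank / (optional SINE) /
right flank triple at the root of a tree topology and evolves down every
branch with uniform substitutions and geometric-length indels.  The SINE
copy is gained on a designated branch, which realizes every structural
class: orthologous presence in both genomes (PP), presence in only one
(PM/MP), presence in a clade (informative), in all genomes (shared_all),
in one genome (unique), or in a non-clade set of genomes via independent
insertions (contradicting).  Decoy paralogous flanks can be planted to
produce multimapper clusters, loci can be clipped at contig edges, and a
minus allele can carry an unrelated filler sequence where the SINE would
sit.  Everything is deterministic under the config seed.

The simulator emulates the locus structure the pipeline reasons about; it
does not model target-site duplications, poly-A tails, GC heterogeneity or
nested repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from sineortho.types import InvalidInputError, SineConsensus

BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimulationConfig:
    """Conditions of a simulated genome set.

    Rates are per site per branch; ``divergence`` is the expected pairwise
    flank divergence between two genomes in 2-genome mode (half is applied
    to each branch).  ``n_loci`` maps class names to counts; 2-genome
    classes are PP, PM, MP, multimapper and edge_truncated, tree classes
    are shared_all, unique, informative and contradicting.
    """

    seed: int = 1
    genome_ids: tuple[str, ...] = ("A", "B")
    topology: str = ""  # default: 2-genome "(A,B)" or the given ids
    n_loci: dict[str, int] = field(default_factory=lambda: {"PP": 50, "PM": 30, "MP": 30})
    divergence: float = 0.05
    branch_length: float = 0.02  # tree mode, branches without lengths
    indel_rate: float = 0.002
    indel_mean_len: float = 3.0
    sine_divergence: float = 0.05
    flank_len: int = 300
    sine_len: int = 360
    spacer_min: int = 600
    spacer_max: int = 1200
    foreign_fraction: float = 0.2  # minus alleles carrying unrelated filler
    decoys_per_multimapper: int = 3
    # decoy flank vs the contemporary true flank; after lineage divergence a
    # decoy sits near 85% identity to the query flank, high enough to map
    # under the 0.8x-best secondary retention yet far below the ortholog
    decoy_divergence: float = 0.10
    consensus_name: str = "SINE_sim"

    def __post_init__(self):
        for name, rate in (("divergence", self.divergence),
                           ("indel_rate", self.indel_rate),
                           ("sine_divergence", self.sine_divergence),
                           ("decoy_divergence", self.decoy_divergence)):
            if not (0 <= rate < 0.5):
                raise InvalidInputError(f"{name} must be in [0, 0.5)")
        if any(n < 0 for n in self.n_loci.values()):
            raise InvalidInputError("locus counts must be >= 0")
        if len(self.genome_ids) < 2:
            raise InvalidInputError("need at least two genomes")
        if not self.topology:
            self.topology = "(" + ",".join(self.genome_ids) + ")"


@dataclass
class TruthRecord:
    """Ground truth for one planted locus."""

    locus_id: str
    klass: str
    coords: dict[str, tuple[str, int, int]]  # genome -> (contig, start, end)
    presence: dict[str, bool]

    def expected_status(self, genome_a: str, genome_b: str) -> str:
        pa, pb = self.presence.get(genome_a), self.presence.get(genome_b)
        if pa and pb:
            return "PP"
        if pa:
            return "PM"
        if pb:
            return "MP"
        return "discarded"


def random_dna(rng: np.random.Generator, n: int) -> str:
    return rng.choice(BASES, size=n).tobytes().decode()


def mutate(rng: np.random.Generator, seq: str, sub_rate: float,
           indel_rate: float = 0.0, indel_mean_len: float = 3.0) -> str:
    """Uniform substitutions plus geometric-length insertions/deletions."""
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    n = len(arr)
    if n == 0:
        return seq
    hit = rng.random(n) < sub_rate
    for i in np.flatnonzero(hit):
        choices = BASES[BASES != arr[i]]
        arr[i] = rng.choice(choices)
    out = arr.tobytes().decode()
    if indel_rate > 0:
        p = 1.0 / indel_mean_len
        chars = list(out)
        sites = np.flatnonzero(rng.random(len(chars)) < indel_rate)
        for i in sites[::-1]:  # right-to-left keeps indices valid
            length = int(rng.geometric(p))
            if rng.random() < 0.5:
                del chars[i:i + length]
            else:
                chars[i:i] = list(random_dna(rng, length))
        out = "".join(chars)
    return out


@dataclass
class _LocusSpec:
    locus_id: str
    klass: str
    parts: dict[str, tuple[str, str | None, str]]  # leaf -> (LF, MID, RF)
    presence: dict[str, bool]
    decoy_flanks: dict[str, list[str]] = field(default_factory=dict)
    edge_truncated: bool = False


class _TreeModel:
    """Topology with per-branch rates, evolving (LF, MID, RF) triples."""

    def __init__(self, config: SimulationConfig):
        self.cfg = config
        data = config.topology if config.topology.endswith(";") else config.topology + ";"
        self.tree = dendropy.Tree.get(data=data, schema="newick")
        self.leaves = [l.taxon.label for l in self.tree.leaf_node_iter()]
        if set(self.leaves) != set(config.genome_ids):
            raise InvalidInputError("topology leaves do not match genome_ids")
        two = len(config.genome_ids) == 2
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None:
                edge.rate = float(edge.length)
            elif two:
                edge.rate = config.divergence / 2.0
            else:
                edge.rate = config.branch_length

    def internal_nonroot(self):
        root = self.tree.seed_node
        for node in self.tree.preorder_node_iter():
            if node is not root and not node.is_leaf():
                return node
        return None

    def noncladal_leaf_pair(self):
        """Two leaves that do not form a clade (for homoplasy loci)."""
        clades = {frozenset(l.taxon.label for l in n.leaf_iter())
                  for n in self.tree.preorder_node_iter()}
        leaves = sorted(self.leaves)
        for i, a in enumerate(leaves):
            for b in leaves[i + 1:]:
                if frozenset((a, b)) not in clades:
                    return a, b
        return None

    def evolve_locus(self, rng: np.random.Generator, lf: str, rf: str,
                     gain_nodes, sine_seq_for, foreign_leaves: set[str],
                     sine_len: int) -> dict[str, tuple[str, str | None, str]]:
        """Propagate a locus down the tree; returns leaf -> (LF, MID, RF).

        ``gain_nodes`` is the set of nodes at which the insertion appears
        (each gain is an independent copy from ``sine_seq_for(node)``).
        """
        cfg = self.cfg
        out = {}

        def descend(node, lf_seq, mid_seq, rf_seq):
            if node in gain_nodes:
                mid_seq = sine_seq_for(node)
            if node.is_leaf():
                label = node.taxon.label
                mid = mid_seq
                if mid is None and label in foreign_leaves:
                    mid = random_dna(rng, sine_len)
                out[label] = (lf_seq, mid, rf_seq)
                return
            for child in node.child_nodes():
                r = child.edge.rate
                c_lf = mutate(rng, lf_seq, r, cfg.indel_rate, cfg.indel_mean_len)
                c_rf = mutate(rng, rf_seq, r, cfg.indel_rate, cfg.indel_mean_len)
                c_mid = (mutate(rng, mid_seq, r, cfg.indel_rate, cfg.indel_mean_len)
                         if mid_seq is not None else None)
                descend(child, c_lf, c_mid, c_rf)

        descend(self.tree.seed_node, lf, None, rf)
        return out


def simulate(config: SimulationConfig):
    """Generate genomes and truth for the configured locus classes.

    Returns (genomes, truth, consensus): ``genomes`` maps genome_id ->
    {contig: sequence}, ``truth`` is a list of TruthRecord, and
    ``consensus`` is the simulated family consensus used for planting.
    """
    rng = np.random.default_rng(config.seed)
    model = _TreeModel(config)
    consensus = SineConsensus(config.consensus_name, random_dna(rng, config.sine_len))
    root = model.tree.seed_node
    leaf_nodes = {l.taxon.label: l for l in model.tree.leaf_node_iter()}

    specs: list[_LocusSpec] = []
    counter = 0
    for klass in sorted(config.n_loci):
        for i in range(config.n_loci[klass]):
            locus_id = f"L{counter:05d}_{klass}"
            counter += 1
            lf = random_dna(rng, config.flank_len)
            rf = random_dna(rng, config.flank_len)

            presence = {g: False for g in config.genome_ids}
            foreign: set[str] = set()
            gains = set()
            if klass in ("PP", "shared_all", "multimapper", "edge_truncated"):
                gains = {root}
            elif klass == "PM":
                gains = {leaf_nodes[config.genome_ids[0]]}
            elif klass == "MP":
                gains = {leaf_nodes[config.genome_ids[1]]}
            elif klass == "unique":
                label = model.leaves[i % len(model.leaves)]
                gains = {leaf_nodes[label]}
            elif klass == "informative":
                node = model.internal_nonroot()
                if node is None:
                    raise InvalidInputError("topology has no internal clade")
                gains = {node}
            elif klass == "contradicting":
                pair = model.noncladal_leaf_pair()
                if pair is None:
                    raise InvalidInputError("topology has no non-clade leaf pair")
                gains = {leaf_nodes[pair[0]], leaf_nodes[pair[1]]}
            else:
                raise InvalidInputError(f"unknown locus class {klass!r}")

            if klass in ("PM", "MP") and rng.random() < config.foreign_fraction:
                foreign = {g for g in config.genome_ids
                           if leaf_nodes[g] not in gains}

            def sine_seq_for(node, _rng=rng):
                return mutate(_rng, consensus.sequence, config.sine_divergence)

            parts = model.evolve_locus(rng, lf, rf, gains, sine_seq_for,
                                       foreign, config.sine_len)
            for g, (_, mid, _) in parts.items():
                gained = any(n is leaf_nodes[g] or n in _ancestors(leaf_nodes[g])
                             for n in gains)
                presence[g] = gained

            spec = _LocusSpec(locus_id, klass, parts, presence,
                              edge_truncated=(klass == "edge_truncated"))
            if klass == "multimapper":
                target = config.genome_ids[1]
                decoys = []
                for _ in range(config.decoys_per_multimapper):
                    decoy_lf = mutate(rng, parts[target][0], config.decoy_divergence)
                    decoys.append(decoy_lf + random_dna(
                        rng, config.sine_len + config.flank_len))
                spec.decoy_flanks[target] = decoys
            specs.append(spec)

    genomes: dict[str, dict[str, str]] = {}
    truth = [TruthRecord(s.locus_id, s.klass, {}, dict(s.presence)) for s in specs]
    order = rng.permutation(len(specs))  # same locus order in every genome
    edge_no = {idx: n for n, idx in
               enumerate(i for i, s in enumerate(specs) if s.edge_truncated)}

    def spacer() -> str:
        return random_dna(rng, int(rng.integers(config.spacer_min,
                                                config.spacer_max + 1)))

    for genome in config.genome_ids:
        chunks: list[str] = []
        pos = 0
        coords: dict[int, tuple[str, int, int]] = {}
        for idx in order:
            spec = specs[idx]
            lf, mid, rf = spec.parts[genome]
            if spec.edge_truncated:
                # dedicated contig; in the first genome the locus starts the
                # contig with a clipped left flank, exercising edge clamps
                contig = f"edge{edge_no[idx]}"
                if genome == config.genome_ids[0]:
                    lf = lf[-120:]
                    seq = lf + (mid or "") + rf
                    genomes.setdefault(genome, {})[contig] = seq + random_dna(rng, 400)
                    coords[idx] = (contig, 0, len(seq))
                else:
                    lead = spacer()
                    seq = lf + (mid or "") + rf
                    genomes.setdefault(genome, {})[contig] = lead + seq + random_dna(rng, 400)
                    coords[idx] = (contig, len(lead), len(lead) + len(seq))
                continue
            gap = spacer()
            chunks.append(gap)
            pos += len(gap)
            locus_seq = lf + (mid or "") + rf
            coords[idx] = ("chr1", pos, pos + len(locus_seq))
            chunks.append(locus_seq)
            pos += len(locus_seq)
            for decoy in spec.decoy_flanks.get(genome, ()):
                gap = spacer()
                chunks.append(gap)
                pos += len(gap)
                chunks.append(decoy)
                pos += len(decoy)
        chunks.append(spacer())
        genomes.setdefault(genome, {})["chr1"] = "".join(chunks)
        for idx, (contig, start, end) in coords.items():
            truth[idx].coords[genome] = (contig, start, end)

    truth.sort(key=lambda t: t.locus_id)
    return genomes, truth, consensus


def _ancestors(node):
    out = set()
    p = node.parent_node
    while p is not None:
        out.add(p)
        p = p.parent_node
    return out


# ---------------------------------------------------------------------------
# Truth-vs-report evaluation
# ---------------------------------------------------------------------------

def evaluate(truth: list[TruthRecord], verdicts, genome_a: str, genome_b: str):
    """Confusion matrix and per-class metrics of a pairwise run vs truth.

    ``verdicts`` are PairVerdicts with locus_a/locus_b coordinates set.
    Pipeline pairs are matched to truth loci by coordinate overlap in
    genome A (falling back to genome B for MP loci absent from A's copy
    set); unmatched pipeline pairs count as false positives.
    """
    from intervaltree import IntervalTree

    trees: dict[tuple[str, str], IntervalTree] = {}
    for i, t in enumerate(truth):
        for genome in (genome_a, genome_b):
            if genome in t.coords:
                contig, start, end = t.coords[genome]
                trees.setdefault((genome, contig), IntervalTree())[start:end] = i

    statuses = ("PP", "PM", "MP")
    confusion = {ts: {ps: 0 for ps in statuses + ("discarded", "missed")}
                 for ts in statuses}
    false_positives = 0
    seen: dict[int, str] = {}
    for v in verdicts:
        matched = None
        for genome, locus in ((genome_a, v.locus_a), (genome_b, v.locus_b)):
            if locus is None:
                continue
            tree = trees.get((genome, locus.contig))
            if tree:
                ovl = tree.overlap(locus.start, locus.end)
                if ovl:
                    matched = max(ovl, key=lambda iv: iv.end - iv.begin).data
                    break
        if matched is None:
            false_positives += 1
            continue
        seen[matched] = v.status
    for i, t in enumerate(truth):
        expected = t.expected_status(genome_a, genome_b)
        if expected not in statuses:
            continue
        got = seen.get(i, "missed")
        if got not in confusion[expected]:
            got = "discarded"
        confusion[expected][got] += 1

    n_correct = sum(confusion[s][s] for s in statuses)
    n_total = sum(sum(row.values()) for row in confusion.values())
    per_class = {}
    for s in statuses:
        tp = confusion[s][s]
        fn = sum(confusion[s].values()) - tp
        fp = sum(confusion[o][s] for o in statuses if o != s)
        per_class[s] = {
            "recall": tp / (tp + fn) if tp + fn else 0.0,
            "precision": tp / (tp + fp) if tp + fp else 0.0,
        }
    return {
        "confusion": confusion,
        "accuracy": n_correct / n_total if n_total else 0.0,
        "per_class": per_class,
        "false_positives": false_positives,
    }


def truth_to_rows(truth: list[TruthRecord]) -> list[dict]:
    """Flatten truth records for TSV export."""
    rows = []
    for t in truth:
        row = {"locus_id": t.locus_id, "class": t.klass}
        for genome, (contig, start, end) in sorted(t.coords.items()):
            row[f"{genome}_contig"] = contig
            row[f"{genome}_start"] = start
            row[f"{genome}_end"] = end
        for genome, present in sorted(t.presence.items()):
            row[f"{genome}_present"] = "plus" if present else "minus"
        rows.append(row)
    return rows
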