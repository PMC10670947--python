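"""Find SINE copies in a simulated genome and apply the proximity filter.

Builds a small genome with planted copies of a simulated SINE consensus,
scans it with the iterative masked search, and prints each accepted copy
with its identity and consensus coverage.
"""

from sineortho import SineConsensus, filter_proximal, scan_genome
from sineortho.simulate import SimulationConfig, simulate

cfg = SimulationConfig(seed=4, n_loci={"PP": 6, "PM": 2})
genomes, truth, consensus = simulate(cfg)

hits = scan_genome(genomes["A"], consensus, genome_id="A")
distant = filter_proximal(hits, min_gap=300)

print(f"consensus: {consensus.name}, {consensus.length} nt")
print(f"{len(hits)} copies found, {len(distant)} remain after the 300-bp "
      "proximity filter\n")
for h in distant:
    print(f"  {h.hit_id}  {h.contig}:{h.start}-{h.end} ({h.strand})  "
          f"identity {h.pct_identity:.1f}%  coverage {h.consensus_coverage:.2f}")
print("\nEach line is one accepted SINE copy: genomic interval, strand, "
      "percent identity to the consensus over the aligned region, and the "
      "fraction of the consensus covered (acceptance needs >=65% and >=0.80).")
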