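# sineortho

Detection and comparison of orthologous SINE-containing loci across
assembled genomes.

## The problem

Short interspersed elements (SINEs) are non-autonomous retrotransposons
present in tens to hundreds of thousands of copies per genome. A SINE
insertion at a given genomic site is an essentially homoplasy-free event:
once inserted, it is almost never excised precisely, so the pattern of
presence/absence of an insertion at orthologous sites across species is a
near-ideal shared derived character for phylogenetics. The hard part is
computational: finding every copy in each assembly, deciding which sites in
two genomes are the *same* (orthologous) locus without a whole-genome
alignment, and calling presence or absence reliably in the face of
truncated copies, diverged flanks, and flanks that map to many places.

`sineortho` implements a flank-anchored workflow for this, aimed at
comparisons of two to four assemblies (the package was designed around
squamate reptile genomes and the Squam1 SINE family, but is
family-agnostic):

1. **Discovery** — iterative local-alignment search of a family consensus
   against each genome with masking of accepted copies, until no new copy
   is found. A copy is accepted at >=65% identity over the aligned region
   and >=80% consensus coverage. Copies closer than 300 bp to another copy
   are excluded (their flanks are not independent anchors).
2. **Flank anchoring** — the 300-bp left flank (in SINE orientation) of
   each copy is extracted and mapped reciprocally to the other genome on
   both strands; all alignments of >=100 aligned bp are kept, including
   multimappers. Mapped and query intervals are extended downstream by
   SINE length + 300 bp to cover the putative insertion and right flank.
3. **Clustering** — per genome, overlapping candidate intervals are merged;
   merged loci are linked through the flank mappings and connected
   components form groups: *doubles* (2 loci), *multiples* (3–10), and
   *poly* (>10, exported for inspection, never auto-resolved).
4. **Classification** — for each double, a triple alignment (locus A,
   locus B, consensus) is segmented into left flank / SINE / right flank.
   Pairs with a flank shorter than 150 nt, a SINE span touching the
   alignment end, or flank identity below 65% are discarded. Each genome
   gets a presence call in the SINE region (>=100 nt at >=65% identity to
   the consensus), yielding **PP** (insertion in both), **PM** (first
   only), or **MP** (second only).
5. **Multicopy resolution** — in a multiple group, the most similar
   cross-genome pair (whole-locus global identity) is classified like a
   double; remaining members below 65% identity to the pair are dropped.
   If only the pair survives it is promoted into the doubles stream.
6. **Multi-genome patterns** — pairwise verdict tables sharing an anchor
   genome are joined by anchor-interval overlap into per-locus
   presence/absence vectors, classified against a newick topology:
   `shared_all`, `unique`, `informative` (the plus-set is a clade),
   `contradicting` (it is not), or `incomplete`.

A bundled simulator (`sineortho.simulate`) generates genome sets with
planted loci of every structural class plus a ground-truth table, so the
whole pipeline is testable without downloads.

## Worked example

```python
from sineortho import run_pairwise
from sineortho.simulate import SimulationConfig, evaluate, simulate

cfg = SimulationConfig(seed=4, n_loci={"PP": 8, "PM": 4, "MP": 4, "multimapper": 2})
genomes, truth, consensus = simulate(cfg)
result = run_pairwise(genomes["A"], genomes["B"], consensus, "A", "B")
print(result.summary["verdicts"])
```

prints

```
{'PP': 9, 'PM': 4, 'MP': 4, 'discarded': 0}
```

i.e. all planted polymorphic loci were recovered (one multimapper group was
resolved and promoted, giving 8+1 PP). A classified pair carries its
segment statistics; a planted PM locus looks like

```
PM  A:chr1:6651-7611 <-> B:chr1:6414-7370
    LF 300/296 nt, 96.6% | SINE 360/0 nt, A-cons 96.4%, B-cons 0.0% | RF 300/660 nt, 95.3%
```

— the flanks align at ~96% identity in both genomes, genome A carries a
360-nt SINE at 96% identity to the consensus, and genome B has nothing in
the SINE region: a polymorphic insertion, usable as a derived character.
(`evaluate(truth, result.verdicts, "A", "B")` scores the run against the
planted truth.) The scripts in `examples/` walk through discovery, a full
pairwise comparison, and a four-genome pattern analysis; the same stages
are available from the shell via the `sine-ortho` CLI
(`find`, `flanks`, `map`, `simulate`, `run`, `combine`, `summarize`).

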