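# Methods

This note documents the models, conventions and numerical choices behind
`sineortho`, what the simulator does and does not emulate, and the known
limitations.

## Coordinates and identity conventions

All coordinates are 0-based half-open on the forward strand (BED
convention); minus-strand features keep forward coordinates with a strand
field. Sequence identity is reported in two conventions:

- **Alignment identity** (discovery, mapping): identical positions divided
  by aligned columns (matches + mismatches + internal gaps) of the local
  alignment, x100.
- **Pairwise segment identity** (triple-alignment statistics, resolver):
  identical aligned positions divided by the *shorter ungapped* sequence
  length of the segment, x100 — the convention of common
  alignment-statistics tools. An aligned-columns denominator is available
  (`segment_stats(..., denominator="columns")`); the min-length form is
  more conservative for segments of unequal length, which is what the
  presence/absence decision needs.

All threshold comparisons are inclusive: a flank of exactly 150 nt, or an
identity of exactly 65%, passes. Nothing in the data dictates strictness
at the boundary; inclusive comparison makes the printed threshold the last
accepted value.

## Alignment engine

Pairwise alignment is Biopython's `PairwiseAligner`. Two scoring schemes
are used:

- **Search scoring** (discovery and flank mapping): match +5, mismatch −4,
  gap open −12, gap extend −4 — ordinary DNA local-alignment weights. The
  acceptance thresholds, not the matrix, carry the scientific content, and
  are exposed separately.
- **Locus scoring** (whole-locus global alignment): same substitution
  weights but gap extend −1, with free end gaps. The reason is structural:
  a locus missing the SINE differs from its partner by one ~300+ nt
  indel. At extend −4 that indel costs more than mismatching the entire
  SINE against unrelated sequence, so the aligner would smear the absence
  across the alignment and destroy the flank/SINE segmentation; at
  extend −1 the single long gap wins, which is the biologically correct
  representation. Free end gaps absorb the deliberate overshoot of
  extracted loci (the interval extension covers SINE + 300 bp whether or
  not the insertion is there).

The internal mapper is exact-k-mer seed-and-extend: k-mers of the target
are indexed (k=19 for flank mapping, k=12 for discovery, where higher
divergence must still seed); seed matches are grouped into diagonal bands,
merged into windows, and each window is aligned locally, iterating with
in-window masking so several copies per window are all reported. Secondary
alignments are kept down to 0.8x the flank's best score (multimapping is
an analysis target here, not noise to suppress); an absolute score floor
of 60 removes chance seeds. Soft-masked (lowercase) or non-ACGT positions
never seed. The same interface accepts an externally constructed mapper,
so a short-read mapper backend can be substituted for full-scale runs.

Seeding bounds sensitivity: an exact k-mer must survive in the copy, so at
k=19 copies beyond ~15% divergence are found unreliably, and at k=12 the
practical discovery limit is ~20–25% divergence. The 65% acceptance
threshold is therefore sharp as a *filter* (an aligned copy at 64.7% is
rejected), while *recall* near the threshold is seed-limited — the same
trade-off any seeded search has.

## Discovery

The genome is scanned repeatedly with the consensus; each pass accepts
every non-overlapping alignment with identity >=65% and consensus coverage
>=80%, soft-masks the accepted intervals, and repeats until a pass finds
nothing new. Masked bases strictly increase, so termination is guaranteed;
masking is soft so coordinates never shift. Tandem or nested copies
surface in later passes once their neighbours are masked.

The proximity filter removes every copy whose end-to-start gap to any
other copy on the contig is below 300 bp — *both* members of a close pair,
since neither copy's flank is then an independent single-locus anchor. A
`keep="first"` mode retains the leftmost member for sensitivity analysis.

## Flanks, extension, clustering

The orthology anchor is the 300-bp flank upstream of the copy in the
SINE's own orientation; minus-strand copies yield the reverse complement
of the genomic right flank. Flanks truncated by a contig edge are emitted
short and flagged; zero-length flanks are dropped with a warning.

"Mapping in both directions" is implemented as reciprocal mapping
(A-flanks -> B and B-flanks -> A), each direction searching both target
strands; the two mapping tables are then combined, which is what makes the
link graph symmetric. Mapped intervals shorter than 100 aligned bp are
discarded. Each flank interval — query-side and mapped — is extended
downstream (strand-aware; a strand-naive compatibility flag reproduces a
coordinate-file-only extension) by SINE length + 300 bp, clamped to contig
bounds, so the candidate interval covers the putative insertion and right
flank.

Per genome, candidate intervals overlapping by >=1 bp merge transitively
(configurable minimum overlap). Merged loci become nodes; every mapping
contributes an edge from the merged locus containing the source copy's
flank to the merged locus containing the mapped interval. Connected
components are the groups: doubles (2 loci) go straight to
classification, multiples (3–10) to the resolver, poly groups (>10) are
exported unresolved — their flanks contain repeats whose homology cannot
be asserted automatically. Exact self-coordinate hits (a flank finding
itself when a genome is compared with itself under one id) are excluded.
Loci with no surviving link are reported as "unpaired": absence of a
mappable ortholog, not absence of the insertion.

## Triple alignment and classification

For a pair of locus sequences (each oriented by its locus strand), the
two loci are aligned globally (locus scoring, free end gaps), and the
consensus row is placed by composition: the consensus is locally aligned
to whichever locus matches it better, and that correspondence is threaded
through the columns of the pairwise alignment, with consensus bases absent
from the anchor becoming insertion columns gapped in both loci. This is a
deterministic stand-in for aligning the consensus to the A×B profile and
gives the identical segmentation whenever the consensus matches either
locus at all; if it aligns to neither above score 60, the pair is
discarded as `low_sine_support`.

The SINE region is the consensus row's non-gap column span — the only
segmentation computable from the alignment itself. Columns left and right
of it are the LF and RF segments. Discard rules, in order: SINE span
touching the first/last column (`leftSINE`/`rightSINE` — the flank is
absent on that side; checked first because an absent flank would otherwise
always masquerade as a short one), flank shorter than 150 nt in either
row (`shortLF`/`shortRF`, using the min of the two rows), flank identity
below 65% (`low_flank_identity`). Presence per genome: the row's ungapped
length in the SINE region >=100 nt *and* its identity to the consensus
>=65%. Both present = PP, first only = PM, second only = MP; neither =
`minus_minus`, discarded rather than counted as polymorphic (it usually
means a truncated query copy failed its own presence call). A minus row
that still carries >=100 nt of sequence in the SINE region is flagged
(`foreign_b`) — an unrelated filler of similar length, exportable for
follow-up.

## Multicopy resolution

The closest cross-genome pair by whole-locus global identity (ties: more
identical nucleotides, then lexicographic locus ids — fully deterministic)
is classified like a double. Remaining members with identity to the pair
below 65% are dropped; the 65% reuses the universal identity threshold
since no separate value is dictated by the problem. If exactly the pair
survives, it is promoted; if more survive, the group is exported as a
multilocus set and excluded from pairwise statistics. Whole-locus identity
against the min-length denominator has a high random baseline (~50–55%
for unrelated sequence of equal length, because global alignment with
affine gaps pairs many positions by chance), so unrelated decoys sit near
45–65% and genuinely straddle the member threshold, while true orthologs
sit above 90% — the discrimination comes from the gap, not the absolute
value.

## Multi-genome patterns

Verdict tables sharing an anchor genome are joined by transitive overlap
of their anchor-genome intervals. Per genome, plus/minus calls are taken
from the verdicts (PP: both plus; PM: anchor plus, other minus; MP:
reverse); a genome reported both plus and minus for one joined locus
becomes `unknown` with a conflict flag, and genomes absent from a table
stay `unknown` — absence of an ortholog call is never treated as absence
of the insertion.

A pattern's category against a rooted newick topology: `absent` (no plus),
`shared_all`, `unique` (one plus), `informative` (the plus-set equals the
leaf set of a clade), else `contradicting` (a non-clade plus-set of >=2
implies more than one insertion event or a precise loss). Unknown statuses
are handled by enumerating all completions: if every completion yields the
same category it is used, otherwise the pattern is `incomplete`. Note the
anchor-join consequence: an insertion unique to a *non-anchor* genome is
seen in only one pairwise table, leaves the other genomes unknown, and
honestly classifies `incomplete` rather than `unique`.

## Simulator

The simulator evolves each planted locus — ancestral left flank /
optional SINE / right flank — down a tree topology with uniform
substitutions and geometric-length indels (mean 3 nt) per branch, gaining
an independent consensus-derived copy on a designated branch per class:
root (PP/shared_all), a single leaf (PM/MP/unique, rotating leaves), the
first internal clade (informative), or two non-sister leaves
(contradicting, i.e. simulated homoplasy). Defaults: 5% pairwise flank
divergence (half per branch in 2-genome mode), 5% SINE-to-consensus
divergence, indel rate 0.002/site/branch, 300-bp flanks, 360-nt consensus,
loci separated by 600–1200 bp random spacers on one contig, default class
mix 50 PP + 30 PM + 30 MP. A fraction (20%) of minus alleles carry an
unrelated random filler of SINE-like length instead of a clean absence.
Multimapper loci add decoys to the second genome: a copy of the true flank
at 10% divergence (~85% identity to the mapped query flank — high enough
to survive the 0.8x-best secondary retention, far below the ortholog)
followed by random sequence. Edge-truncated loci sit at position 0 of
dedicated small contigs with the left flank clipped to 120 bp. Everything
is driven by one `numpy` generator, so a config + seed fixes all outputs
byte for byte.

What the simulator does *not* emulate — and what passing tests therefore
do not show about real data: target-site duplications and poly-A tails,
GC and repeat-landscape heterogeneity, nested/fragmented repeats, SINE
subfamily structure, assembly gaps and base-call errors, and genome
rearrangement (locus order is conserved). Real genomes will yield far more
discarded pairs, unpaired loci and poly groups than the simulation does.

## Problem sizes

The shipped configurations are desk-scale by design: simulated genomes of
~100–200 kb with tens to a hundred planted loci, a 200-replicate resolver
experiment, and oracle comparisons on targets up to ~40 kb. The pipeline
itself is O(copies x genome) in seeding and O(pairs) in classification;
full-genome runs are supported through the same interfaces with an
external mapper backend, but are not part of the test suite.

## Known limitations

- Orthology rests on one 300-bp flank; tandem expansions or flank-resident
  repeats produce multiples/poly groups rather than confident calls.
- No TSD or breakpoint calling, no insertion dating, no subfamily
  classification; the consensus is an input.
- The pattern join is anchor-centric (see above); loci absent from the
  anchor genome are invisible to the multi-genome analysis.
- Chimeric merged loci are not split; oversized merges surface as poly
  groups, which is a report, not a resolution.
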