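# Methods

## Problem setting and model

`genereconcile` reconciles two gene prediction sets derived from successive
assemblies of the same genome.  The working assumptions are:

* the two versions describe the same underlying gene complement, so most
  genes have exactly one counterpart with near-identical sequence;
* discrepancies come from a small number of structural causes — a locus
  predicted as one gene in one version and several in the other (splits,
  merges, artificial chimeras), tandem repeats collapsed in the
  lower-coverage assembly, assembly-level rearrangements (inverted segments,
  scaffold reassignments), and genes placed on the artificial "unknown"
  chromosome;
* absolute chromosome coordinates are not comparable across assemblies, but
  local gene order is largely conserved, and cross-species protein evidence
  is an arbiter for one-to-many topologies: a real gene is covered by one
  protein; an artificial chimera shows distinct proteins on disjoint
  regions.

The pipeline is deliberately rule-based rather than probabilistic: each
decision corresponds to an explicit, inspectable predicate, which is what a
manual curation workflow needs.

## Matching

Hits (internal aligner or external 12-column tabular input) pass three
stringency filters, applied with **strict** inequalities: percent identity
> 95, e-value < 1e-20, and, per query, only the top 4 hits by bit score.
Bit-score ties break by higher identity, longer alignment, then
lexicographic subject id (the ordering must be total for reproducibility).
In transcript (EST) mode an alignment-length floor of 100 bp replaces the
neighbor-gene context that genomic comparisons enjoy.  Both query/subject
directions are computed and unioned into one edge per gene pair, with the
per-gene alignment hull and a direction flag retained; how the two
directional hit sets combine is an interpretation (the source procedure runs
both directions but does not state the merge), so the union is recorded
explicitly per edge.

A candidate one-to-one pair is *consistent* when it and the nearest paired
neighbor on either side (in newer-version gene order) map to adjacent genes
in older-version order.  "Adjacent" tolerates `max_skip` (default 1)
intervening genes without a one-to-one partner, so newly predicted or
dropped genes do not break every neighborhood.  Pairs whose gene sits alone
on a scaffold, or with no reachable paired neighbor, are *untestable* — never
inconsistent.

## Internal aligner

A desk-scale seed-and-extend local aligner stands in for a full genomic
aligner when only sequences are given: exact 16-mer seeds via a sorted-hash
index, per-(subject, diagonal) clustering with a 100-diagonal merge band,
ungapped X-drop extension (X = 20) on single-diagonal clusters, and banded
edit-distance refinement (edlib) when a cluster spans several diagonals
(i.e. contains indels).  Both query strands are searched; minus-strand hits
are reported with descending subject coordinates.  Scoring is +1 match, −2
mismatch, −3 per gap column.  The e-value is a **surrogate**: a
Karlin–Altschul-style `E = m·n·2^(−bits)` with fixed λ = 1.28, K = 0.46.
It is monotone in the raw score and adequate for thresholding but is not a
calibrated database statistic; when calibrated statistics matter, supply
external tabular hits (sequences above 50 kb are refused with exactly that
instruction).

## Cardinality classification

Per connected component of the bipartite match graph:

1. **One-to-one** components are `OK`.  Neighbor-inconsistent pairs whose
   score *density* (raw alignment score per aligned column, recovered from
   the bit score) falls below the 5th percentile of the consistent pairs'
   densities are `low_score`.  Density rather than total bit score is used
   so that long genes are not punished — a perfect alignment has density 1
   regardless of length.
2. **Hubs** (degree ≥ 2) are tested for whether their partners hit the
   *same portion* (every pairwise reciprocal overlap ≥ 50% of the shorter
   interval), *different portions* (every overlap below it) or a *mixed*
   pattern.
3. A component with ≥ 2 structural conditions (or any mixed hub) is
   `multiple`; no precedence order is invented for these.  For the classic
   two-by-two complex topology the three candidate corrections (keep, move a
   portion, merge) are enumerated with the protein evidence that would
   decide each.
4. Older-side same-portion hubs make the newer genes `redundant` (collapsed
   tandem repeats).  The mirrored case — several older genes on the same
   portion of one newer gene — is deliberately *not* interpreted as
   redundancy, because an error in the older, lower-coverage prediction is
   the more likely cause; such components are reported
   `unresolved_ambiguous`.
5. Different-portion hubs are resolved by protein evidence.  The
   multiple-distinct-proteins test runs **before** the single-spanning-
   protein test: a chimera with one long part can cover ≥ 60% of the locus
   with a single protein, so testing the spanning predicate first would
   misclassify skewed chimeras.  A protein "supports a part" when its hit
   covers ≥ 60% of the protein's length; parts are distinct when their
   intervals overlap < 20% of the shorter part; a protein "spans" when its
   hit covers ≥ 60% of the union interval.  All three fractions are
   configurable (`ClassifyPolicy`); no published values exist for them.
6. Components that need evidence but lack it are `unresolved_ambiguous`
   with `evidence="none"` — never guessed.
7. Evidence is restricted by default to proteins flagged as
   existence-demonstrated at the protein level; a flag relaxes this.

Split proposals: a k-part chimera keeps its id and adds k−1 records suffixed
`_2`, `_3` (the suffix convention is documented for `_2`; `_3` extends it to
triples).  Proposals whose part intervals overlap beyond the 20% tolerance
are rejected and the call downgraded to unresolved rather than emitting a
broken split.

Every non-repeat-track gene in both versions receives exactly one call;
older-side genes in a structural component carry the component's label under
their own version tag so the partition invariant holds on both sides, while
the headline taxonomy reads off the newer version's calls.  Repeat-track
genes are excluded from matching by default (they are speculative, masked
models); `include_repeat=True` re-admits them.

## Positional analysis

Positions are normalized to percent of chromosome length (gene midpoint /
chromosome length, length inferred as the max gene end unless supplied).
Pair categories partition the matched pairs: `unknown_involved` (either side
on the unknown chromosome; takes precedence), `same_chrom` (both placed on
the same chromosome), `different_or_random` (everything else).
Modifications: unknown → placed (newly placed from unknown), random → placed
on the same base chromosome (newly positioned), any other cross-chromosome
pair (reassigned, with per-flow counts).

Inversions are detected as **maximal contiguous runs** (minimum 3 pairs,
configurable) over same-chromosome pairs sorted by newer-version order in
which the older-version order is strictly decreasing — a strict-order rule
rather than a windowed rank-correlation, because it is exact on the signal
of interest and cannot fire on noise at zero divergence.  Unmatched genes
are simply absent from the pair list, so they never break a run; reversing
both coordinate systems yields no runs (a global reflection is not an
inversion).  The per-run rank correlation is reported as the orientation
score.  Display conventions for plots (random chromosomes at 1/10 scale,
unknown chromosome magnified 20×) are applied only in `plot_positions`,
never in computation.

## Unification and categorization

The unified set is seeded with the highest-priority source and complemented
with genes from each successive source not identified in a higher one;
groups are connected components over the supplied cross-matches, and each
group's unique ID comes from its highest-priority member.  Annotation
transfers outright across clean one-to-one pairs; *every* gene with a
cardinality issue (or without a counterpart) is flagged `needs_review` for
independent re-annotation.  When a group unites genes with conflicting prior
annotations, the higher-priority source wins.

The four-group classification of best cross-species hits (known function /
unknown function / viral-or-transposable / no hit) is keyword-based; the
default transposon/viral keyword list (transposon, retrotransposon,
transposase, gag, pol, polyprotein, integrase, reverse transcriptase, viral,
virus) is a configurable argument, since only the class — not its detection
rule — is established.  Category catalogs are dotted-code hierarchies of up
to 8 levels (parents implied by the code); a gene may carry at most 7
categories, and rollups count a gene once per distinct ancestor at every
level.

## Synthetic benchmark

The generator derives versions A (older) and B (newer) from a random
ancestral complement.  Defaults are the package's standard benchmark
conditions: 2 chromosomes × 250 genes; 20 events each of split-in-B,
merge-in-B, tandem-expansion, chimera-in-B (5 triple) and chimera-in-A;
3 inversion blocks (6–14 genes); 10 relocations; 30 unplacements; zero
divergence; full protein-level evidence.  Open quantities were fixed once
at field-plausible desk scale: gene lengths log-uniform 300–3000 bp,
intergenic spacing uniform 200–2000 bp, minimum split-part length 150 bp.

Design choices that matter for interpretation:

* the alphabet is uppercase ACGT and divergence `d` applies substitutions
  only (no indels), to the B copy only — so cross-version identity is
  analytically 100·(1−d)% and the 95% filter threshold has a predictable
  relationship to `d`;
* structural events occupy disjoint ancestral genes, so each planted event
  maps to exactly one expected call and precision/recall are well defined;
* evidence proteins are nucleotide cDNA-like stand-ins (the ancestral
  sequence); the classifier's evidence predicates are interval-based and
  agnostic to the alphabet;
* chimeras fuse adjacent genes, splits cut at a uniform breakpoint at least
  150 bp from each end, inverted blocks reverse both order and strand,
  unplacements move the gene to the unknown chromosome in A only.

What the generator does **not** emulate — and hence what passing benchmarks
do not show about real data: indel divergence and alignment ambiguity,
repeat families and paralogous domain sharing (the main source of spurious
links in real comparisons), compound events on one locus (available behind
`allow-compound`-style manual configs by planting overlapping events, but
not the default), biased gene spacing, partial protein evidence with wrong
proteins, and annotation pipeline artifacts such as UTR disagreements.
Benchmarks here certify the bookkeeping and the decision rules, not
performance on a real genome pair.

Determinism: one `numpy` generator seeded from the config drives every
draw; identical configs give byte-identical outputs.

## Numerical and degenerate-input choices

* Coordinates are 1-based inclusive throughout (GFF convention); both
  versions are assumed to use the same base convention.
* The unknown-chromosome label (`chrUn`) and random-chromosome suffix
  (`_random`) are configurable, since assembly naming schemes vary.
* Strict threshold inequalities mean ties at exactly 95.0% identity or
  exactly 1e-20 are rejected.
* The low-score floor comparison carries a 1e-6 absolute slack to absorb
  float noise in the bit-score round trip.
* Empty inputs flow through: filtering an empty hit list, classifying a
  graph with isolated nodes (all `unmatched`), zero chimeras (zero
  proposals) are all defined, not errors.  Zero-length chromosomes and
  infeasible simulation configs are rejected up front.
* Benchmark problem sizes (500 ancestral genes; five seeds for the
  divergence sweep) were chosen as the smallest sizes at which every event
  class has enough instances (≥ 10) for per-class precision/recall to be
  meaningful.

## Known limitations

* The aligner's e-value is a surrogate (see above); identity and bit score
  are the trustworthy quantities.
* `low_score` depends on the score distribution of the consistent pairs in
  the same run; it is a relative flag, not an absolute quality call.
* The neighbor rule examines the nearest paired neighbor on each side only;
  deep tandem arrays of unpaired genes (beyond `max_skip`) render pairs
  untestable rather than resolving them.
* Inversion runs require strictly decreasing order; a single mis-sorted
  gene inside a real inverted segment splits the run in two.  Run-merging
  across small interruptions is intentionally left to the caller
  (`min_run` is the only knob).
* Proposed splits and merges are emitted as proposals; the package never
  rewrites input annotations.
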