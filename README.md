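# genereconcile

Reconcile gene model predictions between two assembly versions of a genome.

When a genome assembly is upgraded (higher sequence coverage, a revised gene
prediction pipeline), the community inherits two incompatible gene catalogs:
years of functional annotation hang off the old gene IDs, while new arrays
and sequencing resources use the new ones.  Mapping one catalog onto the
other by sequence homology alone is not enough — paralogous domains weave a
many-to-many web of links, and each prediction set contains its own split,
merged and chimeric gene models.  `genereconcile` is a toolkit for working
through that web: it is written for genome annotators and comparative
genomicists who need to transfer annotation between assembly versions and to
flag the loci where the predictions disagree.

## The method

Two gene sets (an older version *A* and a newer version *B*) are compared by
nucleotide homology in both directions.  Hits are kept only under high
stringency — identity strictly above 95%, e-value strictly below 1e-20, at
most the four best matches per query — and putative identities are validated
by **gene-order consistency**: at least two consecutively positioned genes
in *B* must hit two consecutive genes in *A*, since absolute coordinates
cannot be trusted across assemblies.

The filtered hits form a bipartite match graph.  The number of partners a
gene has is its **cardinality** |gene B| = {gene A₁ … gene Aₙ} = n, and each
connected component is classified:

| call | topology | meaning |
|---|---|---|
| `OK` / `low_score` | 1 ↔ 1 | clean pair (low score = suspicious but consistent) |
| `redundant` | many B → one A, same portion | tandem repeats collapsed in A |
| `overlap` | many B → one A, different portions, one spanning protein | B wrongly split; reassemble |
| `split` | same topology, one distinct protein per B gene | A was an artificial chimera |
| `merged` | one B → many A, one spanning protein | B correctly merged an over-split locus |
| `to_split` | one B → many A, k ≥ 2 distinct proteins on disjoint regions | B is an artificial chimera |
| `multiple` | ≥ 2 of the above conditions | complex case, resolutions enumerated |
| `unmatched` | degree 0 | no counterpart |

Chimera resolution uses cross-species protein evidence: a k-part chimera
yields k−1 proposed new gene records suffixed `_2`, `_3`, … after the source
ID.  One-to-one pairs then feed a positional analysis on percent-of-
chromosome coordinates: pairs are categorized (same chromosome / unknown
chromosome involved / different-or-random), placement improvements and
chromosome reassignments are labelled, and inverted assembly segments are
detected as maximal gene-order runs whose order reverses between versions.
Finally, several gene sources can be unified into a non-redundant catalog
under a priority order, with annotation transfer, re-review flags for every
gene with a cardinality issue, four-group functional classification and
hierarchical category rollups.

Because real assembly pairs come without ground truth, the package ships a
synthetic generator (`simulate_pair`) that derives two versions from a
common ancestral gene complement by planting known edit events — splits,
merges, tandem expansions, double/triple chimeras in either version, block
inversions, chromosome relocations, unplacements — so every classification
is scoreable against the event log.

## Worked example

```bash
python examples/simulate_and_classify.py
```

simulates the standard benchmark (2 chromosomes × 250 ancestral genes, 20
planted events per structural class, zero divergence) and reconciles the two
versions:

```
version A: 500 genes, version B: 515 genes, 500 evidence proteins

cardinality calls (version B):
  OK            355
  overlap        40
  redundant      40
  split          40
  to_split       20
  merged         20
...
split proposals: 20 chimeras (5 triple) -> 25 proposed new gene records

recovery against the planted events (precision / recall):
  tandem_expand_in_B   1.00 / 1.00
  split_in_B           1.00 / 1.00
  ...
  invert_block         1.00 / 1.00
```

Every planted event class is recovered perfectly: the 20 two-gene splits
appear as 40 `overlap` calls, the 20 tandem expansions as 40 `redundant`
calls, the 20 newer-version chimeras (5 of them triple) as 20 `to_split`
calls proposing 20·1 + 5·1 = 25 new gene records, and the three planted
inversion blocks surface as exactly three order-reversal runs.

Other entry points: `examples/split_accounting.py` (chimera arithmetic),
`examples/positions_and_inversions.py` (positional categories and runs),
`examples/unify_and_categorize.py` (multi-source unification and category
rollup).  A thin CLI covers the shell workflow:

```bash
reconcile simulate --out sim/ --seed 9 --genes-per-chromosome 60
reconcile run --genes-a sim/genes_A.gff3 --genes-b sim/genes_B.gff3 \
              --seq-a sim/genes_A.fasta --seq-b sim/genes_B.fasta \
              --proteins sim/proteins.fasta --out out/
```

## Layout

```
src/genereconcile/
  models.py       domain types (GeneModel, MatchHit, calls, records)
  io_formats.py   FASTA / GFF3-or-TSV gene tables / 12-column hits / TSV tables
  aligner.py      small-scale seeded nucleotide aligner (internal stand-in)
  matching.py     stringency filters, top-k truncation, neighbor consistency
  cardinality.py  match graph, cardinality classification, split proposals
  positions.py    percent positions, pair categories, inversion runs
  integration.py  unified set, Venn regions, annotation transfer, catalog
  synthetic.py    ground-truth assembly-pair generator and recovery scoring
  pipeline.py     end-to-end reconcile_pair()
```

See `docs/methods.md` for the model's assumptions, tunable parameters and
known limitations.
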