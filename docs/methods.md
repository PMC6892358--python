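# Methods

## The block model and its assumptions

syntenykit detects *framed, collinear* synteny blocks: maximal runs of
ortholog anchors whose positional indices in the comparison genome are
strictly sequential (±1 per step) while both genomes stay on the same
chromosome. This is a gene-order model, not a sequence-alignment model. Its
assumptions, and what follows from them:

- **Anchors only.** Ordinals are assigned only to genes that survive the
  one-to-one reduction of the ortholog relation. Unpaired genes are invisible
  to the scan, so an unannotated gene interleaved between two anchors never
  breaks a run. This is deliberate: numbering every gene would shatter blocks
  wherever annotation density differs between genomes.
- **One-to-one orthology.** The scan needs a function from reference ordinals
  to comparison ordinals. Input relations may be many-to-many; two reduction
  policies are provided. `drop_ambiguous` (default) removes every gene
  involved in a multi-mapping — conservative, and symmetric between genomes.
  `keep_first_by_position` keeps, for each gene, the positionally first
  partner, then enforces injectivity on the other side the same way; it keeps
  more anchors at the cost of an arbitrary (but deterministic) choice.
- **Strand is ignored.** Block orientation is defined by the direction of the
  comparison-index run, not by gene strands; strands are parsed and stored for
  display but play no role in detection.
- **Strictly consecutive vs monotonic runs.** The default requires ordinal
  steps of exactly ±1 ("sequential indices"). A `mode="monotonic"` variant
  accepts any step of constant sign, merging blocks across local scrambling;
  it exists for exploration and is not used by any default pipeline.
- **Singleton runs.** Orientation needs at least two indices. With the default
  `min_anchors=2` single-anchor runs are dropped; at `min_anchors=1` they are
  emitted with orientation `+` by convention.
- **Tie-breaks.** Genes sharing (chromosome, start) are ordered by end, then
  feature ID, making ordinal assignment — and therefore the entire pipeline —
  deterministic. Chromosome names are compared as strings everywhere, and the
  same comparator is used on both the detection path and the ground-truth
  path of the simulator.

Block boundaries are the outer limits of member genes, so blocks on the same
chromosome may leave gaps (intergenic runs without anchors) but never overlap
on their anchor sets: with `min_anchors=1` the blocks partition the anchors.

Coordinates are 1-based inclusive throughout (the GFF3 convention); the block
file format and all region queries inherit this, and interval touching at a
single base counts as overlap.

## Interval mapping granularity

A reference interval maps to (a) the full comparison span of each overlapping
block and (b) an *anchor-trimmed* span — the hull of comparison genes whose
reference partners overlap the interval. No within-block base-pair
interpolation is attempted because the model defines no coordinate system
inside a block; for fine-grained mapping the anchor hull is the honest
resolution limit. For inverted blocks the trimmed hull moves toward the
block's far end as the reference window advances, which the tests check.

## Ontology and annotation semantics

- Closure follows `is_a` and `part_of` edges only, matching common
  GO-browser convention; `regulates`-family edges are ignored.
- A term query retrieves genes annotated to the term or any descendant
  (true-path rule). Closure can be disabled per call (`closure=False`), but
  the default is on: published term searches return genes annotated at more
  specific descendant terms.
- `NOT`-qualified GAF rows are excluded from retrieval and kept in a separate
  negative list (exportable as TSV).
- All evidence codes are accepted, including IEA; no evidence filter is
  applied anywhere.
- MP and DO associations are ingested through the same 17-column GAF 2.x
  reader as GO; term-source routing is by the ontology named in each genome's
  config.
- Term lookup accepts IDs, names, and synonyms, case-insensitively; an
  ambiguous name resolves to the lexicographically first ID with a warning.

## Filter scoping

The display filter evaluates clauses (symbol, feature type, term) over a
*display set*: reference features overlapping the selected region plus
comparison features inside the comparison spans of blocks that the region
overlaps. Comparison-side restriction is block-driven rather than a
comparison-coordinate window, because the block detail view is block-driven.
Scopes:

- `either` — a feature matches by its own annotation (`self`) or via any
  ortholog's annotation in the other genome (`via_ortholog`).
- `reference` / `comparison` — clauses are evaluated against one genome's
  annotations only, but matches are still reported on both tracks through
  orthology (that is how a browser highlights both displays); provenance
  records which side supplied the evidence.

These definitions make the scope algebra exact: the (feature, clause) match
set under `either` is the union of the sets under the two single-genome
scopes, a property the suite asserts on every fixture. "Boolean operators"
is implemented as one top-level AND/OR over clauses, not an expression tree —
sufficient for a filter-panel interface and easily extended. The
"exclude non-matching features" toggle is display metadata carried on the
match table; it never changes the rows.

## Synthetic data

`simulate_genome_pair` builds genome A as identity gene order (evenly spaced
5 kb genes every 10 kb) and derives genome B by planting segment inversions
and translocations on gene boundaries (segments of ≥ 2 genes). The expected
block decomposition is reconstructed directly from the final arrangement by a
self-contained positional walk, independent of the anchor-index machinery
under test, and the planted-recovery suite demands exact equality of spans,
orientations, and counts. `random_dag` emits rank-ordered OBO DAGs that are
acyclic by construction.

The two walkthrough bundles encode the published candidate-gene scenarios:

- **lung** — reference human chr6 with the 6q23–25 interval
  (130,300,000–161,000,000), the eleven *positive regulation of cell death*
  genes (PRKN annotated in mouse only; MYB and TIAM2 in human only; the other
  eight in both) interleaved with ten unannotated decoys, five annotated
  genes outside the interval, and mouse orthologs on chr17 in reversed order
  so the interval's block is an inversion.
- **t2dm** — reference mouse chr2 with the *T2dm2sa* QTL
  (29,417,935–148,533,014) as a QTL-type feature, the published MP-term gene
  lists inside the interval, MP-annotated genes outside it, and a human
  syntenic interval split across chr11/chr20/chr2 (one segment inverted)
  carrying the three DO *type 2 diabetes mellitus* genes plus decoys
  annotated to a parent term, a NOT-qualified association, and one annotated
  human gene outside every block span.

One published gene list names thirteen genes but prints twelve symbols; the
fixture encodes the twelve printed symbols and the replay asserts twelve.
Toy ontologies give every queried term one parent and one child, with at
least one gene annotated only at the child, so each replay exercises closure.

What these fixtures do *not* emulate: realistic gene density or spacing,
overlapping genes, many-to-many ortholog families, assembly gaps, unplaced
scaffolds, annotation noise, or genome-scale block counts. Passing replays
show the query semantics are right on interval-scale data with planted truth;
they say nothing about performance or edge behavior on full genome releases,
which the quarterly-refresh data model (ETL into SQLite, read-only queries)
is nevertheless designed for.

## Storage and endpoints

Loaders run in a fixed order (features + blocks, ontologies, annotations,
config/provenance) into one SQLite file; re-running replaces content rather
than appending, and per-source row counts and drop counts are recorded in a
provenance table. Annotations citing genes absent from the features table are
dropped and counted. Endpoints are read-only, return documents stamped with
`schema_version: 1`, and report bad input as structured error documents with
HTTP-style codes rather than exceptions; the CLI prints the same JSON, and
the suite asserts endpoint output equals the corresponding library call's
serialization on every fixture. An HTTP wrapper would be a thin layer over
`QueryService` and is intentionally out of scope here.

## Problem sizes and numerical choices

The randomized suites use sizes chosen to exercise the combinatorics while
keeping the whole suite interactive: 1,000 random permutations of n ≤ 50 for
the detection/enumeration cross-check, 100 planted scenarios of 40 genes on 3
chromosomes with 0–5 inversions and translocations, and 100 random 200-term
DAGs for closure. All randomness is seeded; the hypothesis property tests run
derandomized. There are no floating-point quantities anywhere in the core —
coordinates, ordinals, and counts are integers, so every comparison in the
suite is exact equality.

## Known limitations

- Two genomes only; no multi-genome chains or ancestral reconstruction.
- No block merging across small interruptions; a single mis-mapped anchor
  splits a block (by design of the strict run rule — use the monotonic mode
  to see the effect of relaxing it).
- The one-to-one reduction discards paralog-family information.
- Lexicographic chromosome ordering ("10" < "2") is a stable but unnatural
  sort; it affects ordinal numbering (hence nothing observable, as both
  genomes and the ground-truth path use the same order) and the grouping keys
  of overview output.
- GFF3 ingestion is flat: top-level features only, no transcript/exon
  substructure, no sequence (FASTA) handling, no assembly liftover.
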