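# syntenykit

A Python library and CLI for **conserved-synteny analysis between two
annotated genomes**: detecting framed, collinear synteny blocks from ortholog
anchors, exchanging them in a simple tab-delimited block format, and searching
the genome features inside syntenic regions by their biological annotations
(Gene Ontology, Mammalian Phenotype, Disease Ontology). It re-implements, as a
reusable back end, the kind of machinery an interactive synteny browser needs:
the block detector, the data loaders and embedded database, the
annotation-driven display filter, and cross-genome interval mapping.

It is aimed at comparative-genomics workflows in which a trait interval mapped
in one species (a GWAS locus, a QTL) is projected onto another species'
genome, and prior biological knowledge about the genes in the syntenic
interval — in either species — is used to prioritize candidates.

## The block model

Inputs are two genomes' gene models (GFF3, 1-based inclusive coordinates) and
an orthology relation given as a binary relation of gene pairs. After the
relation is reduced to a one-to-one map, each genome's anchored genes are
sorted by (chromosome, start) and numbered 1..N. Scanning genome A's anchors
in order and writing down the ordinal of each ortholog in genome B gives a
sequence of B-indices; **each maximal run of sequential indices — changing by
exactly +1 (ascending) or −1 (descending) at every step, with no chromosome
change in either genome — is one synteny block**. Orientation is `+` when the
B-indices increase and `−` (an inversion) when they decrease; block boundaries
are the outer limits of the member genes in each genome. Blocks are serialized
one per line in ten tab-separated columns:

```
ref_chr  ref_taxon  ref_start  ref_end  comp_chr  comp_taxon  comp_start  comp_end  ±  ID=<unique id>
```

Annotation search follows the ontologies' true-path convention: a query term
retrieves genes annotated to the term or to any descendant reached via
`is_a`/`part_of` edges, with `NOT`-qualified associations excluded. Filter
queries combine symbol / feature-type / term clauses with a Boolean operator
and are scoped to the *reference* genome, the *comparison* genome, or
*either*; a gene can match through its own annotation (`self`) or through its
ortholog's annotation in the other genome (`via_ortholog`).

## Worked example

The bundled fixture generator reconstructs a published candidate-gene
walkthrough: a human lung-cancer susceptibility interval (6q23–25,
chr6:130,300,000–161,000,000) searched for genes annotated to the GO process
*positive regulation of cell death* in either the human or the mouse genome.

```python
from pathlib import Path
from syntenykit.fixtures import make_usecase_fixture, load_usecase
from syntenykit.filter_engine import resolve_display_set, apply_filter

fx = make_usecase_fixture("lung", Path("lung_demo"))
lc = load_usecase(fx)

for b in lc.blocks:
    print(b.block_id, b.ref_chromosome, b.ref_start, b.ref_end, "->",
          b.comp_chromosome, b.comp_start, b.comp_end, b.orientation, len(b.anchors))

display = resolve_display_set(fx.region, lc.blocks, lc.ref_features, lc.comp_features)
table = apply_filter(fx.queries["either"], display, lc.annotations,
                     lc.ontologies, lc.pairs)
print(len(table.feature_ids("reference")))
print(sorted(table.symbols("reference")))
```

prints

```
SynBlock:hsmm:1 6 5000000 13049999 -> 10 4000000 7619999 + 5
SynBlock:hsmm:2 6 131000000 157099999 -> 17 3000000 19019999 - 21
11
['BCLAF1', 'CCN2', 'FNDC1', 'HEBP2', 'IGF2R', 'IL20RA', 'LATS1', 'MAP3K5', 'MYB', 'PRKN', 'TIAM2']
```

The interval's block on mouse chromosome 17 is an inversion (`−`), and the
search returns eleven genes. `PRKN` is among them only because of its *mouse*
ortholog's annotation (`table.provenance_of("hsa:PRKN")` →
`{'via_ortholog'}`); re-running with `fx.queries["reference"]` (human
annotations only) drops it to ten. The match table exports to CSV with
`export_matches_csv`.

The same machinery is available from a shell: `syntenykit blocks` computes a
block file from two GFF3s and an ortholog table, `syntenykit load` runs the
four data loaders into a single-file SQLite database, and
`syntenykit query <endpoint>` prints the JSON documents (feature search,
features-by-region, blocks-by-chromosome, term search, filter, overview) that
a browser front end would consume.

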