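"""Deterministic synthetic data: genome pairs with planted rearrangements,
random ontology DAGs, and the two published candidate-gene walkthroughs as
self-contained fixture bundles.

Everything here is synthetic and generated at run time — no downloads. Gene
coordinates are invented (evenly spaced, deterministic) except where a real
span is part of the scenario itself (the *T2dm2sa* QTL interval on mouse
chromosome 2 and the human 6q lung-cancer susceptibility interval); analyses of
these fixtures therefore count genes and check structure rather than comparing
invented coordinates.

The simulator plants inversions and translocations on gene boundaries in an
otherwise identity ortholog map, so the expected block decomposition is
constructible directly from the resulting gene arrangement, independently of
the production detection path.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Sequence

from .errors import ValidationError
from .filter_engine import FilterClause, FilterQuery
from .genome_model import (
    FeatureSet,
    GeneFeature,
    GenomeConfig,
    RegionSelection,
    load_genome_config,
    write_gff3,
)
from .ontology_annotation import AnnotationSet, Ontology, read_gaf, read_obo
from .synteny_blocks import (
    AnchorIndex,
    OrthologPair,
    SyntenyBlock,
    compute_blocks,
    index_anchors,
    write_block_file,
    write_ortholog_pairs,
)

GENE_SPACING = 10_000
GENE_LENGTH = 5_000
FIRST_GENE_START = 1_000


# ---------------------------------------------------------------------------
# planted-rearrangement genome pairs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulatedPair:
    """A synthetic genome pair with planted rearrangements and known truth."""

    seed: int
    n_genes: int
    plan: tuple[tuple, ...]                      # applied rearrangements, in order
    ref_features: tuple[GeneFeature, ...]
    comp_features: tuple[GeneFeature, ...]
    pairs: tuple[OrthologPair, ...]
    expected_blocks: tuple[SyntenyBlock, ...]    # ground truth, min_anchors=1
    ref_gff3: Path | None = None
    comp_gff3: Path | None = None
    orthologs_tsv: Path | None = None
    expected_blocks_tsv: Path | None = None


def _arrangement_features(
    arrangement: Mapping[str, Sequence[int]],
    taxon_id: int,
    id_prefix: str,
    symbol_prefix: str,
) -> list[GeneFeature]:
    feats = []
    for chrom in sorted(arrangement):
        for pos, gene in enumerate(arrangement[chrom]):
            start = FIRST_GENE_START + pos * GENE_SPACING
            feats.append(
                GeneFeature(
                    feature_id=f"{id_prefix}{gene + 1:04d}",
                    symbol=f"{symbol_prefix}{gene + 1}",
                    taxon_id=taxon_id,
                    chromosome=chrom,
                    start=start,
                    end=start + GENE_LENGTH - 1,
                    strand="+",
                    feature_type="protein coding gene",
                )
            )
    return feats


def _expected_blocks_from_arrangements(
    ref_arr: Mapping[str, Sequence[int]],
    comp_arr: Mapping[str, Sequence[int]],
    ref_features: Sequence[GeneFeature],
    comp_features: Sequence[GeneFeature],
    min_anchors: int,
    id_tag: str,
) -> list[SyntenyBlock]:
    """Ground-truth blocks read directly off the two gene arrangements.

    This reconstruction is deliberately self-contained: it walks the reference
    arrangement chromosome by chromosome and groups genes that stay adjacent
    (offset +-1 in comparison ordinal, same comparison chromosome), without
    going through the anchor-index machinery under test.
    """
    comp_pos: dict[int, tuple[str, int]] = {}
    ordinal = 0
    for chrom in sorted(comp_arr):
        for gene in comp_arr[chrom]:
            ordinal += 1
            comp_pos[gene] = (chrom, ordinal)
    ref_by_gene = {int(f.feature_id[-4:]) - 1: f for f in ref_features}
    comp_by_gene = {int(f.feature_id[-4:]) - 1: f for f in comp_features}

    groups: list[list[int]] = []
    for chrom in sorted(ref_arr):
        current: list[int] = []
        direction = 0
        for gene in ref_arr[chrom]:
            if current:
                pchrom, pord = comp_pos[current[-1]]
                gchrom, gord = comp_pos[gene]
                step = gord - pord
                extends = gchrom == pchrom and (
                    step == direction if direction else step in (1, -1)
                )
                if extends:
                    direction = step
                    current.append(gene)
                    continue
                groups.append(current)
                current, direction = [gene], 0
            else:
                current = [gene]
        if current:
            groups.append(current)

    blocks: list[SyntenyBlock] = []
    n = 0
    for group in groups:
        if len(group) < min_anchors:
            continue
        n += 1
        refs = [ref_by_gene[g] for g in group]
        comps = [comp_by_gene[g] for g in group]
        ascending = len(group) == 1 or comp_pos[group[1]][1] > comp_pos[group[0]][1]
        blocks.append(
            SyntenyBlock(
                ref_chromosome=refs[0].chromosome,
                ref_taxon_id=refs[0].taxon_id,
                ref_start=min(f.start for f in refs),
                ref_end=max(f.end for f in refs),
                comp_chromosome=comps[0].chromosome,
                comp_taxon_id=comps[0].taxon_id,
                comp_start=min(f.start for f in comps),
                comp_end=max(f.end for f in comps),
                orientation="+" if ascending else "-",
                block_id=f"SynBlock:{id_tag}:{n}",
            )
        )
    return blocks


def simulate_genome_pair(
    n_genes: int,
    n_inversions: int = 0,
    n_translocations: int = 0,
    seed: int = 0,
    n_chromosomes: int = 1,
    out_dir: str | Path | None = None,
    min_anchors: int = 1,
    ref_taxon_id: int = 90001,
    comp_taxon_id: int = 90002,
) -> SimulatedPair:
    """Simulate a genome pair: identity gene order plus planted rearrangements.

    Genome A carries genes 1..n split across `n_chromosomes`; genome B starts
    as a copy and is transformed by `n_inversions` segment reversals and
    `n_translocations` segment moves to another chromosome, each planted on
    gene boundaries (segments of >= 2 genes). The same seed reproduces the
    same files byte for byte.

    Raises
    ------
    ValidationError
        If the requested rearrangements are not placeable (fewer than two genes
        on every chromosome, or translocations requested with one chromosome).
    """
    if n_genes < 2:
        raise ValidationError("n_genes must be >= 2")
    if n_translocations > 0 and n_chromosomes < 2:
        raise ValidationError("translocations need at least two chromosomes")
    rng = random.Random(seed)

    chrom_names = [str(i + 1) for i in range(n_chromosomes)]
    ref_arr: dict[str, list[int]] = {c: [] for c in chrom_names}
    for gene in range(n_genes):
        ref_arr[chrom_names[gene * n_chromosomes // n_genes]].append(gene)
    comp_arr: dict[str, list[int]] = {c: list(genes) for c, genes in ref_arr.items()}

    plan: list[tuple] = []
    for _ in range(n_inversions):
        candidates = [c for c in chrom_names if len(comp_arr[c]) >= 2]
        if not candidates:
            raise ValidationError("no chromosome with >= 2 genes left to invert")
        chrom = rng.choice(candidates)
        genes = comp_arr[chrom]
        i = rng.randrange(0, len(genes) - 1)
        j = rng.randrange(i + 1, len(genes))
        genes[i:j + 1] = reversed(genes[i:j + 1])
        plan.append(("inversion", chrom, i, j))
    for _ in range(n_translocations):
        sources = [c for c in chrom_names if len(comp_arr[c]) >= 2]
        if not sources:
            raise ValidationError("no chromosome with >= 2 genes left to translocate from")
        src = rng.choice(sources)
        genes = comp_arr[src]
        i = rng.randrange(0, len(genes) - 1)
        j = rng.randrange(i + 1, len(genes))
        segment = genes[i:j + 1]
        del genes[i:j + 1]
        dest = rng.choice([c for c in chrom_names if c != src])
        at = rng.randrange(0, len(comp_arr[dest]) + 1)
        comp_arr[dest][at:at] = segment
        plan.append(("translocation", src, i, j, dest, at))

    ref_features = _arrangement_features(ref_arr, ref_taxon_id, "simA:", "simgene")
    comp_features = _arrangement_features(comp_arr, comp_taxon_id, "simB:", "SIMGENE")
    pairs = tuple(
        OrthologPair(f"simA:{g + 1:04d}", f"simB:{g + 1:04d}") for g in range(n_genes)
    )
    expected = _expected_blocks_from_arrangements(
        ref_arr, comp_arr, ref_features, comp_features, min_anchors, id_tag="sim"
    )

    paths: dict[str, Path | None] = dict.fromkeys(
        ("ref_gff3", "comp_gff3", "orthologs_tsv", "expected_blocks_tsv")
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths["ref_gff3"] = out_dir / "ref.gff3"
        paths["comp_gff3"] = out_dir / "comp.gff3"
        paths["orthologs_tsv"] = out_dir / "orthologs.tsv"
        paths["expected_blocks_tsv"] = out_dir / "expected_blocks.tsv"
        write_gff3(ref_features, paths["ref_gff3"])
        write_gff3(comp_features, paths["comp_gff3"])
        write_ortholog_pairs(pairs, paths["orthologs_tsv"])
        write_block_file(expected, paths["expected_blocks_tsv"])

    return SimulatedPair(
        seed=seed,
        n_genes=n_genes,
        plan=tuple(plan),
        ref_features=tuple(ref_features),
        comp_features=tuple(comp_features),
        pairs=pairs,
        expected_blocks=tuple(expected),
        **paths,
    )


# ---------------------------------------------------------------------------
# random ontology DAGs
# ---------------------------------------------------------------------------

def random_dag(
    n_terms: int,
    edge_prob: float = 0.02,
    seed: int = 0,
    prefix: str = "TEST",
    out_path: str | Path | None = None,
) -> str:
    """Generate a random acyclic ontology as OBO text (edges only child->earlier).

    Terms are ranked; every non-root term gets at least one parent of lower
    rank, extra parents with probability `edge_prob`, and roughly a fifth of
    edges use ``part_of`` instead of ``is_a``. Deterministic per seed.
    """
    if n_terms < 1:
        raise ValidationError("n_terms must be >= 1")
    rng = random.Random(seed)
    lines = ["format-version: 1.2", f"ontology: {prefix.lower()}", ""]
    for i in range(n_terms):
        term = f"{prefix}:{i + 1:07d}"
        lines += [f"[Term]", f"id: {term}", f"name: synthetic term {i + 1}"]
        if i > 0:
            parents = {rng.randrange(i)}
            parents |= {j for j in range(i) if rng.random() < edge_prob}
            for j in sorted(parents):
                parent = f"{prefix}:{j + 1:07d}"
                if rng.random() < 0.2:
                    lines.append(f"relationship: part_of {parent}")
                else:
                    lines.append(f"is_a: {parent}")
        lines.append("")
    text = "\n".join(lines)
    if out_path is not None:
        Path(out_path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# use-case fixture bundles
# ---------------------------------------------------------------------------

UseCaseName = Literal["lung", "t2dm"]

#: genes the lung-cancer walkthrough highlights for "positive regulation of
#: cell death" searched in either genome (human 6q23-25 interval)
LUNG_MATCH_SYMBOLS = (
    "MYB", "CCN2", "MAP3K5", "HEBP2", "BCLAF1", "TIAM2",
    "IL20RA", "LATS1", "FNDC1", "IGF2R", "PRKN",
)
LUNG_MOUSE_ONLY = ("PRKN",)          # annotated in mouse, not human
LUNG_HUMAN_ONLY = ("MYB", "TIAM2")   # annotated in human, not mouse
LUNG_REGION = RegionSelection(9606, "6", 130_300_000, 161_000_000)

#: the T2dm2sa QTL interval on mouse chromosome 2 (GRCm38)
T2DM_QTL_SPAN = (29_417_935, 148_533_014)
T2DM_IGT_SYMBOLS = (
    "Pkn3", "Lcn2", "Dpm2", "Zbtb43", "Bbs5", "Commd9",
    "Hipk3", "Pax6", "Hdc", "Ap4e1", "Chgb", "Pcsk2",
)
T2DM_INSULIN_SYMBOLS = ("Lcn2", "Slc2a8", "Dpp4", "Bdnf", "Hdc", "Snap25", "Pcsk2")
T2DM_BMI_SYMBOL = "Snap25"
T2DM_DO_SYMBOLS = ("GPD2", "NEUROD1", "MAPK8IP1")

_GO_OBO = """format-version: 1.2
ontology: go

[Term]
id: GO:0008150
name: biological_process
namespace: biological_process

[Term]
id: GO:0010941
name: regulation of cell death
namespace: biological_process
is_a: GO:0008150

[Term]
id: GO:0010942
name: positive regulation of cell death
namespace: biological_process
is_a: GO:0010941

[Term]
id: GO:0043068
name: positive regulation of programmed cell death
namespace: biological_process
is_a: GO:0010942

[Term]
id: GO:0043069
name: negative regulation of cell death
namespace: biological_process
is_a: GO:0010941
"""

_MP_OBO = """format-version: 1.2
ontology: mp

[Term]
id: MP:0000001
name: mammalian phenotype

[Term]
id: MP:0005376
name: homeostasis/metabolism phenotype
is_a: MP:0000001

[Term]
id: MP:0002078
name: abnormal glucose homeostasis
is_a: MP:0005376

[Term]
id: MP:0005293
name: impaired glucose tolerance
is_a: MP:0002078

[Term]
id: MP:0099001
name: severely impaired glucose tolerance
is_a: MP:0005293

[Term]
id: MP:0002079
name: increased circulating insulin level
synonym: "hyperinsulinemia" EXACT []
is_a: MP:0002078

[Term]
id: MP:0099002
name: markedly increased circulating insulin level
is_a: MP:0002079

[Term]
id: MP:0001259
name: abnormal body weight
is_a: MP:0000001

[Term]
id: MP:0010025
name: increased body mass index
is_a: MP:0001259
"""

_DO_OBO = """format-version: 1.2
ontology: do

[Term]
id: DOID:4
name: disease

[Term]
id: DOID:9351
name: diabetes mellitus
is_a: DOID:4

[Term]
id: DOID:9352
name: type 2 diabetes mellitus
is_a: DOID:9351

[Term]
id: DOID:0110742
name: type 2 diabetes mellitus 2
is_a: DOID:9352
"""


@dataclass(frozen=True)
class UseCaseFixture:
    """File bundle plus queries and expected outcomes for one walkthrough."""

    case: UseCaseName
    directory: Path
    ref_config: Path
    comp_config: Path
    ref_gff3: Path
    comp_gff3: Path
    orthologs_tsv: Path
    blocks_tsv: Path
    obo_paths: Mapping[str, Path]                  # ontology name -> OBO file
    gaf_paths: Mapping[tuple[str, str], Path]      # (genome role, ontology) -> GAF file
    region: RegionSelection
    queries: Mapping[str, FilterQuery]
    expected_symbols: Mapping[str, tuple[str, ...]]


@dataclass(frozen=True)
class LoadedUseCase:
    """A use-case fixture read back through the package's own readers."""

    fixture: UseCaseFixture
    ref_config: GenomeConfig
    comp_config: GenomeConfig
    ref_features: FeatureSet
    comp_features: FeatureSet
    pairs: tuple[OrthologPair, ...]
    anchor_index: AnchorIndex
    blocks: tuple[SyntenyBlock, ...]
    ontologies: Mapping[str, Ontology]
    annotations: Mapping[str, AnnotationSet]       # genome role -> merged annotations


def _gaf_row(feature_id: str, symbol: str, term: str, taxon: int,
             qualifier: str = "", evidence: str = "IEA") -> str:
    cols = ["SYN", feature_id, symbol, qualifier, term, "SYN:0000001", evidence, "",
            "P", "", "", "gene", f"taxon:{taxon}", "20190101", "syntenykit", "", ""]
    return "\t".join(cols)


def _write_gaf(path: Path, rows: Sequence[str]) -> None:
    path.write_text("!gaf-version: 2.2\n" + "\n".join(rows) + ("\n" if rows else ""))


def _write_config(path: Path, taxon_id: int, build: str, role: str,
                  chromosomes: Sequence[tuple[str, int]], ontologies: Sequence[str]) -> None:
    lines = [f"taxon_id: {taxon_id}", f"build_name: {build}", f"role: {role}", "chromosomes:"]
    lines += [f"  - [\"{name}\", {length}]" for name, length in chromosomes]
    lines.append("ontologies: [" + ", ".join(ontologies) + "]")
    path.write_text("\n".join(lines) + "\n")


def _spaced_features(symbols: Sequence[str], chrom: str, taxon: int, id_prefix: str,
                     first: int, spacing: int, length: int,
                     feature_type: str = "protein coding gene") -> list[GeneFeature]:
    out = []
    for p, sym in enumerate(symbols):
        start = first + p * spacing
        out.append(GeneFeature(f"{id_prefix}{sym}", sym, taxon, chrom,
                               start, start + length - 1, "+", feature_type))
    return out


def _mouse_symbol(human_symbol: str) -> str:
    return human_symbol.capitalize()


def _make_lung_fixture(out: Path) -> UseCaseFixture:
    """Human 6q23-25 lung-cancer susceptibility interval walkthrough.

    Reference = human (GRCh38 chr6), comparison = mouse. The interval holds the
    eleven genes the walkthrough reports for GO "positive regulation of cell
    death" plus ten unannotated decoys; five more annotated genes sit outside
    the interval. The mouse orthologs of the interval genes lie on chromosome
    17 in reversed order, so the interval's block is an inversion.
    """
    # positional order inside the interval: matches interleaved with decoys
    in_region = ["CCN2", "DCY1", "MYB", "DCY2", "BCLAF1", "MAP3K5", "DCY3",
                 "HEBP2", "IL20RA", "DCY4", "DCY5", "LATS1", "DCY6", "TIAM2",
                 "DCY7", "DCY8", "FNDC1", "DCY9", "IGF2R", "DCY10", "PRKN"]
    outside = ["OUTG1", "OUTG2", "OUTG3", "OUTG4", "OUTG5"]

    human = _spaced_features(outside, "6", 9606, "hsa:", 5_000_000, 2_000_000, 50_000)
    human += _spaced_features(in_region, "6", 9606, "hsa:", 131_000_000, 1_300_000, 100_000)
    # mouse orthologs: interval genes reversed on chr 17, outside genes on chr 10
    mouse = _spaced_features([_mouse_symbol(s) for s in reversed(in_region)],
                             "17", 10090, "mmu:", 3_000_000, 800_000, 20_000)
    mouse += _spaced_features([_mouse_symbol(s) for s in outside],
                              "10", 10090, "mmu:", 4_000_000, 900_000, 20_000)
    pairs = [OrthologPair(f"hsa:{s}", f"mmu:{_mouse_symbol(s)}") for s in in_region + outside]

    human_self = [s for s in LUNG_MATCH_SYMBOLS if s not in LUNG_MOUSE_ONLY]
    human_rows = [
        _gaf_row(f"hsa:{s}", s,
                 "GO:0043068" if s in ("MYB", "IGF2R") else "GO:0010942", 9606,
                 evidence="EXP" if s in ("MYB", "TIAM2") else "IEA")
        for s in human_self
    ]
    human_rows += [_gaf_row(f"hsa:{s}", s, "GO:0043069", 9606) for s in in_region if s.startswith("DCY")]
    human_rows += [_gaf_row(f"hsa:{s}", s, "GO:0010942", 9606) for s in outside]
    human_rows.append(_gaf_row("hsa:DCY1", "DCY1", "GO:0010942", 9606, qualifier="NOT"))

    mouse_annotated = [s for s in LUNG_MATCH_SYMBOLS if s not in LUNG_HUMAN_ONLY]
    mouse_rows = [
        _gaf_row(f"mmu:{_mouse_symbol(s)}", _mouse_symbol(s),
                 "GO:0043068" if s == "PRKN" else "GO:0010942", 10090)
        for s in mouse_annotated
    ]

    (out / "go.obo").write_text(_GO_OBO)
    _write_gaf(out / "human_go.gaf", human_rows)
    _write_gaf(out / "mouse_go.gaf", mouse_rows)
    write_gff3(human, out / "ref.gff3")
    write_gff3(mouse, out / "comp.gff3")
    write_ortholog_pairs(pairs, out / "orthologs.tsv")
    idx = index_anchors(human, mouse, pairs)
    write_block_file(compute_blocks(idx, min_anchors=2), out / "blocks.tsv")
    _write_config(out / "ref_config.yaml", 9606, "GRCh38", "reference",
                  [("6", 170_805_979)], ["GO"])
    _write_config(out / "comp_config.yaml", 10090, "GRCm38", "comparison",
                  [("10", 130_694_993), ("17", 94_987_271)], ["GO", "MP"])

    term_clause = FilterClause("term", "positive regulation of cell death", ontology="GO")
    queries = {
        "either": FilterQuery((term_clause,), LUNG_REGION, scope="either"),
        "reference": FilterQuery((term_clause,), LUNG_REGION, scope="reference"),
    }
    expected = {
        "either": LUNG_MATCH_SYMBOLS,
        "reference": tuple(s for s in LUNG_MATCH_SYMBOLS if s not in LUNG_MOUSE_ONLY),
    }
    return UseCaseFixture(
        case="lung", directory=out,
        ref_config=out / "ref_config.yaml", comp_config=out / "comp_config.yaml",
        ref_gff3=out / "ref.gff3", comp_gff3=out / "comp.gff3",
        orthologs_tsv=out / "orthologs.tsv", blocks_tsv=out / "blocks.tsv",
        obo_paths={"GO": out / "go.obo"},
        gaf_paths={("reference", "GO"): out / "human_go.gaf",
                   ("comparison", "GO"): out / "mouse_go.gaf"},
        region=LUNG_REGION, queries=queries, expected_symbols=expected,
    )


def _make_t2dm_fixture(out: Path) -> UseCaseFixture:
    """Mouse *T2dm2sa* QTL walkthrough (type 2 diabetes, mouse chromosome 2).

    Reference = mouse, comparison = human. The QTL interval carries the genes
    the walkthrough lists for the MP terms (impaired glucose tolerance,
    increased circulating insulin level, increased body mass index) plus
    decoys; its human syntenic interval spans three chromosomes and carries the
    three Disease Ontology "type 2 diabetes mellitus" genes.
    """
    # mouse chr 2 gene order inside the QTL, as three human-chromosome segments
    seg_chr11 = ["Commd9", "Hipk3", "Pax6", "Bdnf", "Mapk8ip1", "Hdc", "Ap4e1", "Dcm1"]
    seg_chr20 = ["Snap25", "Chgb", "Pcsk2", "Dcm2", "Slc2a8"]   # inverted in human
    seg_chr2 = ["Dpp4", "Gpd2", "Neurod1", "Pkn3", "Lcn2", "Dpm2",
                "Zbtb43", "Bbs5", "Dcm3", "Dcm4"]
    in_qtl = seg_chr11 + seg_chr20 + seg_chr2
    outside = ["Igtout1", "Igtout2", "Igtout3"]   # beyond the QTL on chr 2

    mouse = _spaced_features(in_qtl, "2", 10090, "mmu:", 32_000_000, 4_500_000, 30_000)
    mouse += _spaced_features(outside, "2", 10090, "mmu:", 155_000_000, 3_000_000, 30_000)
    qtl = GeneFeature("mmu:qtl:T2dm2sa", "T2dm2sa", 10090, "2",
                      T2DM_QTL_SPAN[0], T2DM_QTL_SPAN[1], ".", "QTL")
    mouse.append(qtl)

    human = _spaced_features([s.upper() for s in seg_chr11], "11", 9606, "hsa:",
                             2_000_000, 3_000_000, 80_000)
    human += _spaced_features([s.upper() for s in reversed(seg_chr20)], "20", 9606, "hsa:",
                              1_500_000, 2_500_000, 80_000)
    human += _spaced_features([s.upper() for s in seg_chr2], "2", 9606, "hsa:",
                              2_000_000, 3_000_000, 80_000)
    # annotated human gene outside every syntenic span: must never be displayed
    human.append(GeneFeature("hsa:T2DOUT", "T2DOUT", 9606, "2",
                             120_000_000, 120_080_000, "+", "protein coding gene"))
    pairs = [OrthologPair(f"mmu:{s}", f"hsa:{s.upper()}") for s in in_qtl]

    mp_rows = [
        _gaf_row(f"mmu:{s}", s,
                 "MP:0099001" if s == "Pcsk2" else "MP:0005293", 10090)
        for s in T2DM_IGT_SYMBOLS
    ]
    mp_rows += [
        _gaf_row(f"mmu:{s}", s,
                 "MP:0099002" if s == "Snap25" else "MP:0002079", 10090)
        for s in T2DM_INSULIN_SYMBOLS
    ]
    mp_rows.append(_gaf_row("mmu:Snap25", "Snap25", "MP:0010025", 10090))
    mp_rows += [_gaf_row(f"mmu:{s}", s, "MP:0005293", 10090) for s in outside]
    mp_rows.append(_gaf_row("mmu:Gpd2", "Gpd2", "MP:0005293", 10090, qualifier="NOT"))

    do_rows = [
        _gaf_row("hsa:GPD2", "GPD2", "DOID:9352", 9606),
        _gaf_row("hsa:NEUROD1", "NEUROD1", "DOID:9352", 9606),
        _gaf_row("hsa:MAPK8IP1", "MAPK8IP1", "DOID:0110742", 9606),
        _gaf_row("hsa:DCM3", "DCM3", "DOID:9351", 9606),
        _gaf_row("hsa:T2DOUT", "T2DOUT", "DOID:9352", 9606),
        _gaf_row("hsa:DCM4", "DCM4", "DOID:9352", 9606, qualifier="NOT"),
    ]

    (out / "mp.obo").write_text(_MP_OBO)
    (out / "do.obo").write_text(_DO_OBO)
    _write_gaf(out / "mouse_mp.gaf", mp_rows)
    _write_gaf(out / "human_do.gaf", do_rows)
    write_gff3(mouse, out / "ref.gff3")
    write_gff3(human, out / "comp.gff3")
    write_ortholog_pairs(pairs, out / "orthologs.tsv")
    idx = index_anchors(mouse, human, pairs)
    write_block_file(compute_blocks(idx, min_anchors=2), out / "blocks.tsv")
    _write_config(out / "ref_config.yaml", 10090, "GRCm38", "reference",
                  [("2", 182_113_224)], ["MP", "GO"])
    _write_config(out / "comp_config.yaml", 9606, "GRCh38", "comparison",
                  [("2", 242_193_529), ("11", 135_086_622), ("20", 64_444_167)], ["DO"])

    region = RegionSelection(10090, "2", *T2DM_QTL_SPAN)
    queries = {
        "igt": FilterQuery((FilterClause("term", "impaired glucose tolerance", "MP"),),
                           region, scope="reference"),
        "insulin": FilterQuery((FilterClause("term", "increased circulating insulin level", "MP"),),
                               region, scope="reference"),
        "bmi": FilterQuery((FilterClause("term", "increased body mass index", "MP"),),
                           region, scope="reference"),
        "do": FilterQuery((FilterClause("term", "type 2 diabetes mellitus", "DO"),),
                          region, scope="comparison"),
    }
    expected = {
        "igt": T2DM_IGT_SYMBOLS,
        "insulin": T2DM_INSULIN_SYMBOLS,
        "bmi": (T2DM_BMI_SYMBOL,),
        "do": T2DM_DO_SYMBOLS,
    }
    return UseCaseFixture(
        case="t2dm", directory=out,
        ref_config=out / "ref_config.yaml", comp_config=out / "comp_config.yaml",
        ref_gff3=out / "ref.gff3", comp_gff3=out / "comp.gff3",
        orthologs_tsv=out / "orthologs.tsv", blocks_tsv=out / "blocks.tsv",
        obo_paths={"MP": out / "mp.obo", "DO": out / "do.obo"},
        gaf_paths={("reference", "MP"): out / "mouse_mp.gaf",
                   ("comparison", "DO"): out / "human_do.gaf"},
        region=region, queries=queries, expected_symbols=expected,
    )


def make_usecase_fixture(case: UseCaseName, out_dir: str | Path) -> UseCaseFixture:
    """Write one walkthrough fixture bundle (GFF3 x2, orthologs, OBO/GAF, blocks, configs)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if case == "lung":
        return _make_lung_fixture(out)
    if case == "t2dm":
        return _make_t2dm_fixture(out)
    raise ValueError(f"unknown use case {case!r}")


def load_usecase(fixture: UseCaseFixture) -> LoadedUseCase:
    """Read a fixture bundle back through the package's own readers."""
    from .genome_model import read_gff3
    from .synteny_blocks import read_ortholog_pairs

    ref_cfg = load_genome_config(fixture.ref_config)
    comp_cfg = load_genome_config(fixture.comp_config)
    ref_features = read_gff3(fixture.ref_gff3, ref_cfg.build.taxon_id)
    comp_features = read_gff3(fixture.comp_gff3, comp_cfg.build.taxon_id)
    pairs = tuple(read_ortholog_pairs(fixture.orthologs_tsv))
    idx = index_anchors(ref_features, comp_features, pairs)
    blocks = tuple(compute_blocks(idx, min_anchors=2))
    ontologies = {name: read_obo(path, name=name) for name, path in fixture.obo_paths.items()}
    annotations: dict[str, AnnotationSet] = {}
    for (role, onto_name), path in fixture.gaf_paths.items():
        parsed = read_gaf(path, ontologies[onto_name])
        annotations[role] = annotations[role].merge(parsed) if role in annotations else parsed
    return LoadedUseCase(
        fixture=fixture, ref_config=ref_cfg, comp_config=comp_cfg,
        ref_features=FeatureSet(ref_features), comp_features=FeatureSet(comp_features),
        pairs=pairs, anchor_index=idx, blocks=blocks,
        ontologies=ontologies, annotations=annotations,
    )


#: the worked example line of the block file format (mouse chr 1 -> human chr 8)
EXAMPLE_BLOCK_RECORD = (
    "1\t10090\t3205901\t9299878\t8\t9606\t49909789\t55526155\t-\tID=SynBlock:mmhs:1"
)


__all__ = [
    "SimulatedPair", "simulate_genome_pair", "random_dag",
    "UseCaseFixture", "LoadedUseCase", "make_usecase_fixture", "load_usecase",
    "LUNG_MATCH_SYMBOLS", "LUNG_MOUSE_ONLY", "LUNG_HUMAN_ONLY", "LUNG_REGION",
    "T2DM_QTL_SPAN", "T2DM_IGT_SYMBOLS", "T2DM_INSULIN_SYMBOLS",
    "T2DM_BMI_SYMBOL", "T2DM_DO_SYMBOLS", "EXAMPLE_BLOCK_RECORD",
]
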