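"""Display-set resolution, the Boolean feature filter, CSV export, feature search."""

import pytest

from syntenykit.errors import TermNotFoundError, ValidationError
from syntenykit.filter_engine import (
    FilterClause,
    FilterQuery,
    apply_filter,
    export_matches_csv,
    read_matches_csv,
    resolve_display_set,
    search_reference_features,
)
from syntenykit.fixtures import (
    LUNG_MATCH_SYMBOLS,
    LUNG_MOUSE_ONLY,
    T2DM_QTL_SPAN,
)
from syntenykit.genome_model import RegionSelection


def display(loaded, region=None):
    fx = loaded.fixture
    return resolve_display_set(region or fx.region, loaded.blocks,
                               loaded.ref_features, loaded.comp_features)


def run(loaded, query):
    return apply_filter(query, display(loaded, query.region), loaded.annotations,
                        loaded.ontologies, loaded.pairs)


class TestResolveDisplaySet:
    def test_region_inside_one_block(self, lung):
        """A region inside the 6q interval shows only that block's mouse span."""
        region = RegionSelection(9606, "6", 131_000_000, 132_000_000)
        ds = display(lung, region)
        assert {f.chromosome for f in ds.comparison} == {"17"}
        assert len(ds.comparison) == 21  # the whole block's comparison span

    def test_region_spanning_blocks_on_two_comparison_chromosomes(self, lung):
        region = RegionSelection(9606, "6", 1, 160_000_000)
        ds = display(lung, region)
        assert {f.chromosome for f in ds.comparison} == {"10", "17"}
        # brute force: union of comparison features in each overlapping block span
        brute = set()
        for b in lung.blocks:
            if b.ref_overlaps("6", region.start, region.end):
                for f in lung.comp_features:
                    if f.chromosome == b.comp_chromosome and f.start <= b.comp_end and f.end >= b.comp_start:
                        brute.add(f.feature_id)
        assert {f.feature_id for f in ds.comparison} == brute

    def test_region_in_synteny_gap(self, lung):
        region = RegionSelection(9606, "6", 165_000_000, 166_000_000)
        ds = display(lung, region)
        assert ds.reference == () and ds.comparison == ()

    def test_annotated_gene_outside_blocks_never_displayed(self, t2dm):
        ds = display(t2dm)
        assert "hsa:T2DOUT" not in {f.feature_id for f in ds.comparison}


class TestApplyFilter:
    def test_lung_either_scope_returns_eleven_genes(self, lung):
        table = run(lung, lung.fixture.queries["either"])
        assert sorted(table.symbols("reference")) == sorted(LUNG_MATCH_SYMBOLS)
        assert len(table.feature_ids("reference")) == 11
        # PRKN matched through its mouse ortholog only; MYB/TIAM2 by human annotation
        assert table.provenance_of("hsa:PRKN") == {"via_ortholog"}
        assert table.provenance_of("hsa:MYB") == {"self"}
        assert table.provenance_of("hsa:TIAM2") == {"self"}

    def test_lung_reference_scope_drops_mouse_only_gene(self, lung):
        table = run(lung, lung.fixture.queries["reference"])
        symbols = table.symbols("reference")
        assert not set(LUNG_MOUSE_ONLY) & symbols
        assert len(symbols) == 10
        # single-genome scope still highlights the comparison track via orthology
        assert table.provenance_of("mmu:Ccn2") == {"via_ortholog"}

    def test_empty_annotation_set_yields_empty_table(self, lung):
        table = apply_filter(lung.fixture.queries["either"],
                             display(lung), {}, lung.ontologies, lung.pairs)
        assert len(table) == 0

    def test_and_is_subset_of_or(self, lung):
        fx = lung.fixture
        clauses = (FilterClause("term", "positive regulation of cell death", "GO"),
                   FilterClause("feature_type", "protein coding gene"))
        or_q = FilterQuery(clauses, fx.region, combinator="OR")
        and_q = FilterQuery(clauses, fx.region, combinator="AND")
        or_ids = set(run(lung, or_q).feature_ids())
        and_ids = set(run(lung, and_q).feature_ids())
        assert and_ids <= or_ids

    def test_symbol_and_type_clauses(self, t2dm):
        fx = t2dm.fixture
        q = FilterQuery((FilterClause("symbol", "pax6"),), fx.region, scope="reference")
        assert run(t2dm, q).symbols("reference") == {"Pax6"}
        q = FilterQuery((FilterClause("feature_type", "QTL"),), fx.region, scope="reference")
        assert run(t2dm, q).symbols("reference") == {"T2dm2sa"}

    def test_unknown_term_names_the_term(self, lung):
        q = FilterQuery((FilterClause("term", "no such process", "GO"),), lung.fixture.region)
        with pytest.raises(TermNotFoundError, match="no such process"):
            run(lung, q)

    def test_scope_union_equals_either(self, lung, t2dm):
        """matches(reference) | matches(comparison) == matches(either), per fixture."""
        for loaded in (lung, t2dm):
            for query in loaded.fixture.queries.values():
                either = run(loaded, FilterQuery(query.clauses, query.region, scope="either"))
                ref = run(loaded, FilterQuery(query.clauses, query.region, scope="reference"))
                comp = run(loaded, FilterQuery(query.clauses, query.region, scope="comparison"))
                union = {(r.feature_id, r.matched_clause) for r in ref.rows} | {
                    (r.feature_id, r.matched_clause) for r in comp.rows}
                assert {(r.feature_id, r.matched_clause) for r in either.rows} == union

    def test_exclude_nonmatching_flag_only_metadata(self, lung):
        fx = lung.fixture
        q = fx.queries["either"]
        flagged = FilterQuery(q.clauses, q.region, scope=q.scope, exclude_nonmatching=True)
        a, b = run(lung, q), run(lung, flagged)
        assert a.rows == b.rows
        assert (a.exclude_nonmatching, b.exclude_nonmatching) == (False, True)

    def test_rows_sorted_and_deduplicated(self, t2dm):
        table = run(t2dm, t2dm.fixture.queries["igt"])
        keys = [(r.genome, r.chromosome, r.start, r.feature_id, r.matched_clause) for r in table.rows]
        genome_rank = [{"reference": 0, "comparison": 1}[g] for g, *_ in keys]
        assert genome_rank == sorted(genome_rank)
        assert len({(r.feature_id, r.matched_clause) for r in table.rows}) == len(table.rows)

    def test_clause_validation(self):
        with pytest.raises(ValidationError):
            FilterClause("term", "x")  # ontology required
        with pytest.raises(ValidationError):
            FilterQuery((), RegionSelection(1, "1", 1, 2))


class TestCsvExport:
    def test_roundtrip_identity(self, lung, tmp_path):
        table = run(lung, lung.fixture.queries["either"])
        path = tmp_path / "matches.csv"
        export_matches_csv(table, path)
        assert read_matches_csv(path).rows == table.rows

    def test_empty_table_is_header_only(self, lung, tmp_path):
        q = FilterQuery((FilterClause("symbol", "NOPE"),), lung.fixture.region)
        path = tmp_path / "empty.csv"
        export_matches_csv(run(lung, q), path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1 and lines[0].startswith("feature_id,symbol,genome")

    def test_comma_in_symbol_quoted(self, tmp_path, lung):
        import dataclasses
        table = run(lung, lung.fixture.queries["either"])
        row = dataclasses.replace(table.rows[0], symbol="weird, symbol")
        weird = dataclasses.replace(table, rows=(row, *table.rows[1:]))
        path = tmp_path / "quoted.csv"
        export_matches_csv(weird, path)
        assert '"weird, symbol"' in path.read_text()
        assert read_matches_csv(path).rows[0].symbol == "weird, symbol"


class TestSearchReferenceFeatures:
    def test_qtl_found_by_symbol(self, t2dm):
        hits = search_reference_features(t2dm.ref_features, t2dm.annotations["reference"],
                                         t2dm.ontologies, "T2dm2sa")
        assert hits and hits[0].feature_type == "QTL"
        assert (hits[0].chromosome, hits[0].start, hits[0].end) == ("2", *T2DM_QTL_SPAN)

    def test_absent_symbol_empty(self, t2dm):
        assert search_reference_features(t2dm.ref_features, t2dm.annotations["reference"],
                                         t2dm.ontologies, "Nonexistent") == []

    def test_exact_ranks_before_prefix(self, t2dm):
        hits = search_reference_features(t2dm.ref_features, t2dm.annotations["reference"],
                                         t2dm.ontologies, "Dpp4")
        assert hits[0].symbol == "Dpp4"

    def test_term_query_equals_annotation_composition(self, t2dm):
        """Term search == features_annotated_to ∩ reference features."""
        from syntenykit.ontology_annotation import features_annotated_to
        onto = t2dm.ontologies["MP"]
        term = onto.resolve_term("impaired glucose tolerance")
        want = features_annotated_to(t2dm.annotations["reference"], onto, term)
        hits = search_reference_features(t2dm.ref_features, t2dm.annotations["reference"],
                                         t2dm.ontologies, "impaired glucose tolerance")
        assert {f.feature_id for f in hits} == {fid for fid in want if fid in t2dm.ref_features}
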