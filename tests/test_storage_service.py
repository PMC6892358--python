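"""ETL loaders, database round trips, and JSON endpoint / library equivalence."""

import json

import pytest
from click.testing import CliRunner

from syntenykit.cli import main as cli_main
from syntenykit.filter_engine import apply_filter, resolve_display_set
from syntenykit.genome_model import read_gff3
from syntenykit.region_mapper import genome_overview
from syntenykit.storage_service import (
    LoaderError,
    QueryService,
    etl_load,
    match_table_doc,
)
from syntenykit.synteny_blocks import read_block_file


def load_db(fixture, tmp_path, name="usecase.db", **kwargs):
    return etl_load(
        tmp_path / name,
        fixture.ref_config, fixture.comp_config,
        fixture.ref_gff3, fixture.comp_gff3,
        fixture.orthologs_tsv,
        obo_paths=fixture.obo_paths,
        gaf_paths=fixture.gaf_paths,
        **kwargs,
    )


@pytest.fixture(scope="module")
def t2dm_db(t2dm_fixture, tmp_path_factory):
    return load_db(t2dm_fixture, tmp_path_factory.mktemp("db"))


@pytest.fixture(scope="module")
def t2dm_service(t2dm_db):
    return QueryService(t2dm_db)


class TestEtlLoad:
    def test_counts_match_parsed_inputs(self, t2dm_fixture, t2dm_db, t2dm):
        counts = t2dm_db.row_counts()
        assert counts["features"] == len(t2dm.ref_features) + len(t2dm.comp_features)
        assert counts["blocks"] == len(t2dm.blocks)
        assert counts["ontology_terms"] == sum(len(o) for o in t2dm.ontologies.values())
        n_annotations = sum(len(a) for a in t2dm.annotations.values())
        assert counts["annotations"] == n_annotations

    def test_rerun_is_idempotent(self, t2dm_fixture, tmp_path):
        first = load_db(t2dm_fixture, tmp_path).row_counts()
        second = load_db(t2dm_fixture, tmp_path).row_counts()
        assert first == second

    def test_gaf_for_unknown_gene_dropped_and_counted(self, t2dm_fixture, tmp_path):
        gaf = t2dm_fixture.gaf_paths[("reference", "MP")]
        extra = tmp_path / "extra.gaf"
        row = "\t".join(["SYN", "mmu:Ghost", "Ghost", "", "MP:0005293", "SYN:1", "IEA", "",
                        "P", "", "", "gene", "taxon:10090", "20190101", "x", "", ""])
        extra.write_text(gaf.read_text() + row + "\n")
        patched = dict(t2dm_fixture.gaf_paths)
        patched[("reference", "MP")] = extra
        bundle = etl_load(tmp_path / "g.db", t2dm_fixture.ref_config, t2dm_fixture.comp_config,
                          t2dm_fixture.ref_gff3, t2dm_fixture.comp_gff3,
                          t2dm_fixture.orthologs_tsv, obo_paths=t2dm_fixture.obo_paths,
                          gaf_paths=patched)
        with bundle.connect() as conn:
            assert conn.execute(
                "SELECT COUNT(*) FROM annotations WHERE feature_id='mmu:Ghost'"
            ).fetchone()[0] == 0
            dropped = conn.execute(
                "SELECT rows_skipped FROM provenance WHERE loader='annotations' AND source=?",
                (str(extra),)).fetchone()[0]
        assert dropped == 1

    def test_loader_failure_names_loader(self, t2dm_fixture, tmp_path):
        bad = tmp_path / "bad.gff3"
        bad.write_text("1\tx\tgene\t5\n")
        with pytest.raises(LoaderError, match="features_and_blocks"):
            etl_load(tmp_path / "bad.db", t2dm_fixture.ref_config, t2dm_fixture.comp_config,
                     bad, t2dm_fixture.comp_gff3, t2dm_fixture.orthologs_tsv,
                     obo_paths=t2dm_fixture.obo_paths, gaf_paths=t2dm_fixture.gaf_paths)

    def test_features_and_blocks_roundtrip_through_db(self, t2dm_fixture, t2dm_db, t2dm):
        service = QueryService(t2dm_db)
        stored_ref = {f.feature_id: f for f in service._features["reference"]}
        parsed = read_gff3(t2dm_fixture.ref_gff3, 10090)
        assert stored_ref == {f.feature_id: f for f in parsed}
        from_file = read_block_file(t2dm_fixture.blocks_tsv)
        stored = sorted(service._blocks, key=lambda b: b.block_id)
        assert stored == sorted(from_file, key=lambda b: b.block_id)


class TestEndpointLibraryEquivalence:
    def test_blocks_by_chromosome_matches_overview(self, t2dm_service, t2dm):
        doc = t2dm_service.blocks_by_chromosome("2")
        assert doc["blocks"] == genome_overview(t2dm.blocks)["2"]

    def test_overview_endpoint(self, t2dm_service, t2dm):
        assert t2dm_service.overview()["overview"] == genome_overview(t2dm.blocks)

    def test_features_by_region_matches_library(self, t2dm_service, t2dm):
        fx = t2dm.fixture
        doc = t2dm_service.features_by_region("reference", "2", fx.region.start, fx.region.end)
        got = [f["feature_id"] for f in doc["features"]]
        want = [f.feature_id for f in t2dm.ref_features.in_region(fx.region)]
        assert got == want

    def test_inverted_region_is_error_document(self, t2dm_service):
        doc = t2dm_service.features_by_region("reference", "2", 100, 50)
        assert doc["error"]["code"] == 400

    def test_filter_endpoint_replays_usecase(self, t2dm_service, t2dm):
        fx = t2dm.fixture
        query = fx.queries["do"]
        doc = t2dm_service.filter(
            [{"criterion": "term", "value": "type 2 diabetes mellitus", "ontology": "DO"}],
            "2", fx.region.start, fx.region.end, scope="comparison",
        )
        display = resolve_display_set(fx.region, t2dm.blocks, t2dm.ref_features,
                                      t2dm.comp_features)
        table = apply_filter(query, display, t2dm.annotations, t2dm.ontologies, t2dm.pairs)
        assert doc["matches"] == match_table_doc(table)
        assert {m["symbol"] for m in doc["matches"] if m["genome"] == "comparison"} == {
            "GPD2", "NEUROD1", "MAPK8IP1"}

    def test_term_search_endpoint(self, t2dm_service, t2dm):
        doc = t2dm_service.term_search("hyperinsulinemia")
        (hit,) = doc["terms"]
        assert hit["term_id"] == "MP:0002079"
        assert set(hit["descendants"]) == t2dm.ontologies["MP"].descendant_closure("MP:0002079")


class TestCli:
    def test_blocks_command_writes_block_file(self, t2dm_fixture, tmp_path):
        out = tmp_path / "blocks.tsv"
        runner = CliRunner()
        result = runner.invoke(cli_main, [
            "blocks", "--ref-gff3", str(t2dm_fixture.ref_gff3),
            "--comp-gff3", str(t2dm_fixture.comp_gff3),
            "--orthologs", str(t2dm_fixture.orthologs_tsv),
            "--ref-taxon", "10090", "--comp-taxon", "9606", "--out", str(out),
        ])
        assert result.exit_code == 0, result.output
        assert read_block_file(out) == read_block_file(t2dm_fixture.blocks_tsv)

    def test_load_then_query_prints_endpoint_json(self, t2dm_fixture, t2dm, tmp_path):
        db = tmp_path / "cli.db"
        runner = CliRunner()
        load_args = [
            "load", "--db", str(db),
            "--ref-config", str(t2dm_fixture.ref_config),
            "--comp-config", str(t2dm_fixture.comp_config),
            "--ref-gff3", str(t2dm_fixture.ref_gff3),
            "--comp-gff3", str(t2dm_fixture.comp_gff3),
            "--orthologs", str(t2dm_fixture.orthologs_tsv),
        ]
        for name, path in t2dm_fixture.obo_paths.items():
            load_args += ["--obo", f"{name}={path}"]
        for (role, name), path in t2dm_fixture.gaf_paths.items():
            load_args += ["--gaf", f"{role}:{name}={path}"]
        result = runner.invoke(cli_main, load_args)
        assert result.exit_code == 0, result.output
        result = runner.invoke(cli_main, ["query", "blocks-by-chromosome",
                                          "--db", str(db), "--chromosome", "2"])
        assert result.exit_code == 0, result.output
        assert json.loads(result.output)["blocks"] == genome_overview(t2dm.blocks)["2"]
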