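"""The data layer: ETL loaders into a single-file SQLite database plus
read-only JSON query endpoints.

Four loaders run in a fixed order — (1) genome features and synteny blocks,
(2) ontologies, (3) biological annotations, (4) configuration/provenance —
mirroring a quarterly-refresh model in which all mutation goes through
:func:`etl_load` and every query surface is read-only. Each endpoint returns a
JSON-serializable document with a ``schema_version`` field; the CLI prints the
same documents, so the HTTP shape of a deployment is a thin wrapper away.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
import sqlite3
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .errors import SyntenyKitError, TermNotFoundError, ValidationError
from .filter_engine import (
    FilterClause,
    FilterQuery,
    MatchTable,
    apply_filter,
    resolve_display_set,
    search_reference_features,
)
from .genome_model import (
    FeatureSet,
    GeneFeature,
    RegionSelection,
    load_config_pair,
    read_gff3,
)
from .ontology_annotation import Annotation, AnnotationSet, Ontology, OntologyTerm, read_gaf, read_obo
from .region_mapper import genome_overview
from .synteny_blocks import (
    OrthologPair,
    SyntenyBlock,
    compute_blocks,
    index_anchors,
    read_block_file,
    read_ortholog_pairs,
)

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

_SCHEMA = """
CREATE TABLE genomes (
    role TEXT PRIMARY KEY CHECK (role IN ('reference','comparison')),
    taxon_id INTEGER NOT NULL,
    build_name TEXT NOT NULL
);
CREATE TABLE chromosomes (
    role TEXT NOT NULL REFERENCES genomes(role),
    name TEXT NOT NULL,
    length INTEGER NOT NULL CHECK (length > 0),
    ord INTEGER NOT NULL,
    PRIMARY KEY (role, name)
);
CREATE TABLE features (
    feature_id TEXT NOT NULL,
    role TEXT NOT NULL REFERENCES genomes(role),
    taxon_id INTEGER NOT NULL,
    chromosome TEXT NOT NULL,
    start INTEGER NOT NULL,
    end INTEGER NOT NULL,
    strand TEXT NOT NULL,
    feature_type TEXT NOT NULL,
    symbol TEXT NOT NULL,
    PRIMARY KEY (role, feature_id)
);
CREATE TABLE blocks (
    block_id TEXT PRIMARY KEY,
    ref_chromosome TEXT NOT NULL, ref_taxon_id INTEGER NOT NULL,
    ref_start INTEGER NOT NULL, ref_end INTEGER NOT NULL,
    comp_chromosome TEXT NOT NULL, comp_taxon_id INTEGER NOT NULL,
    comp_start INTEGER NOT NULL, comp_end INTEGER NOT NULL,
    orientation TEXT NOT NULL CHECK (orientation IN ('+','-'))
);
CREATE TABLE block_anchors (
    block_id TEXT NOT NULL REFERENCES blocks(block_id),
    ord INTEGER NOT NULL,
    ref_feature_id TEXT NOT NULL,
    comp_feature_id TEXT NOT NULL,
    PRIMARY KEY (block_id, ord)
);
CREATE TABLE orthologs (
    ref_feature_id TEXT NOT NULL,
    comp_feature_id TEXT NOT NULL,
    PRIMARY KEY (ref_feature_id, comp_feature_id)
);
CREATE TABLE ontology_terms (
    term_id TEXT PRIMARY KEY,
    ontology TEXT NOT NULL,
    name TEXT NOT NULL,
    namespace TEXT NOT NULL,
    obsolete INTEGER NOT NULL DEFAULT 0
);
CREATE TABLE term_edges (
    child_id TEXT NOT NULL REFERENCES ontology_terms(term_id),
    parent_id TEXT NOT NULL,
    relation TEXT NOT NULL CHECK (relation IN ('is_a','part_of')),
    PRIMARY KEY (child_id, parent_id, relation)
);
CREATE TABLE term_synonyms (
    term_id TEXT NOT NULL REFERENCES ontology_terms(term_id),
    synonym TEXT NOT NULL
);
CREATE TABLE annotations (
    role TEXT NOT NULL REFERENCES genomes(role),
    feature_id TEXT NOT NULL,
    term_id TEXT NOT NULL REFERENCES ontology_terms(term_id),
    ontology TEXT NOT NULL,
    qualifiers TEXT NOT NULL DEFAULT '',
    evidence_code TEXT NOT NULL DEFAULT '',
    taxon_id INTEGER NOT NULL DEFAULT 0,
    symbol TEXT NOT NULL DEFAULT '',
    negated INTEGER NOT NULL DEFAULT 0,
    FOREIGN KEY (role, feature_id) REFERENCES features(role, feature_id)
);
CREATE TABLE config (
    role TEXT NOT NULL,
    key TEXT NOT NULL,
    value TEXT NOT NULL,
    PRIMARY KEY (role, key)
);
CREATE TABLE provenance (
    loader TEXT NOT NULL,
    source TEXT NOT NULL,
    rows_loaded INTEGER NOT NULL,
    rows_skipped INTEGER NOT NULL,
    loaded_at TEXT NOT NULL
);
"""

_TABLES = (
    "genomes", "chromosomes", "features", "blocks", "block_anchors", "orthologs",
    "ontology_terms", "term_edges", "term_synonyms", "annotations", "config", "provenance",
)


class LoaderError(SyntenyKitError):
    """A data loader failed; names the loader and the offending input."""

    def __init__(self, loader: str, detail: str):
        self.loader = loader
        super().__init__(f"loader {loader!r} failed: {detail}")


@dataclass
class DatabaseBundle:
    """Handle to a loaded single-file database."""

    path: Path

    def connect(self) -> sqlite3.Connection:
        conn = sqlite3.connect(self.path)
        conn.row_factory = sqlite3.Row
        conn.execute("PRAGMA foreign_keys = ON")
        return conn

    def row_counts(self) -> dict[str, int]:
        with self.connect() as conn:
            return {
                t: conn.execute(f"SELECT COUNT(*) FROM {t}").fetchone()[0] for t in _TABLES
            }


def etl_load(
    db_path: str | Path,
    ref_config: str | Path,
    comp_config: str | Path,
    ref_gff3: str | Path,
    comp_gff3: str | Path,
    orthologs: str | Path,
    obo_paths: Mapping[str, str | Path],
    gaf_paths: Mapping[tuple[str, str], str | Path],
    blocks_file: str | Path | None = None,
    min_anchors: int = 2,
) -> DatabaseBundle:
    """Run the loaders in order and (re)build the database from scratch.

    Re-running on the same inputs replaces the content rather than
    duplicating it (the schema is dropped and rebuilt), so the load is
    idempotent. Synteny blocks are read from `blocks_file` when given,
    otherwise computed from the ortholog anchors. GAF rows citing genes absent
    from the features table are dropped and counted in provenance. Any loader
    failure aborts the load, naming the loader.
    """
    db_path = Path(db_path)
    loader = "features_and_blocks"
    try:
        ref_cfg, comp_cfg = load_config_pair(ref_config, comp_config)
        ref_features = read_gff3(ref_gff3, ref_cfg.build.taxon_id,
                                 symbol_attribute=ref_cfg.symbol_attribute)
        comp_features = read_gff3(comp_gff3, comp_cfg.build.taxon_id,
                                  symbol_attribute=comp_cfg.symbol_attribute)
        pairs = read_ortholog_pairs(orthologs)
        if blocks_file is not None:
            blocks = read_block_file(blocks_file)
        else:
            blocks = compute_blocks(index_anchors(ref_features, comp_features, pairs),
                                    min_anchors=min_anchors)
    except SyntenyKitError as exc:
        raise LoaderError(loader, str(exc)) from exc

    loader = "ontologies"
    try:
        ontologies = {name: read_obo(p, name=name) for name, p in obo_paths.items()}
    except SyntenyKitError as exc:
        raise LoaderError(loader, str(exc)) from exc

    loader = "annotations"
    annotation_sets: dict[tuple[str, str], AnnotationSet] = {}
    try:
        for (role, onto_name), p in gaf_paths.items():
            if onto_name not in ontologies:
                raise ValidationError(f"GAF {p} cites unloaded ontology {onto_name!r}")
            annotation_sets[(role, onto_name)] = read_gaf(p, ontologies[onto_name])
    except SyntenyKitError as exc:
        raise LoaderError(loader, str(exc)) from exc

    if db_path.exists():
        db_path.unlink()
    bundle = DatabaseBundle(path=db_path)
    now = _dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds")
    with bundle.connect() as conn:
        conn.executescript(_SCHEMA)
        for cfg, role in ((ref_cfg, "reference"), (comp_cfg, "comparison")):
            conn.execute("INSERT INTO genomes VALUES (?,?,?)",
                         (role, cfg.build.taxon_id, cfg.build.build_name))
            conn.executemany(
                "INSERT INTO chromosomes VALUES (?,?,?,?)",
                [(role, name, length, i) for i, (name, length) in enumerate(cfg.build.chromosomes)],
            )
            conn.execute("INSERT INTO config VALUES (?,?,?)",
                         (role, "ontologies", json.dumps(list(cfg.ontologies))))
            conn.execute("INSERT INTO config VALUES (?,?,?)",
                         (role, "symbol_attribute", cfg.symbol_attribute))
        for feats, role, src in ((ref_features, "reference", ref_gff3),
                                 (comp_features, "comparison", comp_gff3)):
            conn.executemany(
                "INSERT INTO features VALUES (?,?,?,?,?,?,?,?,?)",
                [(f.feature_id, role, f.taxon_id, f.chromosome, f.start, f.end,
                  f.strand, f.feature_type, f.symbol) for f in feats],
            )
            conn.execute("INSERT INTO provenance VALUES (?,?,?,?,?)",
                         ("features_and_blocks", str(src), len(feats), 0, now))
        conn.executemany("INSERT INTO orthologs VALUES (?,?)",
                         sorted({(p.ref_feature_id, p.comp_feature_id) for p in pairs}))
        conn.executemany(
            "INSERT INTO blocks VALUES (?,?,?,?,?,?,?,?,?,?)",
            [(b.block_id, b.ref_chromosome, b.ref_taxon_id, b.ref_start, b.ref_end,
              b.comp_chromosome, b.comp_taxon_id, b.comp_start, b.comp_end, b.orientation)
             for b in blocks],
        )
        for b in blocks:
            conn.executemany(
                "INSERT INTO block_anchors VALUES (?,?,?,?)",
                [(b.block_id, i, a.ref_feature_id, a.comp_feature_id)
                 for i, a in enumerate(b.anchors)],
            )
        conn.execute("INSERT INTO provenance VALUES (?,?,?,?,?)",
                     ("features_and_blocks", str(blocks_file or "(computed)"),
                      len(blocks), 0, now))
        for name, ontology in ontologies.items():
            terms = sorted(ontology.terms.values(), key=lambda t: t.term_id)
            conn.executemany(
                "INSERT INTO ontology_terms VALUES (?,?,?,?,?)",
                [(t.term_id, name, t.name, t.namespace, int(t.obsolete)) for t in terms],
            )
            for t in terms:
                conn.executemany("INSERT INTO term_edges VALUES (?,?,?)",
                                 [(t.term_id, pid, rel) for pid, rel in sorted(t.parents)])
                conn.executemany("INSERT INTO term_synonyms VALUES (?,?)",
                                 [(t.term_id, s) for s in t.synonyms])
            conn.execute("INSERT INTO provenance VALUES (?,?,?,?,?)",
                         ("ontologies", str(obo_paths[name]), len(terms), 0, now))
        known_ids = {("reference", f.feature_id) for f in ref_features} | {
            ("comparison", f.feature_id) for f in comp_features
        }
        for (role, onto_name), aset in annotation_sets.items():
            rows = []
            dropped = aset.dropped_unknown_terms
            for ann in (*aset.positive, *aset.negative):
                if (role, ann.feature_id) not in known_ids:
                    dropped += 1
                    continue
                rows.append((role, ann.feature_id, ann.term_id, onto_name,
                             "|".join(sorted(ann.qualifiers)), ann.evidence_code,
                             ann.taxon_id, ann.symbol, int(ann.negated)))
            conn.executemany("INSERT INTO annotations VALUES (?,?,?,?,?,?,?,?,?)", rows)
            conn.execute("INSERT INTO provenance VALUES (?,?,?,?,?)",
                         ("annotations", str(gaf_paths[(role, onto_name)]),
                          len(rows), dropped, now))
    counts = bundle.row_counts()
    logger.info("etl_load(%s): %s", db_path, counts)
    return bundle


# ---------------------------------------------------------------------------
# read-back and query endpoints
# ---------------------------------------------------------------------------

def _load_features(conn: sqlite3.Connection, role: str) -> list[GeneFeature]:
    return [
        GeneFeature(r["feature_id"], r["symbol"], r["taxon_id"], r["chromosome"],
                    r["start"], r["end"], r["strand"], r["feature_type"])
        for r in conn.execute("SELECT * FROM features WHERE role=?", (role,))
    ]


def _load_blocks(conn: sqlite3.Connection) -> list[SyntenyBlock]:
    blocks = []
    for r in conn.execute("SELECT * FROM blocks ORDER BY block_id"):
        anchors = tuple(
            OrthologPair(a["ref_feature_id"], a["comp_feature_id"])
            for a in conn.execute(
                "SELECT * FROM block_anchors WHERE block_id=? ORDER BY ord", (r["block_id"],)
            )
        )
        blocks.append(
            SyntenyBlock(r["ref_chromosome"], r["ref_taxon_id"], r["ref_start"], r["ref_end"],
                         r["comp_chromosome"], r["comp_taxon_id"], r["comp_start"], r["comp_end"],
                         r["orientation"], r["block_id"], anchors)
        )
    blocks.sort(key=lambda b: (b.ref_chromosome, b.ref_start, b.ref_end, b.block_id))
    return blocks


def _load_ontologies(conn: sqlite3.Connection) -> dict[str, Ontology]:
    by_name: dict[str, list[OntologyTerm]] = {}
    parents: dict[str, set[tuple[str, str]]] = {}
    synonyms: dict[str, list[str]] = {}
    for r in conn.execute("SELECT * FROM term_edges"):
        parents.setdefault(r["child_id"], set()).add((r["parent_id"], r["relation"]))
    for r in conn.execute("SELECT * FROM term_synonyms"):
        synonyms.setdefault(r["term_id"], []).append(r["synonym"])
    for r in conn.execute("SELECT * FROM ontology_terms"):
        by_name.setdefault(r["ontology"], []).append(
            OntologyTerm(r["term_id"], r["name"], r["namespace"],
                         frozenset(parents.get(r["term_id"], ())),
                         tuple(synonyms.get(r["term_id"], ())), bool(r["obsolete"]))
        )
    return {name: Ontology(terms, name=name) for name, terms in by_name.items()}


def _load_annotations(conn: sqlite3.Connection) -> dict[str, AnnotationSet]:
    out: dict[str, AnnotationSet] = {}
    for r in conn.execute("SELECT * FROM annotations"):
        aset = out.setdefault(r["role"], AnnotationSet())
        aset.add(Annotation(
            feature_id=r["feature_id"], term_id=r["term_id"],
            qualifiers=frozenset(q for q in r["qualifiers"].split("|") if q),
            evidence_code=r["evidence_code"], taxon_id=r["taxon_id"],
            symbol=r["symbol"], ontology=r["ontology"],
        ))
    return out


def _error(code: int, message: str) -> dict:
    return {"schema_version": SCHEMA_VERSION, "error": {"code": code, "message": message}}


def _feature_doc(f: GeneFeature) -> dict:
    return {
        "feature_id": f.feature_id, "symbol": f.symbol, "taxon_id": f.taxon_id,
        "chromosome": f.chromosome, "start": f.start, "end": f.end,
        "strand": f.strand, "feature_type": f.feature_type,
    }


class QueryService:
    """Read-only JSON endpoints over a loaded database.

    Endpoints: ``features-by-region``, ``blocks-by-chromosome``, ``term-search``,
    ``filter`` (wraps the display filter), ``overview`` (wraps the genome
    summary). Every response is a plain dict with ``schema_version``; errors are
    structured documents with an HTTP-style code, never exceptions.
    """

    def __init__(self, bundle: DatabaseBundle):
        self.bundle = bundle
        with bundle.connect() as conn:
            self._genomes = {
                r["role"]: dict(r) for r in conn.execute("SELECT * FROM genomes")
            }
            self._features = {
                role: FeatureSet(_load_features(conn, role))
                for role in ("reference", "comparison")
            }
            self._blocks = _load_blocks(conn)
            self._ontologies = _load_ontologies(conn)
            self._annotations = _load_annotations(conn)
            self._pairs = [
                OrthologPair(r["ref_feature_id"], r["comp_feature_id"])
                for r in conn.execute("SELECT * FROM orthologs ORDER BY ref_feature_id, comp_feature_id")
            ]

    # -- endpoints ---------------------------------------------------------

    def features_by_region(self, role: str, chromosome: str, start: int, end: int) -> dict:
        if role not in self._features:
            return _error(400, f"unknown genome role {role!r}")
        try:
            region = RegionSelection(self._genomes[role]["taxon_id"], chromosome,
                                     int(start), int(end))
        except (ValidationError, ValueError) as exc:
            return _error(400, str(exc))
        hits = self._features[role].in_region(region)
        return {"schema_version": SCHEMA_VERSION, "role": role,
                "region": {"chromosome": chromosome, "start": region.start, "end": region.end},
                "features": [_feature_doc(f) for f in hits]}

    def blocks_by_chromosome(self, chromosome: str) -> dict:
        arcs = genome_overview(self._blocks).get(chromosome, [])
        return {"schema_version": SCHEMA_VERSION, "ref_chromosome": chromosome, "blocks": arcs}

    def overview(self) -> dict:
        return {"schema_version": SCHEMA_VERSION, "overview": genome_overview(self._blocks)}

    def term_search(self, query: str) -> dict:
        hits = []
        for name, ontology in sorted(self._ontologies.items()):
            try:
                term_id = ontology.resolve_term(query)
            except TermNotFoundError:
                continue
            term = ontology.terms[term_id]
            hits.append({"ontology": name, "term_id": term_id, "name": term.name,
                         "descendants": sorted(ontology.descendant_closure(term_id))})
        return {"schema_version": SCHEMA_VERSION, "query": query, "terms": hits}

    def filter(
        self,
        clauses: Sequence[Mapping[str, str]],
        chromosome: str,
        start: int,
        end: int,
        combinator: str = "OR",
        scope: str = "either",
    ) -> dict:
        try:
            region = RegionSelection(self._genomes["reference"]["taxon_id"],
                                     chromosome, int(start), int(end))
            query = FilterQuery(
                clauses=tuple(
                    FilterClause(c["criterion"], c["value"], c.get("ontology")) for c in clauses
                ),
                region=region, combinator=combinator, scope=scope,  # type: ignore[arg-type]
            )
        except (ValidationError, ValueError, KeyError) as exc:
            return _error(400, str(exc))
        display = resolve_display_set(region, self._blocks,
                                      self._features["reference"], self._features["comparison"])
        try:
            table = apply_filter(query, display, self._annotations, self._ontologies, self._pairs)
        except TermNotFoundError as exc:
            return _error(404, str(exc))
        return {"schema_version": SCHEMA_VERSION, "matches": match_table_doc(table)}

    def feature_search(self, query: str) -> dict:
        hits = search_reference_features(
            self._features["reference"], self._annotations.get("reference"),
            self._ontologies, query,
        )
        return {"schema_version": SCHEMA_VERSION, "query": query,
                "features": [_feature_doc(f) for f in hits]}


def match_table_doc(table: MatchTable) -> list[dict]:
    """Serialize a match table the way the filter endpoint returns it."""
    return [
        {"feature_id": r.feature_id, "symbol": r.symbol, "genome": r.genome,
         "chromosome": r.chromosome, "start": r.start, "end": r.end,
         "feature_type": r.feature_type, "matched_clause": r.matched_clause,
         "provenance": r.provenance, "term_id": r.term_id}
        for r in table.rows
    ]


__all__ = [
    "DatabaseBundle", "QueryService", "LoaderError", "etl_load",
    "match_table_doc", "SCHEMA_VERSION",
]
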