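"""The syntenic-block feature display filter and the reference feature search.

Three search criteria are supported — feature symbol, feature type, and
annotation term — combinable with a single top-level Boolean operator (AND/OR)
and scoped to the reference genome, the comparison genome, or either. Searches
run over a *display set*: the reference features inside a selected region plus
the comparison features inside the comparison spans of the synteny blocks that
region overlaps.

Match provenance distinguishes a feature that satisfied a clause directly
(``self``) from one pulled in through its ortholog's annotation in the other
genome (``via_ortholog``). Under a single-genome scope, clauses are evaluated
against that genome's annotations only, but matches are still reported on both
tracks through the ortholog relation — that is how the browser highlights both
the reference and comparison displays.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd

from .errors import TermNotFoundError, ValidationError
from .genome_model import FeatureSet, GeneFeature, RegionSelection, feature_sort_key
from .ontology_annotation import AnnotationSet, Ontology, features_annotated_to
from .synteny_blocks import OrthologPair, SyntenyBlock

logger = logging.getLogger(__name__)

Criterion = Literal["symbol", "feature_type", "term"]
Scope = Literal["reference", "comparison", "either"]
Genome = Literal["reference", "comparison"]
Provenance = Literal["self", "via_ortholog"]


@dataclass(frozen=True)
class FilterClause:
    """One search criterion: a symbol, a feature type, or an ontology term."""

    criterion: Criterion
    value: str
    ontology: str | None = None

    def __post_init__(self):
        if self.criterion not in ("symbol", "feature_type", "term"):
            raise ValidationError(f"unknown criterion {self.criterion!r}")
        if self.criterion == "term" and not self.ontology:
            raise ValidationError("criterion 'term' requires an ontology name")


@dataclass(frozen=True)
class FilterQuery:
    """A Boolean combination of clauses with a genome scope and a display region."""

    clauses: tuple[FilterClause, ...]
    region: RegionSelection
    combinator: Literal["AND", "OR"] = "OR"
    scope: Scope = "either"
    exclude_nonmatching: bool = False

    def __post_init__(self):
        if not self.clauses:
            raise ValidationError("a filter query needs at least one clause")
        if self.combinator not in ("AND", "OR"):
            raise ValidationError(f"combinator must be AND or OR, got {self.combinator!r}")
        if self.scope not in ("reference", "comparison", "either"):
            raise ValidationError(f"unknown scope {self.scope!r}")


@dataclass(frozen=True)
class MatchRow:
    feature_id: str
    symbol: str
    genome: Genome
    chromosome: str
    start: int
    end: int
    feature_type: str
    matched_clause: int  # index into FilterQuery.clauses
    provenance: Provenance
    term_id: str | None = None


MATCH_FIELDS = (
    "feature_id", "symbol", "genome", "chromosome", "start", "end",
    "feature_type", "matched_clause", "provenance", "term_id",
)


@dataclass(frozen=True)
class MatchTable:
    """Filter results, sorted by (genome, chromosome, start, feature_id, clause)."""

    rows: tuple[MatchRow, ...]
    exclude_nonmatching: bool = False

    def __len__(self) -> int:
        return len(self.rows)

    def feature_ids(self, genome: Genome | None = None) -> tuple[str, ...]:
        """Distinct matched feature IDs, optionally restricted to one genome."""
        seen = dict.fromkeys(
            r.feature_id for r in self.rows if genome is None or r.genome == genome
        )
        return tuple(seen)

    def symbols(self, genome: Genome | None = None) -> frozenset[str]:
        return frozenset(r.symbol for r in self.rows if genome is None or r.genome == genome)

    def provenance_of(self, feature_id: str) -> frozenset[str]:
        return frozenset(r.provenance for r in self.rows if r.feature_id == feature_id)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{f: getattr(r, f) for f in MATCH_FIELDS} for r in self.rows],
            columns=list(MATCH_FIELDS),
        )


def _sorted_rows(rows: Iterable[MatchRow]) -> tuple[MatchRow, ...]:
    genome_rank = {"reference": 0, "comparison": 1}
    return tuple(
        sorted(
            rows,
            key=lambda r: (genome_rank[r.genome], r.chromosome, r.start,
                           r.feature_id, r.matched_clause),
        )
    )


@dataclass(frozen=True)
class DisplaySet:
    """The features visible in the block detail view for a selected region."""

    reference: tuple[GeneFeature, ...]
    comparison: tuple[GeneFeature, ...]


def resolve_display_set(
    region: RegionSelection,
    blocks: Sequence[SyntenyBlock],
    ref_features: Iterable[GeneFeature] | FeatureSet,
    comp_features: Iterable[GeneFeature] | FeatureSet,
) -> DisplaySet:
    """Resolve which features are in view for a reference-genome region.

    The reference side is every feature overlapping the region. The comparison
    side is every feature overlapping the comparison span of any block whose
    reference span overlaps the region. A region falling in a synteny gap
    yields an empty comparison side (warned, not an error).
    """
    ref_fs = ref_features if isinstance(ref_features, FeatureSet) else FeatureSet(ref_features)
    comp_fs = comp_features if isinstance(comp_features, FeatureSet) else FeatureSet(comp_features)
    ref_hits = ref_fs.in_region(region)
    overlapping = [b for b in blocks if b.ref_overlaps(region.chromosome, region.start, region.end)]
    if not overlapping:
        logger.warning("region %s:%d-%d overlaps no synteny block",
                       region.chromosome, region.start, region.end)
    comp_hits: dict[str, GeneFeature] = {}
    for b in overlapping:
        comp_region = RegionSelection(b.comp_taxon_id, b.comp_chromosome, b.comp_start, b.comp_end)
        for f in comp_fs.in_region(comp_region):
            comp_hits[f.feature_id] = f
    return DisplaySet(
        reference=tuple(ref_hits),
        comparison=tuple(sorted(comp_hits.values(), key=feature_sort_key)),
    )


def _direct_matches(
    clause: FilterClause,
    features: Sequence[GeneFeature],
    annotations: AnnotationSet | None,
    ontologies: Mapping[str, Ontology],
) -> tuple[set[str], str | None]:
    """Feature IDs in `features` directly satisfying the clause, plus the resolved term."""
    if clause.criterion == "symbol":
        needle = clause.value.lower()
        return {f.feature_id for f in features if f.symbol.lower() == needle}, None
    if clause.criterion == "feature_type":
        needle = clause.value.lower()
        return {f.feature_id for f in features if f.feature_type.lower() == needle}, None
    # term clause
    if clause.ontology not in ontologies:
        raise TermNotFoundError(f"ontology {clause.ontology!r} is not loaded")
    ontology = ontologies[clause.ontology]
    term_id = ontology.resolve_term(clause.value)
    if annotations is None:
        return set(), term_id
    annotated = features_annotated_to(annotations, ontology, term_id)
    return {f.feature_id for f in features if f.feature_id in annotated}, term_id


def apply_filter(
    query: FilterQuery,
    display_set: DisplaySet,
    annotations: Mapping[Genome, AnnotationSet],
    ontologies: Mapping[str, Ontology],
    ortholog_pairs: Sequence[OrthologPair],
) -> MatchTable:
    """Evaluate a filter query over a display set and return the match table.

    For each clause, direct matches are computed per genome; the scope then
    controls which genome's evidence counts and how matches propagate through
    the ortholog relation (see module docstring). Clauses are combined with the
    query's single Boolean operator. The result is deduplicated on
    (feature, clause) and deterministically sorted.
    """
    sides: dict[Genome, Sequence[GeneFeature]] = {
        "reference": display_set.reference,
        "comparison": display_set.comparison,
    }
    other: dict[Genome, Genome] = {"reference": "comparison", "comparison": "reference"}
    # ortholog maps restricted to nothing — the relation is global; matches are
    # restricted implicitly because only display-set features are reported
    orth: dict[Genome, dict[str, set[str]]] = {"reference": {}, "comparison": {}}
    for p in ortholog_pairs:
        orth["reference"].setdefault(p.ref_feature_id, set()).add(p.comp_feature_id)
        orth["comparison"].setdefault(p.comp_feature_id, set()).add(p.ref_feature_id)

    direct: dict[tuple[Genome, int], set[str]] = {}
    resolved_terms: dict[int, str | None] = {}
    for i, clause in enumerate(query.clauses):
        for genome in ("reference", "comparison"):
            ids, term_id = _direct_matches(
                clause, sides[genome], annotations.get(genome), ontologies
            )
            direct[(genome, i)] = ids
            resolved_terms[i] = term_id

    # per feature and clause: the provenance of its match, if any
    evidence: dict[Genome, dict[str, dict[int, Provenance]]] = {
        "reference": {}, "comparison": {},
    }
    for genome in ("reference", "comparison"):
        evaluated: Genome = genome if query.scope == "either" else query.scope  # type: ignore[assignment]
        for f in sides[genome]:
            for i in range(len(query.clauses)):
                prov: Provenance | None = None
                if query.scope == "either":
                    if f.feature_id in direct[(genome, i)]:
                        prov = "self"
                    elif orth[genome].get(f.feature_id, set()) & direct[(other[genome], i)]:
                        prov = "via_ortholog"
                else:
                    if genome == evaluated:
                        if f.feature_id in direct[(genome, i)]:
                            prov = "self"
                    elif orth[genome].get(f.feature_id, set()) & direct[(evaluated, i)]:
                        prov = "via_ortholog"
                if prov is not None:
                    evidence[genome].setdefault(f.feature_id, {})[i] = prov

    rows: list[MatchRow] = []
    for genome in ("reference", "comparison"):
        by_id = {f.feature_id: f for f in sides[genome]}
        for fid, per_clause in evidence[genome].items():
            if query.combinator == "AND" and len(per_clause) < len(query.clauses):
                continue
            f = by_id[fid]
            for i, prov in sorted(per_clause.items()):
                rows.append(
                    MatchRow(
                        feature_id=f.feature_id, symbol=f.symbol, genome=genome,
                        chromosome=f.chromosome, start=f.start, end=f.end,
                        feature_type=f.feature_type, matched_clause=i,
                        provenance=prov, term_id=resolved_terms[i],
                    )
                )
    return MatchTable(rows=_sorted_rows(rows), exclude_nonmatching=query.exclude_nonmatching)


def export_matches_csv(table: MatchTable, path: str | Path) -> None:
    """Write the match table as an RFC-4180-style CSV with a header row."""
    table.to_dataframe().to_csv(path, index=False)


def read_matches_csv(path: str | Path) -> MatchTable:
    """Read back a CSV written by :func:`export_matches_csv`."""
    df = pd.read_csv(path, dtype={"term_id": "string"})
    rows = []
    for rec in df.to_dict(orient="records"):
        term = rec.get("term_id")
        rows.append(
            MatchRow(
                feature_id=str(rec["feature_id"]), symbol=str(rec["symbol"]),
                genome=rec["genome"], chromosome=str(rec["chromosome"]),
                start=int(rec["start"]), end=int(rec["end"]),
                feature_type=str(rec["feature_type"]),
                matched_clause=int(rec["matched_clause"]),
                provenance=rec["provenance"],
                term_id=None if pd.isna(term) else str(term),
            )
        )
    return MatchTable(rows=_sorted_rows(rows))


def search_reference_features(
    features: Iterable[GeneFeature] | FeatureSet,
    annotations: AnnotationSet | None,
    ontologies: Mapping[str, Ontology],
    query_text: str,
    closure: bool = True,
) -> list[GeneFeature]:
    """The Feature Search panel: find reference features by symbol or annotation term.

    Symbol matching is case-insensitive; exact symbol matches rank before prefix
    matches, each group sorted by position. If the query resolves to a term in
    any loaded ontology, features annotated to the term (with descendant closure
    unless ``closure=False``) are appended. Results are deduplicated; an empty
    result is valid.
    """
    feats = list(features)
    q = query_text.strip().lower()
    exact = [f for f in feats if f.symbol.lower() == q]
    prefix = [f for f in feats if f.symbol.lower().startswith(q) and f.symbol.lower() != q]
    term_hits: list[GeneFeature] = []
    for ontology in ontologies.values():
        try:
            term_id = ontology.resolve_term(query_text)
        except TermNotFoundError:
            continue
        if annotations is not None:
            annotated = features_annotated_to(annotations, ontology, term_id, closure=closure)
            term_hits.extend(f for f in feats if f.feature_id in annotated)
    out: dict[str, GeneFeature] = {}
    for f in (*sorted(exact, key=feature_sort_key),
              *sorted(prefix, key=feature_sort_key),
              *sorted(term_hits, key=feature_sort_key)):
        out.setdefault(f.feature_id, f)
    return list(out.values())


__all__ = [
    "FilterClause", "FilterQuery", "MatchRow", "MatchTable", "DisplaySet",
    "resolve_display_set", "apply_filter", "export_matches_csv",
    "read_matches_csv", "search_reference_features", "MATCH_FIELDS",
]
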