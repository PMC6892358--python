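"""OBO ontology parsing, descendant closure over the term DAG, and GAF2 ingestion.

Supports the three vocabularies the browser filters on — Gene Ontology (GO),
Mammalian Phenotype (MP), and Disease Ontology (DO) — through one code path:
an OBO reader (via :mod:`obonet`), a closure engine restricted to is_a/part_of
edges (the standard true-path convention), and a 17-column GAF 2.x reader.
MP and DO association files are distributed in GAF-like layouts and go through
the same reader.

Term retrieval semantics: a gene counts as annotated to a term if it has a
positive (non-NOT) annotation to the term itself or to any descendant, because
annotation to a more specific child implies the parent.
"""

from __future__ import annotations

import logging
import re
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import obonet

from .errors import OntologyError, ParseError, TermNotFoundError

logger = logging.getLogger(__name__)

CLOSURE_RELATIONS = frozenset({"is_a", "part_of"})

_SYNONYM_RE = re.compile(r'"([^"]*)"')


@dataclass(frozen=True)
class OntologyTerm:
    """One ontology term with its is_a/part_of parents."""

    term_id: str
    name: str
    namespace: str = ""
    parents: frozenset[tuple[str, str]] = frozenset()  # (parent_id, relation)
    synonyms: tuple[str, ...] = ()
    obsolete: bool = False


class Ontology:
    """A DAG of terms supporting descendant closure and name/ID lookup."""

    def __init__(self, terms: Iterable[OntologyTerm], name: str = ""):
        self.name = name
        self.terms: dict[str, OntologyTerm] = {}
        self._children: dict[str, set[str]] = {}
        self._name_index: dict[str, set[str]] = {}
        for t in terms:
            if t.term_id in self.terms:
                raise OntologyError(f"duplicate term ID {t.term_id!r}")
            self.terms[t.term_id] = t
        for t in self.terms.values():
            if t.obsolete:
                continue
            for parent_id, rel in t.parents:
                if rel in CLOSURE_RELATIONS and parent_id in self.terms:
                    self._children.setdefault(parent_id, set()).add(t.term_id)
            for key in (t.name, *t.synonyms):
                if key:
                    self._name_index.setdefault(key.lower(), set()).add(t.term_id)
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for parent, kids in self._children.items():
            g.add_edges_from((parent, k) for k in kids)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            path = " -> ".join(edge[0] for edge in cycle) + f" -> {cycle[-1][1]}"
            raise OntologyError(f"cycle among is_a/part_of edges: {path}")

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def children(self, term_id: str) -> frozenset[str]:
        if term_id not in self.terms:
            raise TermNotFoundError(f"unknown term {term_id!r}")
        return frozenset(self._children.get(term_id, ()))

    def descendant_closure(self, term_id: str) -> frozenset[str]:
        """The term itself plus every term reachable downward via is_a/part_of."""
        if term_id not in self.terms:
            raise TermNotFoundError(f"unknown term {term_id!r}")
        seen = {term_id}
        queue = deque([term_id])
        while queue:
            for child in self._children.get(queue.popleft(), ()):
                if child not in seen:
                    seen.add(child)
                    queue.append(child)
        return frozenset(seen)

    def resolve_term(self, query: str) -> str:
        """Resolve a term ID, name, or synonym (case-insensitive) to a term ID."""
        if query in self.terms:
            return query
        hits = sorted(self._name_index.get(query.strip().lower(), ()))
        if not hits:
            raise TermNotFoundError(
                f"term {query!r} not found in ontology {self.name or '(unnamed)'}"
            )
        if len(hits) > 1:
            logger.warning("term name %r is ambiguous (%s); using %s", query, hits, hits[0])
        return hits[0]


def _parse_synonyms(raw: Iterable[str]) -> tuple[str, ...]:
    out = []
    for s in raw:
        m = _SYNONYM_RE.search(s)
        if m:
            out.append(m.group(1))
    return tuple(out)


def read_obo(path: str | Path, name: str | None = None) -> Ontology:
    """Read an OBO 1.2/1.4 file into an :class:`Ontology`.

    Non-obsolete ``[Term]`` stanzas are loaded; ``is_a`` and
    ``relationship: part_of`` edges are retained for closure, every other
    relationship type is ignored (logged at debug level). Cycles among the
    retained edges are an error.
    """
    path = Path(path)
    try:
        graph = obonet.read_obo(str(path))
    except Exception as exc:  # noqa: BLE001
        raise ParseError(f"failed to parse OBO: {exc}", str(path)) from exc
    terms: list[OntologyTerm] = []
    for term_id, data in graph.nodes(data=True):
        parents: set[tuple[str, str]] = set()
        for parent in data.get("is_a", ()):
            parents.add((parent, "is_a"))
        for rel_line in data.get("relationship", ()):
            parts = rel_line.split()
            if len(parts) >= 2:
                rel, target = parts[0], parts[1]
                if rel in CLOSURE_RELATIONS:
                    parents.add((target, rel))
                else:
                    logger.debug("%s: ignoring relationship %r on %s", path, rel, term_id)
        terms.append(
            OntologyTerm(
                term_id=term_id,
                name=data.get("name", term_id),
                namespace=data.get("namespace", ""),
                parents=frozenset(parents),
                synonyms=_parse_synonyms(data.get("synonym", ())),
            )
        )
    return Ontology(terms, name=name or path.stem)


def descendant_closure(ontology: Ontology, term_id: str) -> frozenset[str]:
    """Module-level convenience wrapper around :meth:`Ontology.descendant_closure`."""
    return ontology.descendant_closure(term_id)


# 17 columns of GAF 2.x, in file order
GAF_COLUMNS = (
    "db", "db_object_id", "db_object_symbol", "qualifier", "term_id",
    "db_reference", "evidence_code", "with_from", "aspect", "db_object_name",
    "synonym", "db_object_type", "taxon", "date", "assigned_by",
    "annotation_extension", "gene_product_form_id",
)


@dataclass(frozen=True)
class Annotation:
    """One gene→term assertion from a GAF row."""

    feature_id: str
    term_id: str
    qualifiers: frozenset[str] = frozenset()
    evidence_code: str = ""
    taxon_id: int = 0
    symbol: str = ""
    ontology: str = ""

    @property
    def negated(self) -> bool:
        return "NOT" in self.qualifiers


@dataclass
class AnnotationSet:
    """Positive and negative (NOT-qualified) annotations with a term index."""

    positive: list[Annotation] = field(default_factory=list)
    negative: list[Annotation] = field(default_factory=list)
    dropped_unknown_terms: int = 0
    _term_index: dict[str, set[str]] = field(default_factory=dict, repr=False)

    def add(self, ann: Annotation) -> None:
        if ann.negated:
            self.negative.append(ann)
        else:
            self.positive.append(ann)
            self._term_index.setdefault(ann.term_id, set()).add(ann.feature_id)

    def merge(self, other: "AnnotationSet") -> "AnnotationSet":
        merged = AnnotationSet()
        for ann in (*self.positive, *self.negative, *other.positive, *other.negative):
            merged.add(ann)
        merged.dropped_unknown_terms = self.dropped_unknown_terms + other.dropped_unknown_terms
        return merged

    def features_for_term(self, term_id: str) -> frozenset[str]:
        """Features positively annotated to exactly this term (no closure)."""
        return frozenset(self._term_index.get(term_id, ()))

    def __len__(self) -> int:
        return len(self.positive) + len(self.negative)


def _parse_taxon(field_value: str) -> int:
    # "taxon:10090" or "taxon:10090|taxon:9606" — first one wins
    first = field_value.split("|")[0].strip()
    if ":" in first:
        first = first.split(":", 1)[1]
    try:
        return int(first)
    except ValueError:
        return 0


def read_gaf(path: str | Path, ontology: Ontology) -> AnnotationSet:
    """Read a 17-column GAF 2.x file, validating terms against an ontology.

    ``!`` comment lines are skipped. Rows whose qualifier contains ``NOT`` go to
    the negative list and are excluded from term retrieval. Rows citing terms
    unknown to (or obsolete in) the ontology are dropped with a warning count.
    """
    path = Path(path)
    out = AnnotationSet()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("!"):
                continue
            cols = line.split("\t")
            if len(cols) != len(GAF_COLUMNS):
                raise ParseError(
                    f"expected {len(GAF_COLUMNS)} tab-separated columns, got {len(cols)}",
                    str(path), lineno,
                )
            row = dict(zip(GAF_COLUMNS, cols))
            term_id = row["term_id"].strip()
            if term_id not in ontology or ontology.terms[term_id].obsolete:
                out.dropped_unknown_terms += 1
                continue
            qualifiers = frozenset(q for q in row["qualifier"].split("|") if q)
            out.add(
                Annotation(
                    feature_id=row["db_object_id"].strip(),
                    term_id=term_id,
                    qualifiers=qualifiers,
                    evidence_code=row["evidence_code"].strip(),
                    taxon_id=_parse_taxon(row["taxon"]),
                    symbol=row["db_object_symbol"].strip(),
                    ontology=ontology.name,
                )
            )
    if out.dropped_unknown_terms:
        logger.warning("%s: dropped %d rows citing unknown/obsolete terms",
                       path, out.dropped_unknown_terms)
    return out


def features_annotated_to(
    annotations: AnnotationSet,
    ontology: Ontology,
    term_id: str,
    closure: bool = True,
) -> frozenset[str]:
    """Features positively annotated to a term or (by default) any descendant."""
    terms = ontology.descendant_closure(term_id) if closure else frozenset({term_id})
    if term_id not in ontology:
        raise TermNotFoundError(f"unknown term {term_id!r}")
    hits: set[str] = set()
    for t in terms:
        hits |= annotations.features_for_term(t)
    return frozenset(hits)


def write_negative_annotations(annotations: AnnotationSet, path: str | Path) -> None:
    """Export NOT-qualified annotations as a TSV (feature, term, evidence, taxon)."""
    with open(path, "w") as fh:
        fh.write("# feature_id\tterm_id\tqualifiers\tevidence_code\ttaxon_id\n")
        for ann in sorted(annotations.negative, key=lambda a: (a.feature_id, a.term_id)):
            fh.write(
                f"{ann.feature_id}\t{ann.term_id}\t{'|'.join(sorted(ann.qualifiers))}\t"
                f"{ann.evidence_code}\t{ann.taxon_id}\n"
            )


__all__ = [
    "OntologyTerm", "Ontology", "Annotation", "AnnotationSet",
    "read_obo", "read_gaf", "descendant_closure", "features_annotated_to",
    "write_negative_annotations", "GAF_COLUMNS", "CLOSURE_RELATIONS",
]
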