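"""Framed, collinear synteny-block detection from ortholog anchors.

The model: take every gene of each genome that participates in a one-to-one
ortholog relation, sort each genome's anchored genes by (chromosome, start) and
number them 1..N. Scanning the reference genome's anchors in order, each maximal
run of comparison ordinals that are *sequential* — changing by exactly +1
(ascending) or -1 (descending) at every step, with no chromosome change on
either side — defines one synteny block. Orientation is "+" for ascending runs
and "-" (an inversion) for descending runs. Block boundaries are the outer
limits of the member genes in each genome.

A relaxed ``mode="monotonic"`` variant (any step of constant sign) is provided
for exploration; the consecutive scan is the default and the one the block
format and tests are built around.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

from .errors import ParseError, ValidationError
from .genome_model import GeneFeature

logger = logging.getLogger(__name__)

MultiPolicy = Literal["drop_ambiguous", "keep_first_by_position"]
RunMode = Literal["consecutive", "monotonic"]

#: short taxon tags used in default block IDs, e.g. SynBlock:mmhs:1
TAXON_TAGS = {10090: "mm", 9606: "hs", 10116: "rn"}


@dataclass(frozen=True)
class OrthologPair:
    """One element of the ortholog relation between the two genomes."""

    ref_feature_id: str
    comp_feature_id: str


@dataclass(frozen=True)
class Anchor:
    """An ortholog gene pair with its per-genome positional ordinals."""

    ref: GeneFeature
    comp: GeneFeature
    ref_ordinal: int
    comp_ordinal: int

    @property
    def pair(self) -> OrthologPair:
        return OrthologPair(self.ref.feature_id, self.comp.feature_id)


@dataclass(frozen=True)
class AnchorIndex:
    """Both genomes' anchored genes, ordered and numbered, plus the anchor list.

    Ordinals are 1..N and consecutive on each side; only genes surviving the
    one-to-one reduction of the ortholog relation are numbered. ``anchors`` is
    sorted by reference ordinal, which is the scan order for block detection.
    """

    ref_order: tuple[GeneFeature, ...]
    comp_order: tuple[GeneFeature, ...]
    anchors: tuple[Anchor, ...]

    @property
    def ref_taxon_id(self) -> int | None:
        return self.ref_order[0].taxon_id if self.ref_order else None

    @property
    def comp_taxon_id(self) -> int | None:
        return self.comp_order[0].taxon_id if self.comp_order else None


@dataclass(frozen=True)
class SyntenyBlock:
    """A conserved-synteny block: paired spans, orientation, ID, member anchors."""

    ref_chromosome: str
    ref_taxon_id: int
    ref_start: int
    ref_end: int
    comp_chromosome: str
    comp_taxon_id: int
    comp_start: int
    comp_end: int
    orientation: Literal["+", "-"]
    block_id: str
    anchors: tuple[OrthologPair, ...] = field(default=(), compare=False)

    def __post_init__(self):
        if self.ref_start > self.ref_end or self.comp_start > self.comp_end:
            raise ValidationError(f"block {self.block_id}: inverted span")
        if self.orientation not in ("+", "-"):
            raise ValidationError(
                f"block {self.block_id}: orientation must be '+' or '-', got {self.orientation!r}"
            )

    def ref_overlaps(self, chromosome: str, start: int, end: int) -> bool:
        return self.ref_chromosome == chromosome and self.ref_start <= end and self.ref_end >= start


def _position_key(f: GeneFeature) -> tuple:
    # chromosome, start, then end and ID purely as deterministic tie-breaks
    return (f.chromosome, f.start, f.end, f.feature_id)


def read_ortholog_pairs(path: str | Path) -> list[OrthologPair]:
    """Read a two-column TSV of (ref_feature_id, comp_feature_id); ``#`` comments allowed."""
    path = Path(path)
    pairs: list[OrthologPair] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise ParseError(f"expected 2 tab-separated columns, got {len(cols)}",
                                 str(path), lineno)
            pairs.append(OrthologPair(cols[0], cols[1]))
    return pairs


def write_ortholog_pairs(pairs: Iterable[OrthologPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# ref_feature_id\tcomp_feature_id\n")
        for p in pairs:
            fh.write(f"{p.ref_feature_id}\t{p.comp_feature_id}\n")


def _reduce_one_to_one(
    pairs: Sequence[OrthologPair],
    ref_by_id: dict[str, GeneFeature],
    comp_by_id: dict[str, GeneFeature],
    multi_policy: MultiPolicy,
) -> list[OrthologPair]:
    """Reduce a possibly many-to-many relation to a bijection per the policy."""
    unique = list(dict.fromkeys(pairs))  # dedupe, preserve order
    if multi_policy == "drop_ambiguous":
        ref_counts: dict[str, int] = {}
        comp_counts: dict[str, int] = {}
        for p in unique:
            ref_counts[p.ref_feature_id] = ref_counts.get(p.ref_feature_id, 0) + 1
            comp_counts[p.comp_feature_id] = comp_counts.get(p.comp_feature_id, 0) + 1
        kept = [p for p in unique
                if ref_counts[p.ref_feature_id] == 1 and comp_counts[p.comp_feature_id] == 1]
    elif multi_policy == "keep_first_by_position":
        # for each ref gene keep the positionally first comparison partner,
        # then enforce injectivity on the comparison side the same way
        best_for_ref: dict[str, OrthologPair] = {}
        for p in unique:
            cur = best_for_ref.get(p.ref_feature_id)
            if cur is None or _position_key(comp_by_id[p.comp_feature_id]) < _position_key(
                comp_by_id[cur.comp_feature_id]
            ):
                best_for_ref[p.ref_feature_id] = p
        best_for_comp: dict[str, OrthologPair] = {}
        for p in best_for_ref.values():
            cur = best_for_comp.get(p.comp_feature_id)
            if cur is None or _position_key(ref_by_id[p.ref_feature_id]) < _position_key(
                ref_by_id[cur.ref_feature_id]
            ):
                best_for_comp[p.comp_feature_id] = p
        kept = list(best_for_comp.values())
    else:
        raise ValueError(f"unknown multi_policy {multi_policy!r}")
    dropped = len(unique) - len(kept)
    if dropped:
        logger.info("ortholog reduction (%s): dropped %d of %d pairs", multi_policy, dropped, len(unique))
    return kept


def index_anchors(
    ref_features: Iterable[GeneFeature],
    comp_features: Iterable[GeneFeature],
    pairs: Sequence[OrthologPair],
    multi_policy: MultiPolicy = "drop_ambiguous",
) -> AnchorIndex:
    """Build the numbered anchor index from features and the ortholog relation.

    The pair set is first reduced to a one-to-one relation (``drop_ambiguous``
    removes every gene involved in a multi-mapping; ``keep_first_by_position``
    keeps the positionally first partner). Each genome's surviving genes are
    then sorted by (chromosome, start) and numbered starting at 1.

    Raises
    ------
    ValidationError
        If any pair references a feature ID absent from the loaded features;
        the message lists every offending ID.
    """
    ref_by_id = {f.feature_id: f for f in ref_features}
    comp_by_id = {f.feature_id: f for f in comp_features}
    missing = sorted(
        {p.ref_feature_id for p in pairs if p.ref_feature_id not in ref_by_id}
        | {p.comp_feature_id for p in pairs if p.comp_feature_id not in comp_by_id}
    )
    if missing:
        raise ValidationError(f"ortholog pairs reference unknown feature IDs: {', '.join(missing)}")

    kept = _reduce_one_to_one(pairs, ref_by_id, comp_by_id, multi_policy)
    ref_anchored = sorted((ref_by_id[p.ref_feature_id] for p in kept), key=_position_key)
    comp_anchored = sorted((comp_by_id[p.comp_feature_id] for p in kept), key=_position_key)
    ref_ord = {f.feature_id: i for i, f in enumerate(ref_anchored, start=1)}
    comp_ord = {f.feature_id: i for i, f in enumerate(comp_anchored, start=1)}

    anchors = tuple(
        sorted(
            (
                Anchor(
                    ref=ref_by_id[p.ref_feature_id],
                    comp=comp_by_id[p.comp_feature_id],
                    ref_ordinal=ref_ord[p.ref_feature_id],
                    comp_ordinal=comp_ord[p.comp_feature_id],
                )
                for p in kept
            ),
            key=lambda a: a.ref_ordinal,
        )
    )
    return AnchorIndex(ref_order=tuple(ref_anchored), comp_order=tuple(comp_anchored), anchors=anchors)


def default_id_tag(ref_taxon_id: int | None, comp_taxon_id: int | None) -> str:
    """Short tag for block IDs, e.g. mouse/human -> ``mmhs``."""
    if ref_taxon_id is None or comp_taxon_id is None:
        return "blocks"
    r = TAXON_TAGS.get(ref_taxon_id, str(ref_taxon_id))
    c = TAXON_TAGS.get(comp_taxon_id, str(comp_taxon_id))
    return f"{r}{c}"


def compute_blocks(
    anchor_index: AnchorIndex,
    min_anchors: int = 2,
    mode: RunMode = "consecutive",
    id_tag: str | None = None,
) -> list[SyntenyBlock]:
    """Detect synteny blocks as maximal runs of sequential comparison ordinals.

    Scanning anchors in reference order, a run extends while the comparison
    ordinal changes by exactly +1 (ascending) or -1 (descending) relative to the
    previous anchor and neither genome's chromosome changes. Each maximal run of
    at least `min_anchors` anchors becomes one block; orientation is "+" for
    ascending and "-" for descending runs. A single-anchor run has no defined
    direction and is reported as "+" (only ever emitted when ``min_anchors=1``).

    ``mode="monotonic"`` relaxes the step rule to any positive (resp. negative)
    ordinal change of constant sign.

    Blocks are emitted in reference order with IDs ``SynBlock:<tag>:<n>``.
    """
    if min_anchors < 1:
        raise ValueError("min_anchors must be >= 1")
    anchors = anchor_index.anchors
    if not anchors:
        return []
    if id_tag is None:
        id_tag = default_id_tag(anchor_index.ref_taxon_id, anchor_index.comp_taxon_id)

    runs: list[list[Anchor]] = []
    run = [anchors[0]]
    direction = 0  # 0 = undetermined, +1 ascending, -1 descending
    for prev, cur in zip(anchors, anchors[1:]):
        delta = cur.comp_ordinal - prev.comp_ordinal
        same_chroms = (
            cur.ref.chromosome == prev.ref.chromosome
            and cur.comp.chromosome == prev.comp.chromosome
        )
        if mode == "consecutive":
            step_ok = delta in (1, -1) if direction == 0 else delta == direction
        else:
            step_ok = delta != 0 if direction == 0 else (delta > 0) == (direction > 0)
        if same_chroms and step_ok:
            if direction == 0:
                direction = 1 if delta > 0 else -1
            run.append(cur)
        else:
            runs.append(run)
            run = [cur]
            direction = 0
    runs.append(run)

    blocks: list[SyntenyBlock] = []
    n = 0
    for run in runs:
        if len(run) < min_anchors:
            continue
        n += 1
        ascending = len(run) == 1 or run[1].comp_ordinal > run[0].comp_ordinal
        refs = [a.ref for a in run]
        comps = [a.comp for a in run]
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
                anchors=tuple(a.pair for a in run),
            )
        )
    return blocks


_BLOCK_COLUMNS = 10


def write_block_file(blocks: Iterable[SyntenyBlock], path: str | Path) -> None:
    """Write blocks in the 10-column tab-delimited block format.

    Columns: reference chromosome, taxon ID, start, end; comparison chromosome,
    taxon ID, start, end; orientation (+/-); ``ID=<unique id>``.
    """
    path = Path(path)
    seen: set[str] = set()
    with open(path, "w") as fh:
        for b in blocks:
            if b.block_id in seen:
                raise ValidationError(f"duplicate block ID {b.block_id!r}")
            seen.add(b.block_id)
            fh.write(
                "\t".join(
                    [
                        b.ref_chromosome, str(b.ref_taxon_id), str(b.ref_start), str(b.ref_end),
                        b.comp_chromosome, str(b.comp_taxon_id), str(b.comp_start), str(b.comp_end),
                        b.orientation, f"ID={b.block_id}",
                    ]
                )
                + "\n"
            )


def read_block_file(path: str | Path) -> list[SyntenyBlock]:
    """Read a 10-column block file. Anchors are not carried by the format.

    The final column is accepted either bare or ``ID=``-prefixed. Duplicate
    block IDs, bad orientations, and wrong column counts are errors.
    """
    path = Path(path)
    blocks: list[SyntenyBlock] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != _BLOCK_COLUMNS:
                raise ParseError(
                    f"expected {_BLOCK_COLUMNS} tab-separated columns, got {len(cols)}",
                    str(path), lineno,
                )
            orientation = cols[8].strip()
            if orientation not in ("+", "-"):
                raise ParseError(f"orientation must be '+' or '-', got {orientation!r}",
                                 str(path), lineno)
            block_id = cols[9].strip()
            if block_id.startswith("ID="):
                block_id = block_id[3:]
            if not block_id:
                raise ParseError("empty block ID", str(path), lineno)
            if block_id in seen:
                raise ParseError(f"duplicate block ID {block_id!r}", str(path), lineno)
            seen.add(block_id)
            try:
                block = SyntenyBlock(
                    ref_chromosome=cols[0], ref_taxon_id=int(cols[1]),
                    ref_start=int(cols[2]), ref_end=int(cols[3]),
                    comp_chromosome=cols[4], comp_taxon_id=int(cols[5]),
                    comp_start=int(cols[6]), comp_end=int(cols[7]),
                    orientation=orientation, block_id=block_id,
                )
            except (ValueError, ValidationError) as exc:
                raise ParseError(str(exc), str(path), lineno) from exc
            blocks.append(block)
    return blocks


__all__ = [
    "OrthologPair", "Anchor", "AnchorIndex", "SyntenyBlock",
    "read_ortholog_pairs", "write_ortholog_pairs", "index_anchors",
    "compute_blocks", "write_block_file", "read_block_file",
    "default_id_tag", "TAXON_TAGS",
]
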