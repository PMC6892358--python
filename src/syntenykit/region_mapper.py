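"""Cross-genome interval mapping and genome-level synteny summaries.

This is the data behind the circular genome overview (reference outer ring,
comparison inner ring, arcs to syntenic regions) and the block-detail track
correspondence. Mapping granularity is deliberately coarse: a reference
interval maps to the full comparison span of each overlapping block, plus an
anchor-trimmed span (the hull of the comparison genes whose reference partners
overlap the interval). No base-pair interpolation inside blocks is attempted —
the block model defines no within-block coordinate system.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .genome_model import FeatureSet, GeneFeature, RegionSelection
from .synteny_blocks import SyntenyBlock

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MappedInterval:
    """One block's contribution to a reference-interval mapping."""

    block_id: str
    orientation: str
    ref_chromosome: str
    ref_start: int          # region ∩ block reference span
    ref_end: int
    comp_chromosome: str
    comp_start: int         # full block comparison span
    comp_end: int
    anchor_comp_start: int | None = None  # hull of anchors overlapping the region
    anchor_comp_end: int | None = None


def _as_lookup(features: Iterable[GeneFeature] | FeatureSet | Mapping[str, GeneFeature] | None):
    if features is None:
        return None
    if isinstance(features, Mapping):
        return features
    return {f.feature_id: f for f in features}


def map_region(
    region: RegionSelection,
    blocks: Sequence[SyntenyBlock],
    ref_features: Iterable[GeneFeature] | FeatureSet | Mapping[str, GeneFeature] | None = None,
    comp_features: Iterable[GeneFeature] | FeatureSet | Mapping[str, GeneFeature] | None = None,
) -> list[MappedInterval]:
    """Map a reference-genome interval into the comparison genome.

    One :class:`MappedInterval` is produced per block overlapping the region,
    ordered by reference position. When feature lookups are supplied and the
    block carries anchors, the anchor-trimmed span is the min..max comparison
    coordinates of anchors whose reference gene overlaps the region; for an
    inverted ("-") block that hull sits at the far end of the block as the
    region slides forward.
    """
    ref_lookup = _as_lookup(ref_features)
    comp_lookup = _as_lookup(comp_features)
    out: list[MappedInterval] = []
    for b in blocks:
        if not b.ref_overlaps(region.chromosome, region.start, region.end):
            continue
        anchor_start = anchor_end = None
        if b.anchors and ref_lookup is not None and comp_lookup is not None:
            comp_spans = []
            for pair in b.anchors:
                rf = ref_lookup.get(pair.ref_feature_id)
                cf = comp_lookup.get(pair.comp_feature_id)
                if rf is None or cf is None:
                    continue
                if rf.start <= region.end and rf.end >= region.start:
                    comp_spans.append((cf.start, cf.end))
            if comp_spans:
                anchor_start = min(s for s, _ in comp_spans)
                anchor_end = max(e for _, e in comp_spans)
        out.append(
            MappedInterval(
                block_id=b.block_id,
                orientation=b.orientation,
                ref_chromosome=b.ref_chromosome,
                ref_start=max(region.start, b.ref_start),
                ref_end=min(region.end, b.ref_end),
                comp_chromosome=b.comp_chromosome,
                comp_start=b.comp_start,
                comp_end=b.comp_end,
                anchor_comp_start=anchor_start,
                anchor_comp_end=anchor_end,
            )
        )
    out.sort(key=lambda m: (m.ref_chromosome, m.ref_start, m.ref_end, m.block_id))
    return out


def genome_overview(blocks: Sequence[SyntenyBlock]) -> dict[str, list[dict]]:
    """All blocks grouped by reference chromosome — the data for the circos arcs.

    Returns a JSON-serializable mapping ``ref_chromosome -> [arc, ...]`` where
    each arc carries the reference span, the comparison chromosome and span, the
    orientation, and the block ID. Every block appears exactly once.
    """
    grouped: dict[str, list[dict]] = {}
    for b in sorted(blocks, key=lambda b: (b.ref_chromosome, b.ref_start, b.ref_end, b.block_id)):
        grouped.setdefault(b.ref_chromosome, []).append(
            {
                "block_id": b.block_id,
                "ref_start": b.ref_start,
                "ref_end": b.ref_end,
                "comp_chromosome": b.comp_chromosome,
                "comp_start": b.comp_start,
                "comp_end": b.comp_end,
                "orientation": b.orientation,
            }
        )
    return grouped


def anchor_guidelines(
    block: SyntenyBlock,
    ref_features: Iterable[GeneFeature] | FeatureSet | Mapping[str, GeneFeature],
    comp_features: Iterable[GeneFeature] | FeatureSet | Mapping[str, GeneFeature],
) -> list[tuple[tuple[int, int], tuple[int, int]]]:
    """Per-anchor (reference span, comparison span) pairs, in reference order.

    These are the guidelines the block-detail view draws between tracks. Blocks
    read from a block file carry no anchors; for those an empty list is returned
    with a warning.
    """
    if not block.anchors:
        logger.warning("block %s carries no anchors (loaded from file?); no guidelines",
                       block.block_id)
        return []
    ref_lookup = _as_lookup(ref_features)
    comp_lookup = _as_lookup(comp_features)
    pairs = []
    for p in block.anchors:
        rf, cf = ref_lookup.get(p.ref_feature_id), comp_lookup.get(p.comp_feature_id)
        if rf is None or cf is None:
            logger.warning("block %s: anchor %s/%s not resolvable to features",
                           block.block_id, p.ref_feature_id, p.comp_feature_id)
            continue
        pairs.append(((rf.start, rf.end), (cf.start, cf.end)))
    return pairs


__all__ = ["MappedInterval", "map_region", "genome_overview", "anchor_guidelines"]
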