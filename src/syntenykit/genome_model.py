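"""Domain types for genomes and gene features, GFF3 ingestion, and genome configs.

Coordinates are 1-based and inclusive throughout (the GFF3 convention); every
downstream module — block detection, the block file format, region queries —
inherits this convention. Chromosome names are stored without a ``chr`` prefix;
readers strip it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import yaml
from gffutils.feature import feature_from_line
from intervaltree import IntervalTree

from .errors import ConfigError, ParseError, ValidationError

logger = logging.getLogger(__name__)

OverlapMode = Literal["any_overlap", "contained"]

#: sort key used everywhere a feature list is emitted — a total order
def feature_sort_key(f: "GeneFeature") -> tuple:
    return (f.chromosome, f.start, f.end, f.feature_id)


def strip_chr(name: str) -> str:
    """Normalize a chromosome name by stripping a leading ``chr`` prefix."""
    return name[3:] if name.lower().startswith("chr") else name


@dataclass(frozen=True)
class GeneFeature:
    """One genome feature (gene, QTL, lncRNA, ...) with a 1-based inclusive span."""

    feature_id: str
    symbol: str
    taxon_id: int
    chromosome: str
    start: int
    end: int
    strand: str = "."
    feature_type: str = "gene"

    def __post_init__(self):
        if self.start < 1 or self.start > self.end:
            raise ValidationError(
                f"feature {self.feature_id}: invalid span {self.start}-{self.end} "
                "(need 1 <= start <= end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"feature {self.feature_id}: bad strand {self.strand!r}")

    def overlaps(self, chromosome: str, start: int, end: int) -> bool:
        return self.chromosome == chromosome and self.start <= end and self.end >= start

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GenomeBuild:
    """A genome assembly: taxon, build name, ordered chromosome sizes, browser role."""

    taxon_id: int
    build_name: str
    chromosomes: tuple[tuple[str, int], ...]
    role: Literal["reference", "comparison"] = "reference"

    def __post_init__(self):
        if self.taxon_id <= 0:
            raise ValidationError(f"taxon_id must be positive, got {self.taxon_id}")
        names = [c[0] for c in self.chromosomes]
        if len(names) != len(set(names)):
            raise ValidationError("duplicate chromosome names in build")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValidationError(f"chromosome {name}: non-positive length {length}")
        if self.role not in ("reference", "comparison"):
            raise ValidationError(f"role must be reference or comparison, got {self.role!r}")

    @property
    def chromosome_names(self) -> tuple[str, ...]:
        return tuple(c[0] for c in self.chromosomes)

    def chromosome_length(self, name: str) -> int | None:
        for n, length in self.chromosomes:
            if n == name:
                return length
        return None


@dataclass(frozen=True)
class RegionSelection:
    """A genomic interval on one genome, 1-based inclusive."""

    taxon_id: int
    chromosome: str
    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValidationError(f"region start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GenomeConfig:
    """Per-genome configuration: the build plus which ontologies are available."""

    build: GenomeBuild
    ontologies: tuple[str, ...] = ()
    symbol_attribute: str = "Name"
    extras: Mapping[str, object] = field(default_factory=dict)


_GFF3_COLUMNS = 9
_KNOWN_CONFIG_KEYS = {
    "taxon_id", "build_name", "role", "chromosomes", "ontologies", "symbol_attribute",
}


def read_gff3(
    path: str | Path,
    taxon_id: int,
    feature_types: Sequence[str] | None = None,
    symbol_attribute: str = "Name",
) -> list[GeneFeature]:
    """Read top-level features from a GFF3 file into :class:`GeneFeature` records.

    Parameters
    ----------
    path
        GFF3 file; column 9 must carry an ``ID`` attribute, the symbol is taken
        from `symbol_attribute` (falling back to the ID).
    taxon_id
        NCBI taxon the features belong to (stamped on every record).
    feature_types
        If given, only rows whose column-3 type is in this list are kept; the
        number of skipped rows is logged. ``None`` keeps every row.

    Coordinates are kept 1-based inclusive, exactly as in the file.
    """
    path = Path(path)
    wanted = set(feature_types) if feature_types is not None else None
    features: list[GeneFeature] = []
    seen_ids: set[str] = set()
    skipped = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith("##FASTA"):
                break
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != _GFF3_COLUMNS:
                raise ParseError(
                    f"expected {_GFF3_COLUMNS} tab-separated columns, got {len(cols)}",
                    path=str(path), line_number=lineno,
                )
            try:
                gff = feature_from_line(line)
            except Exception as exc:  # noqa: BLE001 - surfaced with line context
                raise ParseError(f"malformed GFF3 row: {exc}", str(path), lineno) from exc
            if wanted is not None and gff.featuretype not in wanted:
                skipped += 1
                continue
            attrs = gff.attributes
            fid_vals = attrs.get("ID", [])
            if not fid_vals:
                raise ParseError("row has no ID attribute", str(path), lineno)
            fid = fid_vals[0]
            if fid in seen_ids:
                raise ValidationError(f"duplicate feature ID {fid!r} in {path}")
            seen_ids.add(fid)
            symbol = attrs.get(symbol_attribute, [fid])[0]
            if gff.start > gff.end:
                raise ValidationError(
                    f"{path}:{lineno}: feature {fid}: start {gff.start} > end {gff.end}"
                )
            features.append(
                GeneFeature(
                    feature_id=fid,
                    symbol=symbol,
                    taxon_id=taxon_id,
                    chromosome=strip_chr(gff.seqid),
                    start=gff.start,
                    end=gff.end,
                    strand=gff.strand if gff.strand in ("+", "-") else ".",
                    feature_type=gff.featuretype,
                )
            )
    logger.info("read_gff3(%s): parsed %d features, skipped %d rows", path, len(features), skipped)
    return features


def write_gff3(
    features: Iterable[GeneFeature],
    path: str | Path,
    source: str = "syntenykit",
    symbol_attribute: str = "Name",
) -> None:
    """Write features back out as GFF3 (inverse of :func:`read_gff3`)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in sorted(features, key=feature_sort_key):
            attrs = f"ID={f.feature_id};{symbol_attribute}={f.symbol}"
            fh.write(
                "\t".join(
                    [f.chromosome, source, f.feature_type, str(f.start), str(f.end),
                     ".", f.strand, ".", attrs]
                )
                + "\n"
            )


def load_genome_config(path: str | Path) -> GenomeConfig:
    """Load a per-genome YAML/JSON configuration file.

    Required keys: ``taxon_id``, ``chromosomes`` (list of ``{name, length}`` or
    ``[name, length]`` pairs). Optional: ``build_name``, ``role``, ``ontologies``,
    ``symbol_attribute``. Unknown keys are warned about, never fatal.
    """
    path = Path(path)
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    unknown = set(data) - _KNOWN_CONFIG_KEYS
    if unknown:
        logger.warning("%s: ignoring unknown config keys: %s", path, sorted(unknown))
    if "taxon_id" not in data:
        raise ConfigError(f"{path}: missing required key 'taxon_id'")
    if "chromosomes" not in data or not data["chromosomes"]:
        raise ConfigError(f"{path}: missing required key 'chromosomes'")
    chroms: list[tuple[str, int]] = []
    for entry in data["chromosomes"]:
        if isinstance(entry, dict):
            chroms.append((strip_chr(str(entry["name"])), int(entry["length"])))
        else:
            name, length = entry
            chroms.append((strip_chr(str(name)), int(length)))
    try:
        build = GenomeBuild(
            taxon_id=int(data["taxon_id"]),
            build_name=str(data.get("build_name", "unknown")),
            chromosomes=tuple(chroms),
            role=data.get("role", "reference"),
        )
    except ValidationError as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    return GenomeConfig(
        build=build,
        ontologies=tuple(data.get("ontologies", ())),
        symbol_attribute=str(data.get("symbol_attribute", "Name")),
        extras={k: data[k] for k in unknown},
    )


def load_config_pair(ref_path: str | Path, comp_path: str | Path) -> tuple[GenomeConfig, GenomeConfig]:
    """Load the reference and comparison configs together, checking role consistency."""
    ref = load_genome_config(ref_path)
    comp = load_genome_config(comp_path)
    if ref.build.role == comp.build.role:
        raise ConfigError(
            f"duplicate role: both configs declare role={ref.build.role!r}; "
            "one genome must be 'reference' and the other 'comparison'"
        )
    if ref.build.role != "reference":
        ref, comp = comp, ref
    return ref, comp


class FeatureSet:
    """Interval-indexed collection of features for fast region queries."""

    def __init__(self, features: Iterable[GeneFeature]):
        self._features = sorted(features, key=feature_sort_key)
        self._by_id: dict[str, GeneFeature] = {}
        self._trees: dict[str, IntervalTree] = {}
        for f in self._features:
            if f.feature_id in self._by_id:
                raise ValidationError(f"duplicate feature ID {f.feature_id!r}")
            self._by_id[f.feature_id] = f
            # IntervalTree is half-open; +1 converts the inclusive end
            self._trees.setdefault(f.chromosome, IntervalTree()).addi(f.start, f.end + 1, f)

    def __len__(self) -> int:
        return len(self._features)

    def __iter__(self):
        return iter(self._features)

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self._by_id

    def get(self, feature_id: str) -> GeneFeature | None:
        return self._by_id.get(feature_id)

    def __getitem__(self, feature_id: str) -> GeneFeature:
        return self._by_id[feature_id]

    @property
    def chromosomes(self) -> tuple[str, ...]:
        return tuple(sorted(self._trees))

    def in_region(self, region: RegionSelection, overlap_mode: OverlapMode = "any_overlap") -> list[GeneFeature]:
        if overlap_mode not in ("any_overlap", "contained"):
            raise ValueError(f"unknown overlap_mode {overlap_mode!r}")
        tree = self._trees.get(strip_chr(region.chromosome))
        if tree is None:
            logger.warning("region chromosome %r has no features", region.chromosome)
            return []
        hits = [iv.data for iv in tree.overlap(region.start, region.end + 1)]
        if overlap_mode == "contained":
            hits = [f for f in hits if f.start >= region.start and f.end <= region.end]
        return sorted(hits, key=feature_sort_key)


def features_in_region(
    features: Iterable[GeneFeature] | FeatureSet,
    region: RegionSelection,
    overlap_mode: OverlapMode = "any_overlap",
) -> list[GeneFeature]:
    """Features overlapping (or contained in) a region, sorted deterministically.

    ``any_overlap`` keeps features with ``start <= region.end and end >= region.start``
    (inclusive-coordinate touch counts); ``contained`` requires full containment.
    """
    fs = features if isinstance(features, FeatureSet) else FeatureSet(features)
    return fs.in_region(region, overlap_mode)


__all__ = [
    "GeneFeature", "GenomeBuild", "RegionSelection", "GenomeConfig", "FeatureSet",
    "read_gff3", "write_gff3", "load_genome_config", "load_config_pair",
    "features_in_region", "feature_sort_key", "strip_chr",
]
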