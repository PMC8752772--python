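"""Annotation of copy number variants with counts of overlapped genomic elements.

A CNV (copy number loss or gain) is described only by its genomic interval and
type.  Its feature vector is the number of elements it overlaps in each of a
fixed set of categorized element tracks: gene classes (protein-coding genes,
pseudogenes, RNA genes, morbid and disease-associated genes), regulatory
classes (enhancers, promoters, CTCF/TF binding sites, ...), and
dosage-sensitivity tracks (haploinsufficient genes/regions for losses,
triplosensitive regions for gains, restricted to the highest evidence score).

Coordinates are 0-based half-open (BED convention) throughout.  "Overlap"
means sharing at least one base; no reciprocal-overlap fraction is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "CnvType",
    "FiveTierLabel",
    "CNVRecord",
    "AnnotationSchema",
    "ElementCatalog",
    "FeatureVector",
    "LOSS_ATTRIBUTES",
    "GAIN_ATTRIBUTES",
    "CATEGORY_VOCABULARY",
    "DOSAGE_CATEGORIES",
    "count_overlapping_elements",
    "filter_dosage_sensitive",
    "annotate_cnv",
    "annotate_cnvs",
    "tile_genome",
]


class ValidationError(ValueError):
    """Raised when an input record violates a structural invariant."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class CnvType(str, Enum):
    LOSS = "loss"
    GAIN = "gain"


class FiveTierLabel(str, Enum):
    BENIGN = "benign"
    LIKELY_BENIGN = "likely_benign"
    UNCERTAIN = "uncertain"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    PATHOGENIC = "pathogenic"


@dataclass
class CNVRecord:
    """One structural variant: interval, type, optional multiplicity and label.

    Multiplicity is the resulting copy number of the region: 0 or 1 for
    losses (homozygous / heterozygous deletion), >= 3 for gains.
    """

    interval: GenomicInterval
    cnv_type: CnvType
    multiplicity: int | None = None
    label: FiveTierLabel | None = None
    source_id: str | None = None

    def __post_init__(self) -> None:
        if self.multiplicity is not None:
            if self.cnv_type is CnvType.LOSS and self.multiplicity not in (0, 1):
                raise ValidationError(
                    f"loss multiplicity must be 0 or 1, got {self.multiplicity} "
                    f"({self.source_id or self.interval})"
                )
            if self.cnv_type is CnvType.GAIN and self.multiplicity < 3:
                raise ValidationError(
                    f"gain multiplicity must be >= 3, got {self.multiplicity} "
                    f"({self.source_id or self.interval})"
                )

    @property
    def length(self) -> int:
        return self.interval.length


# Fixed attribute vocabulary.  The first 19 apply to losses; gains drop the
# two haploinsufficiency attributes and add triplosensitive regions.
LOSS_ATTRIBUTES: tuple[str, ...] = (
    "overlapped_gencode_elements",
    "protein_coding_genes",
    "pseudogenes",
    "micro_rna",
    "long_noncoding_rna",
    "ribosomal_rna",
    "small_nuclear_rna",
    "morbid_genes",
    "disease_associated_genes",
    "haploinsufficient_genes",
    "haploinsufficient_regions",
    "regulatory_elements",
    "enhancers",
    "open_chromatin_regions",
    "promoters",
    "promoter_flanking_regions",
    "ctcf_binding_sites",
    "tf_binding_sites",
    "curated_regulatory_elements",
)

GAIN_ATTRIBUTES: tuple[str, ...] = tuple(
    a
    for a in LOSS_ATTRIBUTES
    if a not in ("haploinsufficient_genes", "haploinsufficient_regions")
) + ("triplosensitive_regions",)

CATEGORY_VOCABULARY: frozenset[str] = frozenset(LOSS_ATTRIBUTES) | frozenset(
    GAIN_ATTRIBUTES
)

#: Categories whose elements carry a dosage-sensitivity evidence score.
DOSAGE_CATEGORIES: frozenset[str] = frozenset(
    {
        "haploinsufficient_genes",
        "haploinsufficient_regions",
        "triplosensitive_regions",
    }
)


@dataclass(frozen=True)
class AnnotationSchema:
    """Ordered attribute list for one CNV type."""

    cnv_type: CnvType
    attribute_names: tuple[str, ...]

    @classmethod
    def for_type(cls, cnv_type: CnvType) -> "AnnotationSchema":
        names = LOSS_ATTRIBUTES if cnv_type is CnvType.LOSS else GAIN_ATTRIBUTES
        return cls(cnv_type=cnv_type, attribute_names=names)

    def __len__(self) -> int:
        return len(self.attribute_names)


class _TrackIndex:
    """Per-chromosome sorted endpoint arrays for O(log n) overlap counting.

    For a half-open query [qs, qe) on one chromosome, the number of elements
    overlapping it equals::

        n_chrom - #(element.end <= qs) - #(element.start >= qe)

    The two excluded sets are disjoint (an element cannot end before the
    query and start after it), so the identity is exact for any-overlap
    semantics regardless of nesting or ties.
    """

    def __init__(self, intervals: Sequence[GenomicInterval]):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for chrom, pairs in by_chrom.items():
            arr = np.asarray(pairs, dtype=np.int64)
            self._starts[chrom] = np.sort(arr[:, 0])
            self._ends[chrom] = np.sort(arr[:, 1])

    def count(self, query: GenomicInterval) -> int:
        starts = self._starts.get(query.chrom)
        if starts is None:
            return 0
        ends = self._ends[query.chrom]
        n = len(starts)
        ended_before = int(np.searchsorted(ends, query.start, side="right"))
        start_after = n - int(np.searchsorted(starts, query.end, side="left"))
        return n - ended_before - start_after

    def count_many(self, queries: Sequence[GenomicInterval]) -> np.ndarray:
        return np.fromiter(
            (self.count(q) for q in queries), dtype=np.int64, count=len(queries)
        )


@dataclass
class ElementCatalog:
    """Named category tracks of genomic intervals.

    ``dosage_scores`` holds per-element integer evidence scores, parallel to
    the corresponding track, for dosage-sensitivity categories.  Unknown
    category names are ignored with a warning so that extra tracks in input
    files do not abort an annotation run.
    """

    tracks: dict[str, list[GenomicInterval]] = field(default_factory=dict)
    dosage_scores: dict[str, list[int | None]] = field(default_factory=dict)
    _indexes: dict[str, _TrackIndex] = field(default_factory=dict, repr=False)

    def add_track(
        self,
        category: str,
        intervals: Iterable[GenomicInterval],
        scores: Iterable[int | None] | None = None,
    ) -> None:
        if category not in CATEGORY_VOCABULARY:
            logger.warning("ignoring unknown element category %r", category)
            return
        ivs = list(intervals)
        self.tracks.setdefault(category, []).extend(ivs)
        if scores is not None:
            self.dosage_scores.setdefault(category, []).extend(scores)
        self._indexes.pop(category, None)

    def filter_dosage_tracks(self, required_score: int = 3) -> None:
        """Restrict dosage-sensitivity tracks to elements with the given score."""
        for category in DOSAGE_CATEGORIES & self.tracks.keys():
            scores = self.dosage_scores.get(category)
            self.tracks[category] = filter_dosage_sensitive(
                self.tracks[category], scores, required_score
            )
            self.dosage_scores[category] = [required_score] * len(
                self.tracks[category]
            )
            self._indexes.pop(category, None)

    def index_for(self, category: str) -> _TrackIndex:
        idx = self._indexes.get(category)
        if idx is None:
            idx = _TrackIndex(self.tracks.get(category, []))
            self._indexes[category] = idx
        return idx

    def chromosomes(self) -> set[str]:
        return {iv.chrom for ivs in self.tracks.values() for iv in ivs}


@dataclass
class FeatureVector:
    """Ordered non-negative overlap counts, one per schema attribute."""

    schema: AnnotationSchema
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.counts) != len(self.schema):
            raise ValidationError(
                f"feature vector length {len(self.counts)} != schema length "
                f"{len(self.schema)}"
            )
        if (self.counts < 0).any():
            raise ValidationError("feature counts must be non-negative")

    def as_dict(self) -> dict[str, int]:
        return dict(zip(self.schema.attribute_names, self.counts.tolist()))


def count_overlapping_elements(
    cnv_interval: GenomicInterval, track: Sequence[GenomicInterval]
) -> int:
    """Number of track elements sharing >= 1 base with the CNV interval.

    Each element is counted at most once; elements on other chromosomes never
    count.
    """
    return _TrackIndex(track).count(cnv_interval)


def filter_dosage_sensitive(
    track: Sequence[GenomicInterval],
    scores: Sequence[int | None] | None,
    required_score: int = 3,
) -> list[GenomicInterval]:
    """Keep exactly the elements whose dosage score equals ``required_score``.

    Score 3 denotes sufficient evidence for a dosage-sensitivity mechanism;
    the filter is equality, not >=, because higher codes (e.g. 40) mark
    different evidence categories, not stronger evidence.
    """
    if scores is None or len(scores) != len(track):
        raise ValidationError(
            "dosage-sensitivity track requires one integer score per element"
        )
    kept = []
    for iv, score in zip(track, scores):
        if score is None:
            raise ValidationError(f"element {iv} is missing a dosage score")
        if score == required_score:
            kept.append(iv)
    return kept


def _schema_categories_missing(
    schema: AnnotationSchema, catalog: ElementCatalog
) -> list[str]:
    return [a for a in schema.attribute_names if a not in catalog.tracks]


class ConfigurationError(ValueError):
    """Raised when a catalog does not cover the schema it must annotate."""


def annotate_cnv(cnv: CNVRecord, catalog: ElementCatalog) -> FeatureVector:
    """Feature vector of per-category overlap counts for one CNV.

    Loss vectors include the haploinsufficiency attributes and exclude
    triplosensitivity; gain vectors the converse.
    """
    schema = AnnotationSchema.for_type(cnv.cnv_type)
    missing = _schema_categories_missing(schema, catalog)
    if missing:
        raise ConfigurationError(
            f"catalog is missing categories required by the {cnv.cnv_type.value} "
            f"schema: {', '.join(missing)}"
        )
    counts = np.array(
        [
            catalog.index_for(name).count(cnv.interval)
            for name in schema.attribute_names
        ],
        dtype=np.int64,
    )
    return FeatureVector(schema=schema, counts=counts)


def annotate_cnvs(
    cnvs: Sequence[CNVRecord], catalog: ElementCatalog
) -> "np.ndarray":
    """Annotate many CNVs of one type; returns an (n, n_attributes) count matrix."""
    if not cnvs:
        raise ValidationError("no CNV records to annotate")
    types = {c.cnv_type for c in cnvs}
    if len(types) != 1:
        raise ValidationError("annotate_cnvs requires records of a single CNV type")
    schema = AnnotationSchema.for_type(cnvs[0].cnv_type)
    missing = _schema_categories_missing(schema, catalog)
    if missing:
        raise ConfigurationError(
            f"catalog is missing categories: {', '.join(missing)}"
        )
    queries = [c.interval for c in cnvs]
    cols = [catalog.index_for(name).count_many(queries) for name in schema.attribute_names]
    return np.stack(cols, axis=1)


def tile_genome(
    chrom_sizes: Mapping[str, int], tile_length: int = 1_000_000
) -> list[tuple[CNVRecord, CNVRecord]]:
    """Partition a genome into fixed-length tiles, one (loss, gain) pair each.

    Tiles are consecutive, non-overlapping windows [k*L, (k+1)*L) ordered by
    chromosome then start; the trailing partial tile at each chromosome end is
    included so every base is covered exactly once.  Scoring both a loss and a
    gain per tile maps pathogenicity potential genome-wide without requiring
    any reported variant.
    """
    if tile_length <= 0:
        raise ValidationError(f"tile_length must be positive, got {tile_length}")
    pairs: list[tuple[CNVRecord, CNVRecord]] = []
    for chrom in chrom_sizes:
        size = chrom_sizes[chrom]
        if size < 1:
            raise ValidationError(f"chromosome {chrom} has non-positive size {size}")
        for start in range(0, size, tile_length):
            end = min(start + tile_length, size)
            iv = GenomicInterval(chrom, start, end)
            tile_id = f"{chrom}:{start}-{end}"
            pairs.append(
                (
                    CNVRecord(iv, CnvType.LOSS, source_id=tile_id),
                    CNVRecord(iv, CnvType.GAIN, source_id=tile_id),
                )
            )
    return pairs
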