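"""Download-free synthetic fixtures for the full annotate/train/explain path.

Two generators are provided:

* :func:`sample_feature_dataset` draws labeled overlap-count feature vectors
  directly, matching per-attribute, per-class moments observed on clinically
  classified CNV collections (benign vs. pathogenic means and standard
  deviations of each count attribute).  Counts are drawn from a negative
  binomial parameterized by moment matching — variance far exceeds the mean
  for nearly every attribute — with a Poisson fallback when the variance is
  at or below the mean.  Attributes are sampled independently by default; a
  Gaussian-copula option adds rank correlation between attributes.

* :func:`build_toy_genome` lays out element tracks on a small fictional
  genome with gene-dense and gene-poor regions, then places pathogenic CNVs
  in dense regions and benign CNVs in sparse regions.  It records ground
  truth overlap counts by exhaustive all-pairs checking at generation time,
  so the annotation machinery can be verified against an independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import (
    AnnotationSchema,
    CNVRecord,
    CnvType,
    ConfigurationError,
    ElementCatalog,
    FiveTierLabel,
    GenomicInterval,
    CATEGORY_VOCABULARY,
    DOSAGE_CATEGORIES,
)
from .dataset import LabeledDataset, PartitionTag

__all__ = [
    "CountDistributionSpec",
    "ToyGenomeSpec",
    "ToyGenome",
    "default_moment_specs",
    "sample_feature_dataset",
    "build_toy_genome",
]


@dataclass(frozen=True)
class CountDistributionSpec:
    """First two moments of one count attribute within one class."""

    attribute: str
    label: FiveTierLabel
    mean: float
    std: float

    def __post_init__(self) -> None:
        if self.mean < 0 or self.std < 0:
            raise ConfigurationError("moments must be non-negative")


# Per-class count moments (mean, std) of each attribute among benign and
# pathogenic variants: (benign_mean, benign_std, pathogenic_mean,
# pathogenic_std).  Pathogenic CNVs overlap roughly an order of magnitude
# more elements of almost every category than benign ones.
_LOSS_MOMENTS: dict[str, tuple[float, float, float, float]] = {
    "overlapped_gencode_elements": (4.11, 10.49, 56.43, 54.73),
    "protein_coding_genes": (1.41, 3.29, 19.28, 19.49),
    "pseudogenes": (1.42, 5.46, 11.3, 15.62),
    "micro_rna": (0.07, 0.45, 2.08, 2.98),
    "long_noncoding_rna": (0.79, 1.78, 16.45, 16.34),
    "ribosomal_rna": (0.0, 0.2, 0.02, 0.15),
    "small_nuclear_rna": (0.08, 0.45, 1.2, 2.17),
    "morbid_genes": (0.2, 0.48, 3.84, 3.65),
    "disease_associated_genes": (0.18, 0.46, 3.24, 3.11),
    "haploinsufficient_genes": (0.02, 0.14, 0.48, 0.69),
    "haploinsufficient_regions": (0.06, 0.27, 0.47, 0.67),
    "regulatory_elements": (18.13, 40.77, 453.31, 396.98),
    "enhancers": (3.35, 7.55, 75.64, 72.11),
    "open_chromatin_regions": (3.02, 6.88, 58.18, 53.91),
    "promoters": (1.16, 3.43, 35.69, 37.78),
    "promoter_flanking_regions": (3.41, 8.43, 99.24, 92.16),
    "ctcf_binding_sites": (5.95, 15.41, 53.41, 46.64),
    "tf_binding_sites": (1.11, 3.38, 26.93, 35.99),
    "curated_regulatory_elements": (0.12, 0.61, 4.25, 4.66),
}

_GAIN_MOMENTS: dict[str, tuple[float, float, float, float]] = {
    "overlapped_gencode_elements": (9.46, 18.39, 80.3, 65.18),
    "protein_coding_genes": (2.61, 4.6, 28.17, 25.22),
    "pseudogenes": (3.97, 10.85, 17.34, 19.58),
    "micro_rna": (0.23, 1.18, 2.91, 3.38),
    "long_noncoding_rna": (1.77, 3.16, 21.7, 18.29),
    "ribosomal_rna": (0.0, 0.05, 0.03, 0.2),
    "small_nuclear_rna": (0.19, 0.81, 1.94, 2.9),
    "morbid_genes": (0.37, 0.7, 5.22, 4.6),
    "disease_associated_genes": (0.34, 0.68, 4.26, 3.85),
    "regulatory_elements": (40.36, 59.97, 559.55, 424.5),
    "enhancers": (6.7, 11.01, 82.97, 65.57),
    "open_chromatin_regions": (6.43, 10.76, 66.38, 51.71),
    "promoters": (2.88, 5.3, 51.44, 49.52),
    "promoter_flanking_regions": (7.72, 12.95, 118.6, 91.8),
    "ctcf_binding_sites": (13.77, 23.12, 197.61, 168.01),
    "tf_binding_sites": (2.6, 5.47, 36.9, 44.69),
    "curated_regulatory_elements": (0.26, 0.73, 5.64, 5.28),
    "triplosensitive_regions": (0.02, 0.17, 0.62, 0.74),
}


def default_moment_specs(cnv_type: CnvType) -> list[CountDistributionSpec]:
    """Default per-class moment specs covering the schema for one CNV type."""
    table = _LOSS_MOMENTS if cnv_type is CnvType.LOSS else _GAIN_MOMENTS
    schema = AnnotationSchema.for_type(cnv_type)
    specs = []
    for name in schema.attribute_names:
        bm, bs, pm, ps = table[name]
        specs.append(CountDistributionSpec(name, FiveTierLabel.BENIGN, bm, bs))
        specs.append(CountDistributionSpec(name, FiveTierLabel.PATHOGENIC, pm, ps))
    return specs


def _sample_counts(
    mean: float, std: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Moment-matched count draws: negative binomial, Poisson or constant."""
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    if std == 0.0:
        return np.full(n, round(mean), dtype=np.int64)
    var = std * std
    if mean == 0.0:
        # printed mean rounded to zero; the distribution is effectively a
        # point mass at zero for fixture purposes
        return np.zeros(n, dtype=np.int64)
    if var <= mean:
        return rng.poisson(mean, size=n).astype(np.int64)
    size = mean * mean / (var - mean)  # NB dispersion from moment matching
    p = mean / var
    return rng.negative_binomial(size, p, size=n).astype(np.int64)


def _count_ppf(mean: float, std: float, u: np.ndarray) -> np.ndarray:
    """Quantile function of the same moment-matched count distribution."""
    if std == 0.0 or mean == 0.0:
        return np.full(len(u), round(mean) if std == 0.0 else 0, dtype=np.int64)
    var = std * std
    if var <= mean:
        return stats.poisson.ppf(u, mean).astype(np.int64)
    size = mean * mean / (var - mean)
    p = mean / var
    return stats.nbinom.ppf(u, size, p).astype(np.int64)


def sample_feature_dataset(
    cnv_type: CnvType,
    n_benign: int,
    n_pathogenic: int,
    seed: int,
    specs: list[CountDistributionSpec] | None = None,
    rank_correlation: float | None = None,
    partition_tag: PartitionTag = PartitionTag.TRAINING,
) -> LabeledDataset:
    """Draw a labeled feature-count dataset matched to per-class moments.

    Attributes are independent unless ``rank_correlation`` sets a constant
    Gaussian-copula correlation between all attribute pairs within a class.
    Reproducible for a fixed seed; rows are shuffled so class blocks do not
    align with row order.
    """
    schema = AnnotationSchema.for_type(cnv_type)
    if specs is None:
        specs = default_moment_specs(cnv_type)
    by_key = {(s.attribute, s.label): s for s in specs}
    missing = [
        name
        for name in schema.attribute_names
        for lab in (FiveTierLabel.BENIGN, FiveTierLabel.PATHOGENIC)
        if (name, lab) not in by_key
    ]
    if missing:
        raise ConfigurationError(
            f"moment specs do not cover the schema: missing {sorted(set(missing))}"
        )
    rng = np.random.default_rng(seed)
    k = len(schema)
    blocks = []
    for label, n in (
        (FiveTierLabel.BENIGN, n_benign),
        (FiveTierLabel.PATHOGENIC, n_pathogenic),
    ):
        if rank_correlation is None:
            cols = [
                _sample_counts(by_key[(a, label)].mean, by_key[(a, label)].std, n, rng)
                for a in schema.attribute_names
            ]
        else:
            corr = np.full((k, k), rank_correlation)
            np.fill_diagonal(corr, 1.0)
            z = rng.multivariate_normal(np.zeros(k), corr, size=n, method="cholesky")
            u = stats.norm.cdf(z)
            cols = [
                _count_ppf(by_key[(a, label)].mean, by_key[(a, label)].std, u[:, j])
                for j, a in enumerate(schema.attribute_names)
            ]
        blocks.append(np.stack(cols, axis=1) if n else np.zeros((0, k), dtype=np.int64))
    X = np.vstack(blocks)
    y = np.concatenate(
        [np.zeros(n_benign, dtype=np.int64), np.ones(n_pathogenic, dtype=np.int64)]
    )
    order = rng.permutation(len(y))
    return LabeledDataset(
        cnv_type=cnv_type,
        X=pd.DataFrame(X[order], columns=list(schema.attribute_names)),
        y=y[order],
        partition_tag=partition_tag,
    )


@dataclass
class ToyGenomeSpec:
    """Layout of a small fictional genome for end-to-end fixture runs.

    Each chromosome has a gene-dense first portion (``dense_fraction``) and a
    sparse remainder.  Element densities are per-Mbp; the dense region is
    enriched by ``enrichment``.  Pathogenic CNVs are placed inside dense
    regions and benign CNVs inside sparse regions, so overlap counts separate
    the classes by construction.
    """

    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 10_000_000, "chr2": 8_000_000}
    )
    dense_fraction: float = 0.5
    sparse_density_per_mbp: float = 2.0
    enrichment: float = 10.0
    #: per-category sparse-density overrides (e.g. 0.0 to empty a track)
    density_overrides: dict[str, float] = field(default_factory=dict)
    element_length_range: tuple[int, int] = (200, 5_000)
    cnv_length_range: tuple[int, int] = (50_000, 500_000)
    n_benign: int = 100
    n_pathogenic: int = 100
    cnv_type: CnvType = CnvType.LOSS
    seed: int = 0


@dataclass
class ToyGenome:
    catalog: ElementCatalog
    cnvs: list[CNVRecord]
    ground_truth: pd.DataFrame  # brute-force overlap counts, rows align with cnvs


def _place_elements(
    rng: np.random.Generator,
    chrom: str,
    lo: int,
    hi: int,
    density_per_mbp: float,
    length_range: tuple[int, int],
) -> list[GenomicInterval]:
    span = hi - lo
    n = rng.poisson(density_per_mbp * span / 1e6)
    out = []
    for _ in range(n):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        start = int(rng.integers(lo, max(lo + 1, hi - length)))
        out.append(GenomicInterval(chrom, start, start + length))
    return out


def build_toy_genome(spec: ToyGenomeSpec | None = None) -> ToyGenome:
    """Generate an element catalog and labeled CNVs on a toy genome.

    Ground-truth overlap counts are computed by exhaustive all-pairs checking
    during generation and returned alongside, for use as an independent
    oracle against the indexed annotation path.
    """
    spec = spec or ToyGenomeSpec()
    rng = np.random.default_rng(spec.seed)
    schema = AnnotationSchema.for_type(spec.cnv_type)
    catalog = ElementCatalog()
    for category in sorted(CATEGORY_VOCABULARY):
        base_density = spec.density_overrides.get(
            category, spec.sparse_density_per_mbp
        )
        elements: list[GenomicInterval] = []
        for chrom, size in spec.chrom_sizes.items():
            boundary = int(size * spec.dense_fraction)
            elements.extend(
                _place_elements(
                    rng,
                    chrom,
                    0,
                    boundary,
                    base_density * spec.enrichment,
                    spec.element_length_range,
                )
            )
            elements.extend(
                _place_elements(
                    rng,
                    chrom,
                    boundary,
                    size,
                    base_density,
                    spec.element_length_range,
                )
            )
        scores = (
            [3] * len(elements) if category in DOSAGE_CATEGORIES else None
        )
        catalog.add_track(category, elements, scores)

    chroms = list(spec.chrom_sizes)
    cnvs: list[CNVRecord] = []
    for label, n in (
        (FiveTierLabel.PATHOGENIC, spec.n_pathogenic),
        (FiveTierLabel.BENIGN, spec.n_benign),
    ):
        for i in range(n):
            chrom = chroms[int(rng.integers(len(chroms)))]
            size = spec.chrom_sizes[chrom]
            boundary = int(size * spec.dense_fraction)
            lo, hi = (0, boundary) if label is FiveTierLabel.PATHOGENIC else (
                boundary,
                size,
            )
            length = int(
                rng.integers(spec.cnv_length_range[0], spec.cnv_length_range[1] + 1)
            )
            length = min(length, hi - lo - 1)
            start = int(rng.integers(lo, hi - length))
            cnvs.append(
                CNVRecord(
                    GenomicInterval(chrom, start, start + length),
                    spec.cnv_type,
                    label=label,
                    source_id=f"toy_{label.value}_{i}",
                )
            )

    # brute-force all-pairs ground truth, independent of the indexed counter
    rows = []
    for cnv in cnvs:
        row = {}
        for name in schema.attribute_names:
            row[name] = sum(
                1 for el in catalog.tracks[name] if el.overlaps(cnv.interval)
            )
        rows.append(row)
    ground_truth = pd.DataFrame(rows, columns=list(schema.attribute_names))
    return ToyGenome(catalog=catalog, cnvs=cnvs, ground_truth=ground_truth)
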