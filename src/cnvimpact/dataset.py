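"""Preprocessing of labeled CNV sets: size/multiplicity filters, label
binarization and stratified train/validation/test partitioning.

The training regime uses canonical CNVs only: larger than 1 kbp, smaller than
5 Mbp, with multiplicity 1 (heterozygous deletion) for losses and 3 (single
duplication) for gains, and an unambiguous benign/pathogenic label.  Records
failing a filter are not discarded silently — oversized CNVs, non-canonical
multiplicities and intermediate five-tier labels are each routed to their own
held-out evaluation set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .annotation import (
    AnnotationSchema,
    CNVRecord,
    CnvType,
    FiveTierLabel,
    ValidationError,
)

__all__ = [
    "PartitionTag",
    "LabeledDataset",
    "filter_by_size",
    "filter_by_multiplicity",
    "binarize_labels",
    "split_train_val_test",
]

#: Size filter defaults in base pairs, both bounds strict.
MIN_LENGTH_EXCLUSIVE = 1_000
MAX_LENGTH_EXCLUSIVE = 5_000_000

CANONICAL_MULTIPLICITY = {CnvType.LOSS: 1, CnvType.GAIN: 3}

BINARY_LABELS = frozenset({FiveTierLabel.BENIGN, FiveTierLabel.PATHOGENIC})


class PartitionTag(str, Enum):
    TRAINING = "training"
    VALIDATION = "validation"
    TESTING_BASIC = "testing_basic"
    TESTING_GT5MBP = "testing_gt5mbp"
    TESTING_MULTIPLE = "testing_multiple"
    TESTING_5TIER = "testing_5tier"


@dataclass
class LabeledDataset:
    """Feature matrix plus binary labels for one CNV type and partition.

    ``X`` columns follow the annotation schema order; ``y`` is 1 for
    pathogenic, 0 for benign.  ``five_tier`` optionally carries the original
    five-tier labels for evaluation-only partitions.
    """

    cnv_type: CnvType
    X: pd.DataFrame
    y: np.ndarray
    partition_tag: PartitionTag
    five_tier: list[FiveTierLabel] | None = None
    schema: AnnotationSchema = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.schema is None:
            self.schema = AnnotationSchema.for_type(self.cnv_type)
        expected = list(self.schema.attribute_names)
        if list(self.X.columns) != expected:
            raise ValidationError(
                "feature columns do not match the schema for "
                f"{self.cnv_type.value} variants"
            )
        self.y = np.asarray(self.y, dtype=np.int64)
        if len(self.y) != len(self.X):
            raise ValidationError("X and y lengths differ")
        if self.partition_tag in (
            PartitionTag.TRAINING,
            PartitionTag.VALIDATION,
            PartitionTag.TESTING_BASIC,
        ) and not set(np.unique(self.y)).issubset({0, 1}):
            raise ValidationError("training-regime partitions must be binary-labeled")

    def __len__(self) -> int:
        return len(self.X)

    @property
    def class_counts(self) -> tuple[int, int]:
        """(n_benign, n_pathogenic)."""
        return int((self.y == 0).sum()), int((self.y == 1).sum())


def filter_by_size(
    records: Sequence[CNVRecord],
    min_exclusive: int = MIN_LENGTH_EXCLUSIVE,
    max_exclusive: int = MAX_LENGTH_EXCLUSIVE,
) -> tuple[list[CNVRecord], list[CNVRecord]]:
    """Split records into (kept, oversized); too-small records are dropped.

    Kept records satisfy min_exclusive < length < max_exclusive (both strict).
    Records with length >= max_exclusive form the long-CNV evaluation set:
    almost all reported CNVs above 5 Mbp are pathogenic, so including them in
    training would distort the classifier.  Records at or below 1 kbp are
    outside the method's scope and are dropped.
    """
    kept: list[CNVRecord] = []
    oversized: list[CNVRecord] = []
    for rec in records:
        if rec.length >= max_exclusive:
            oversized.append(rec)
        elif rec.length > min_exclusive:
            kept.append(rec)
    return kept, oversized


def filter_by_multiplicity(
    records: Sequence[CNVRecord], cnv_type: CnvType
) -> tuple[list[CNVRecord], list[CNVRecord]]:
    """Split records into (canonical, multiple) by copy-number multiplicity.

    Canonical means multiplicity 1 for losses and 3 for gains; homozygous
    deletions (multiplicity 0) and double duplications (multiplicity 4+) go
    to the "multiple" evaluation set.  Records without a multiplicity
    annotation are treated as canonical, since most public CNV records omit
    it.
    """
    canonical_m = CANONICAL_MULTIPLICITY[cnv_type]
    canonical: list[CNVRecord] = []
    multiple: list[CNVRecord] = []
    for rec in records:
        if rec.multiplicity is None or rec.multiplicity == canonical_m:
            canonical.append(rec)
        else:
            multiple.append(rec)
    return canonical, multiple


def binarize_labels(
    records: Sequence[CNVRecord],
) -> tuple[list[CNVRecord], list[CNVRecord]]:
    """Split into (binary_records, other_records) by five-tier label.

    Only unambiguous benign/pathogenic records enter the training regime;
    likely-benign, likely-pathogenic and uncertain-significance records are
    kept apart for five-tier evaluation.
    """
    binary: list[CNVRecord] = []
    other: list[CNVRecord] = []
    for rec in records:
        if rec.label is None:
            raise ValidationError(
                f"record {rec.source_id or rec.interval} has no label to binarize"
            )
        if rec.label in BINARY_LABELS:
            binary.append(rec)
        else:
            other.append(rec)
    return binary, other


def split_train_val_test(
    X: pd.DataFrame,
    y: np.ndarray,
    cnv_type: CnvType,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> tuple[LabeledDataset, LabeledDataset, LabeledDataset]:
    """Stratified random partition into training/validation/testing sets.

    Deterministic for a fixed seed; class proportions are preserved within
    each partition.  Fractions must sum to 1.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValidationError(f"fractions must sum to 1, got {fractions}")
    f_train, f_val, f_test = fractions
    y = np.asarray(y, dtype=np.int64)
    idx = np.arange(len(X))
    if f_val + f_test == 0.0:
        tr_idx, va_idx, te_idx = idx, idx[:0], idx[:0]
    else:
        tr_idx, rest_idx = train_test_split(
            idx,
            test_size=f_val + f_test,
            stratify=y,
            random_state=seed,
        )
        if f_test == 0.0:
            va_idx, te_idx = rest_idx, rest_idx[:0]
        elif f_val == 0.0:
            va_idx, te_idx = rest_idx[:0], rest_idx
        else:
            va_idx, te_idx = train_test_split(
                rest_idx,
                test_size=f_test / (f_val + f_test),
                stratify=y[rest_idx],
                random_state=seed + 1,
            )

    def make(indices: np.ndarray, tag: PartitionTag) -> LabeledDataset:
        return LabeledDataset(
            cnv_type=cnv_type,
            X=X.iloc[indices].reset_index(drop=True),
            y=y[indices],
            partition_tag=tag,
        )

    return (
        make(tr_idx, PartitionTag.TRAINING),
        make(va_idx, PartitionTag.VALIDATION),
        make(te_idx, PartitionTag.TESTING_BASIC),
    )
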