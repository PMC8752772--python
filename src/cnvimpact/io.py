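"""Readers and writers for the pipeline's file formats.

Tracks are BED3+ (tab-separated, ``#`` comments) with the element category in
column 4 and an optional integer dosage score in column 5.  CNV call sets are
accepted as headered TSV, headerless BED-like files, or VCF 4.x with
``SVTYPE`` DEL/DUP and ``INFO/END``.  Coordinates are 0-based half-open
internally: BED/TSV coordinates pass through unchanged, VCF ``POS`` is
converted by subtracting 1.

All writers emit deterministic, byte-stable output for fixed inputs: sorted
keys in JSON, fixed float formatting, and a header comment carrying the tool
version and a hash of the run configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import (
    CATEGORY_VOCABULARY,
    CNVRecord,
    CnvType,
    DOSAGE_CATEGORIES,
    ElementCatalog,
    FiveTierLabel,
    GenomicInterval,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_tracks",
    "write_tracks",
    "read_cnvs",
    "write_cnvs",
    "read_chrom_sizes",
    "write_feature_matrix",
    "read_feature_matrix",
    "write_predictions",
    "write_metrics_json",
    "config_hash",
]

_SVTYPE_TO_CNV = {"DEL": CnvType.LOSS, "DUP": CnvType.GAIN}


def config_hash(config: dict) -> str:
    """Short stable hash of a run configuration for output provenance."""
    payload = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _header_comment(config: dict | None) -> str:
    from . import __version__

    h = config_hash(config or {})
    return f"# cnvimpact v{__version__} config={h}\n"


def read_tracks(
    path: str | Path, dosage_required_score: int | None = 3
) -> ElementCatalog:
    """Load a BED3+ element track file into a catalog.

    Column 4 is the category name; column 5, when present on a
    dosage-sensitivity category, is the integer evidence score.  Unknown
    categories are skipped with a warning.  Dosage tracks are filtered to
    ``dosage_required_score`` unless it is None.
    """
    catalog = ElementCatalog()
    rows: dict[str, tuple[list[GenomicInterval], list[int | None]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValidationError(
                    f"{path}:{lineno}: track lines need >= 4 columns "
                    "(chrom, start, end, category)"
                )
            chrom, start, end, category = parts[0], parts[1], parts[2], parts[3]
            score: int | None = None
            if len(parts) >= 5 and parts[4] not in ("", "."):
                score = int(parts[4])
            try:
                iv = GenomicInterval(chrom, int(start), int(end))
            except (ValueError, ValidationError) as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
            ivs, scores = rows.setdefault(category, ([], []))
            ivs.append(iv)
            scores.append(score)
    for category, (ivs, scores) in rows.items():
        if category in DOSAGE_CATEGORIES:
            catalog.add_track(category, ivs, scores)
        else:
            catalog.add_track(category, ivs)
    if dosage_required_score is not None:
        catalog.filter_dosage_tracks(dosage_required_score)
    return catalog


def write_tracks(catalog: ElementCatalog, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_header_comment({"writer": "tracks"}))
        for category in sorted(catalog.tracks):
            scores = catalog.dosage_scores.get(category)
            for i, iv in enumerate(catalog.tracks[category]):
                cols = [iv.chrom, str(iv.start), str(iv.end), category]
                if scores is not None:
                    cols.append(str(scores[i]))
                fh.write("\t".join(cols) + "\n")


def _record_from_fields(
    chrom: str,
    start: str | int,
    end: str | int,
    cnv_type: str,
    multiplicity: str | int | None = None,
    label: str | None = None,
    source_id: str | None = None,
) -> CNVRecord:
    mult = None
    if multiplicity not in (None, "", ".", "nan"):
        mult = int(float(multiplicity))
    lab = None
    if label not in (None, "", ".", "nan"):
        lab = FiveTierLabel(label)
    return CNVRecord(
        GenomicInterval(chrom, int(start), int(end)),
        CnvType(cnv_type.lower()),
        multiplicity=mult,
        label=lab,
        source_id=source_id,
    )


def _read_cnvs_table(path: Path, has_header: bool) -> list[CNVRecord]:
    records: list[CNVRecord] = []
    errors: list[str] = []
    with open(path) as fh:
        header: list[str] | None = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if has_header and header is None:
                header = parts
                continue
            fields = dict(zip(header, parts)) if header else None
            try:
                if fields is not None:
                    rec = _record_from_fields(
                        fields["chrom"],
                        fields["start"],
                        fields["end"],
                        fields["cnv_type"],
                        fields.get("multiplicity"),
                        fields.get("label"),
                        fields.get("source_id") or f"{path.name}:{lineno}",
                    )
                else:
                    rec = _record_from_fields(
                        *parts[:4],
                        parts[4] if len(parts) > 4 else None,
                        parts[5] if len(parts) > 5 else None,
                        source_id=f"{path.name}:{lineno}",
                    )
                records.append(rec)
            except (KeyError, ValueError, ValidationError) as exc:
                errors.append(f"{path}:{lineno}: {exc}")
    for err in errors:
        logger.warning("skipped malformed CNV line: %s", err)
    return records


def _read_cnvs_vcf(path: Path) -> list[CNVRecord]:
    from cyvcf2 import VCF

    records: list[CNVRecord] = []
    for variant in VCF(str(path)):
        svtype = variant.INFO.get("SVTYPE")
        if svtype not in _SVTYPE_TO_CNV:
            logger.warning(
                "skipping %s:%s: unsupported SVTYPE %r",
                variant.CHROM,
                variant.POS,
                svtype,
            )
            continue
        end = variant.INFO.get("END")
        if end is None:
            logger.warning(
                "rejecting %s:%s: symbolic %s record without INFO/END",
                variant.CHROM,
                variant.POS,
                svtype,
            )
            continue
        records.append(
            CNVRecord(
                GenomicInterval(variant.CHROM, variant.POS - 1, int(end)),
                _SVTYPE_TO_CNV[svtype],
                source_id=variant.ID or f"{variant.CHROM}:{variant.POS}",
            )
        )
    return records


def read_cnvs(path: str | Path, fmt: str | None = None) -> list[CNVRecord]:
    """Read CNV records from TSV (headered), BED-like (headerless) or VCF."""
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = {"": "tsv", ".tsv": "tsv", ".bed": "bed", ".vcf": "vcf"}.get(
            suffix, "tsv"
        )
    if fmt == "vcf":
        return _read_cnvs_vcf(path)
    if fmt in ("tsv", "bed"):
        return _read_cnvs_table(path, has_header=(fmt == "tsv"))
    raise ValidationError(f"unknown CNV file format {fmt!r}")


def write_cnvs(records: list[CNVRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_header_comment({"writer": "cnvs"}))
        fh.write("chrom\tstart\tend\tcnv_type\tmultiplicity\tlabel\tsource_id\n")
        for rec in records:
            fh.write(
                "\t".join(
                    [
                        rec.interval.chrom,
                        str(rec.interval.start),
                        str(rec.interval.end),
                        rec.cnv_type.value,
                        "." if rec.multiplicity is None else str(rec.multiplicity),
                        "." if rec.label is None else rec.label.value,
                        rec.source_id or ".",
                    ]
                )
                + "\n"
            )


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Two-column TSV: chromosome name, length."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, size = line.split("\t")[:2]
            sizes[chrom] = int(size)
    return sizes


def write_feature_matrix(
    X: pd.DataFrame,
    path: str | Path,
    labels: np.ndarray | list | None = None,
    source_ids: list[str] | None = None,
    config: dict | None = None,
) -> None:
    """Feature matrix TSV: one row per CNV, stable schema column order."""
    out = X.copy()
    if source_ids is not None:
        out.insert(0, "source_id", source_ids)
    if labels is not None:
        out["label"] = labels
    with open(path, "w") as fh:
        fh.write(_header_comment(config))
        out.to_csv(fh, sep="\t", index=False)


def read_feature_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_predictions(
    frame: pd.DataFrame, path: str | Path, config: dict | None = None
) -> None:
    """Predictions TSV: source_id, probability, call, p_ct."""
    out = frame.copy()
    if "probability" in out:
        out["probability"] = out["probability"].map(lambda v: f"{v:.6f}")
    with open(path, "w") as fh:
        fh.write(_header_comment(config))
        out.to_csv(fh, sep="\t", index=False)


def write_metrics_json(
    metrics: dict, path: str | Path, config: dict | None = None
) -> None:
    payload = {
        "config_hash": config_hash(config or {}),
        "metrics": metrics,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
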