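"""Region-as-transcript quantification and composition summaries.

Detected coverage regions stand in for transcripts: RPKM and TPM are
computed over region read counts and region lengths, not whole gene
bodies.  Composition summaries classify each region by its reference
annotation — cytosolic GUN tRNA (the Q-family substrates), mitochondrial
tRNA, snoRNA, 45S pre-rRNA, other — and report read counts as percentages
of total mapped reads (the percentage denominator is a flag, since "total"
can also mean reads inside detected regions only).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from capq.references import ReferenceRecord, anticodon_of, is_q_family
from capq.signature import SubstrateRecord

COMPOSITION_CATEGORIES = ("tRNA_cyto_GUN", "tRNA_mito", "snoRNA", "rRNA_45S", "other", "unassigned")

RRNA_FEATURES = ("5'ETS", "18S", "ITS1", "5.8S", "ITS2", "28S")


def rpkm(region_read_counts, region_lengths, total_mapped: int) -> np.ndarray:
    """Reads per kilobase of region per million mapped reads.

    RPKM_i = count_i / (length_i / 1e3) / (total_mapped / 1e6).
    """
    counts = np.asarray(region_read_counts, dtype=float)
    lengths = np.asarray(region_lengths, dtype=float)
    if total_mapped <= 0:
        raise ValueError("total_mapped must be > 0")
    if (lengths <= 0).any():
        raise ValueError("region lengths must be > 0")
    return counts / (lengths / 1e3) / (total_mapped / 1e6)


def tpm(region_read_counts, region_lengths) -> np.ndarray:
    """Transcripts per million over the detected regions (sums to 1e6)."""
    counts = np.asarray(region_read_counts, dtype=float)
    lengths = np.asarray(region_lengths, dtype=float)
    if (lengths <= 0).any():
        raise ValueError("region lengths must be > 0")
    if not counts.any():
        raise ValueError("all region counts are zero; TPM undefined")
    rate = counts / lengths
    return rate / rate.sum() * 1e6


def classify_record(record: SubstrateRecord, references: list[ReferenceRecord]) -> str:
    """Composition label of a region from its reference annotation.

    Cytosolic tRNA is labeled ``tRNA_cyto_GUN`` only when the annotated
    anticodon is Q-family (G34-U35); non-GUN cytosolic tRNA falls in
    ``other``.  Mitochondrial tRNA is reported jointly (not split by
    anticodon).  Unannotated references classify as ``other`` with a
    warning.
    """
    by_id = {r.id: r for r in references}
    ref = by_id.get(record.region.ref_id)
    if ref is None:
        warnings.warn(f"region on unannotated reference {record.region.ref_id!r}; classified as other")
        return "other"
    if ref.category == "tRNA_cyto":
        if ref.anticodon_start is not None and is_q_family(anticodon_of(ref)):
            return "tRNA_cyto_GUN"
        return "other"
    if ref.category in ("tRNA_mito", "snoRNA", "rRNA_45S"):
        return ref.category
    return "other"


@dataclass
class CompositionSummary:
    """Per-category read counts and percentages of total mapped reads."""

    read_counts: dict[str, int]
    percents: dict[str, float]
    total_mapped: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "category": list(COMPOSITION_CATEGORIES),
                "read_count": [self.read_counts[c] for c in COMPOSITION_CATEGORIES],
                "percent_of_total": [self.percents[c] for c in COMPOSITION_CATEGORIES],
            }
        )


def summarize_composition(
    records: list[SubstrateRecord],
    references: list[ReferenceRecord],
    total_mapped: int,
    denominator: str = "total_mapped",
) -> CompositionSummary:
    """Read-count composition across the region records.

    ``denominator`` is either ``"total_mapped"`` (all reads mapped to the
    panel; reads outside any region appear under ``unassigned``) or
    ``"in_regions"`` (reads inside detected regions only).  Percentages sum
    to 100 whenever the chosen denominator is positive.
    """
    counts = {c: 0 for c in COMPOSITION_CATEGORIES}
    for rec in records:
        label = rec.category or classify_record(rec, references)
        counts[label] += rec.read_count
    assigned = sum(counts.values())
    if assigned > total_mapped:
        raise ValueError(f"region read counts ({assigned}) exceed total_mapped ({total_mapped})")
    if denominator == "total_mapped":
        counts["unassigned"] = total_mapped - assigned
        denom = total_mapped
    elif denominator == "in_regions":
        denom = assigned
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    percents = {c: (100.0 * n / denom if denom else 0.0) for c, n in counts.items()}
    return CompositionSummary(read_counts=counts, percents=percents, total_mapped=total_mapped)


def aggregate_compositions(summaries: list[CompositionSummary]) -> CompositionSummary:
    """Pool per-run region tables into one composition (sums counts, recomputes %)."""
    if not summaries:
        raise ValueError("no summaries to aggregate")
    counts = {c: sum(s.read_counts[c] for s in summaries) for c in COMPOSITION_CATEGORIES}
    total = sum(s.total_mapped for s in summaries)
    denom = sum(counts.values()) if total == 0 else total
    percents = {c: (100.0 * n / denom if denom else 0.0) for c, n in counts.items()}
    return CompositionSummary(read_counts=counts, percents=percents, total_mapped=total)


def rrna_subregion_report(
    records: list[SubstrateRecord],
    rrna_feature_map: dict[str, tuple[int, int]],
) -> dict[str, int]:
    """Assign 45S region records to named pre-rRNA features.

    ``rrna_feature_map`` gives 0-based half-open intervals for the 45S
    segments (5'ETS, 18S, ITS1, 5.8S, ITS2, 28S) on the 45S reference.
    Each record's reads are counted under the feature containing its best
    transversion position; records outside every feature (or without a
    call) go to ``unassigned``.
    """
    report: dict[str, int] = {name: 0 for name in rrna_feature_map}
    report["unassigned"] = 0
    if not rrna_feature_map:
        warnings.warn("empty rRNA feature map; all reads unassigned")
    for rec in records:
        if (rec.category or "") != "rRNA_45S":
            continue
        pos = rec.best_call.position if rec.best_call else None
        feature = None
        if pos is not None:
            for name, (start, end) in rrna_feature_map.items():
                if start <= pos < end:
                    feature = name
                    break
        report[feature if feature else "unassigned"] += rec.read_count
    return report


def load_rrna_feature_bed(path) -> dict[str, tuple[int, int]]:
    """Read a BED file of 45S features into {name: (start, end)}."""
    out: dict[str, tuple[int, int]] = {}
    with open(path) as bed:
        for line in bed:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            out[fields[3].strip()] = (int(fields[1]), int(fields[2]))
    return out


def write_summary_tsv(summary: CompositionSummary, path) -> None:
    summary.to_frame().to_csv(path, sep="\t", index=False, float_format="%.4f")
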