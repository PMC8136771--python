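"""End-to-end pipeline wiring: deplete → clip → align → pileup → regions →
calls → filter → quantify → classify → summarize.

The stage order is fixed; per-stage read/record counts are logged and a
conservation check fails loudly when reads go missing between stages.
Every run can write its resolved configuration next to its outputs so the
run is reproducible from the sidecar alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

from capq.alignio import AlignedRead, align_simple, clip_cca, deplete_contaminants, read_sam
from capq.quantify import (
    CompositionSummary,
    classify_record,
    rpkm,
    summarize_composition,
    tpm,
    write_summary_tsv,
)
from capq.references import ReferenceRecord
from capq.signature import (
    CoverageRegion,
    SubstrateRecord,
    TransversionCall,
    call_transversions,
    detect_regions,
    filter_substrate_regions,
    pileup,
    write_calls_tsv,
    write_regions_bed,
    write_substrates_tsv,
)

logger = logging.getLogger("capq")


@dataclass
class PipelineConfig:
    """Resolved analysis parameters; JSON round-trippable."""

    min_coverage: int = 10
    min_length: int = 16  # strict: regions must be LONGER than this
    min_ratio: float = 0.30
    min_depth: int = 10
    max_mismatch: int = 3
    min_read_length: int = 16
    depletion_k: int = 12
    depletion_max_mismatch: int = 2
    cca_clip: bool = True
    drop_mapq0: bool = False
    percent_denominator: str = "total_mapped"
    seed: int = 0

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class PipelineResult:
    """Everything one run produced, with per-stage counts."""

    alignments: list[AlignedRead]
    columns: dict
    regions: list[CoverageRegion]
    calls: list[TransversionCall]
    records: list[SubstrateRecord]
    summary: CompositionSummary
    total_mapped: int
    stage_counts: dict[str, int] = field(default_factory=dict)
    removed_read_ids: list[str] = field(default_factory=list)

    @property
    def passing(self) -> list[SubstrateRecord]:
        return [r for r in self.records if r.passes]

    def write(self, outdir, config: PipelineConfig | None = None) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_regions_bed(self.regions, outdir / "regions.bed")
        write_calls_tsv(self.calls, outdir / "transversions.tsv")
        write_substrates_tsv(self.records, outdir / "substrates.tsv")
        write_summary_tsv(self.summary, outdir / "composition.tsv")
        (outdir / "stage_counts.json").write_text(json.dumps(self.stage_counts, indent=2) + "\n")
        if config is not None:
            config.to_json(outdir / "config.json")


def run_pipeline(
    reads: list[tuple[str, str, str]] | None,
    references: list[ReferenceRecord],
    config: PipelineConfig | None = None,
    contaminants: list[tuple[str, str]] | None = None,
    sam_source=None,
) -> PipelineResult:
    """Run the full analysis on FASTQ-style reads (or ingest a SAM).

    ``reads`` are ``(id, sequence, quality)`` triples; pass ``sam_source``
    instead to consume pre-made alignments (depletion and clipping are then
    assumed upstream, as with any external aligner).
    """
    config = config or PipelineConfig()
    counts: dict[str, int] = {}
    removed: list[str] = []

    if sam_source is not None:
        alignments = read_sam(sam_source, references)
        counts["input_alignment_blocks"] = len(alignments)
    else:
        if reads is None:
            raise ValueError("provide reads or sam_source")
        counts["input_reads"] = len(reads)
        if contaminants:
            kept, removed = deplete_contaminants(
                reads, contaminants, k=config.depletion_k, max_mismatch=config.depletion_max_mismatch
            )
            if len(kept) + len(removed) != len(reads):
                raise RuntimeError("depletion lost reads: conservation check failed")
            reads = kept
        counts["post_depletion_reads"] = len(reads)
        if not reads:
            raise ValueError("no reads survived depletion")
        if config.cca_clip:
            reads = [(rid, clip_cca(seq), qual[: len(clip_cca(seq))]) for rid, seq, qual in reads]
        alignments = align_simple(
            reads, references, max_mismatch=config.max_mismatch, min_length=config.min_read_length
        )
        counts["aligned_reads"] = len(alignments)
        logger.info(
            "depleted %d, aligned %d/%d reads", len(removed), len(alignments), counts["post_depletion_reads"]
        )

    if config.drop_mapq0:
        alignments = [a for a in alignments if a.mapq > 0]
        counts["post_mapq_filter"] = len(alignments)

    total_mapped = len({a.read_id for a in alignments})
    columns = pileup(alignments, references)
    depth_total = sum(c.depth for cols in columns.values() for c in cols)
    obs_total = sum(len(a.observed) for a in alignments)
    if depth_total != obs_total:
        raise RuntimeError("pileup conservation check failed")

    regions = detect_regions(columns, references, min_coverage=config.min_coverage)
    counts["regions"] = len(regions)
    calls = call_transversions(columns, regions)
    counts["transversion_calls"] = len(calls)
    records = filter_substrate_regions(
        regions, calls, alignments,
        min_length=config.min_length, min_ratio=config.min_ratio, min_depth=config.min_depth,
    )
    counts["passing_records"] = sum(r.passes for r in records)

    if records:
        region_counts = [r.read_count for r in records]
        lengths = [r.region.length for r in records]
        if total_mapped > 0:
            for rec, val in zip(records, rpkm(region_counts, lengths, total_mapped)):
                rec.rpkm = float(val)
        if any(region_counts):
            for rec, val in zip(records, tpm(region_counts, lengths)):
                rec.tpm = float(val)
        for rec in records:
            rec.category = classify_record(rec, references)

    summary = summarize_composition(
        records, references, total_mapped, denominator=config.percent_denominator
    )
    logger.info(
        "%d regions, %d calls, %d passing records over %d mapped reads",
        len(regions), len(calls), counts["passing_records"], total_mapped,
    )
    return PipelineResult(
        alignments=alignments,
        columns=columns,
        regions=regions,
        calls=calls,
        records=records,
        summary=summary,
        total_mapped=total_mapped,
        stage_counts=counts,
        removed_read_ids=removed,
    )
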