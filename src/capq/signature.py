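"""Pileup, coverage-island detection, transversion calling, substrate filter.

This is the analytical core of the capture-release readout.  Released
substrates carry an abasic site at tRNA position 34; read-through reverse
transcription writes a G→T mismatch there in read space (C→A when the gene
sits on the genomic minus strand), so the diagnostic is a per-site
mismatch ratio inside islands of consecutive coverage.  A region qualifies
as a bound-substrate record when it is longer than 16 nt (strict), its best
transversion site has a mismatch frequency of at least 30% and at least 10
reads cover that site — the length test strict and the other two inclusive,
mirroring the >16 / ≥30% / ≥10 formulation.  All thresholds are arguments.

Coordinates are 0-based half-open internally; the BED writer keeps that
convention, TSV writers report 1-based positions for human consumption.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from capq.alignio import AlignedRead
from capq.references import ReferenceRecord

_BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}
# the two diagnostic transversions: plus-strand image and its minus-strand mirror
DIAGNOSTIC = {"G": "T", "C": "A"}


@dataclass(frozen=True)
class PileupColumn:
    ref_id: str
    position: int  # 0-based
    ref_base: str  # DNA alphabet
    depth: int
    base_counts: dict[str, int]


@dataclass(frozen=True)
class CoverageRegion:
    """Maximal run of consecutive positions with depth >= the floor."""

    ref_id: str
    start: int  # 0-based half-open
    end: int
    mean_coverage: float
    max_coverage: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TransversionCall:
    ref_id: str
    position: int  # 0-based
    ref_base: str  # G or C
    alt_base: str  # T or A respectively
    depth: int
    alt_count: int

    @property
    def ratio(self) -> float:
        return self.alt_count / self.depth


@dataclass
class SubstrateRecord:
    """A detected region joined to its best transversion and the filter verdict."""

    region: CoverageRegion
    best_call: TransversionCall | None
    read_count: int
    passes: bool
    reason: str
    category: str | None = None
    rpkm: float | None = None
    tpm: float | None = None


def pileup(alignments: list[AlignedRead], references: list[ReferenceRecord]) -> dict[str, list[PileupColumn]]:
    """Tally observed bases per reference position.

    Returns columns (depth > 0 only) keyed by reference id; bases outside
    A/C/G/T (e.g. N) add depth via an overflow key but never support calls.
    """
    ref_dna = {r.id: r.sequence.replace("U", "T") for r in references}
    counts: dict[str, np.ndarray] = {r.id: np.zeros((len(r), 5), dtype=np.int64) for r in references}
    for aln in alignments:
        if aln.ref_id not in counts:
            raise ValueError(f"alignment to unknown reference {aln.ref_id!r}")
        mat = counts[aln.ref_id]
        for pos, base in aln.observed:
            if not 0 <= pos < mat.shape[0]:
                raise ValueError(f"{aln.read_id}: position {pos} outside reference {aln.ref_id}")
            mat[pos, _BASE_IDX.get(base, 4)] += 1

    columns: dict[str, list[PileupColumn]] = {}
    for ref in references:
        mat = counts[ref.id]
        cols = []
        for pos in np.nonzero(mat.sum(axis=1))[0]:
            row = mat[pos]
            bc = {b: int(row[i]) for b, i in _BASE_IDX.items() if row[i]}
            if row[4]:
                bc["N"] = int(row[4])
            cols.append(
                PileupColumn(
                    ref_id=ref.id,
                    position=int(pos),
                    ref_base=ref_dna[ref.id][pos],
                    depth=int(row.sum()),
                    base_counts=bc,
                )
            )
        columns[ref.id] = cols
    return columns


def detect_regions(
    columns: dict[str, list[PileupColumn]],
    references: list[ReferenceRecord],
    min_coverage: int = 10,
) -> list[CoverageRegion]:
    """Maximal runs of consecutive positions with depth >= ``min_coverage``.

    Runs are never merged across a failing (or zero-depth) position; length,
    mean and max are computed over in-region columns only.
    """
    if min_coverage < 1:
        raise ValueError("min_coverage must be >= 1")
    regions: list[CoverageRegion] = []
    for ref in references:
        depth = np.zeros(len(ref), dtype=np.int64)
        for col in columns.get(ref.id, []):
            depth[col.position] = col.depth
        ok = depth >= min_coverage
        if not ok.any():
            continue
        edges = np.flatnonzero(np.diff(np.concatenate(([False], ok, [False])).astype(np.int8)))
        for start, end in zip(edges[::2], edges[1::2]):
            seg = depth[start:end]
            regions.append(
                CoverageRegion(
                    ref_id=ref.id,
                    start=int(start),
                    end=int(end),
                    mean_coverage=float(seg.mean()),
                    max_coverage=int(seg.max()),
                )
            )
    return regions


def call_transversions(
    columns: dict[str, list[PileupColumn]],
    regions: list[CoverageRegion],
) -> list[TransversionCall]:
    """Emit G→T / C→A calls at every in-region site with alt support.

    Only the two diagnostic transversions are considered: G→T is the
    plus-strand image of thymidine misincorporation opposite the abasic
    site and C→A its minus-strand mirror.  Sites with zero alt reads are
    not emitted.
    """
    by_ref: dict[str, list[CoverageRegion]] = {}
    for reg in regions:
        by_ref.setdefault(reg.ref_id, []).append(reg)
    calls: list[TransversionCall] = []
    for ref_id, cols in columns.items():
        regs = by_ref.get(ref_id)
        if not regs:
            continue
        for col in cols:
            if not any(r.start <= col.position < r.end for r in regs):
                continue
            alt = DIAGNOSTIC.get(col.ref_base)
            if alt is None:
                continue
            alt_count = col.base_counts.get(alt, 0)
            if alt_count == 0:
                continue
            calls.append(
                TransversionCall(
                    ref_id=ref_id,
                    position=col.position,
                    ref_base=col.ref_base,
                    alt_base=alt,
                    depth=col.depth,
                    alt_count=alt_count,
                )
            )
    return calls


def _reads_overlapping(alignments: list[AlignedRead], region: CoverageRegion) -> int:
    seen: set[str] = set()
    for aln in alignments:
        if aln.ref_id == region.ref_id and aln.start < region.end and aln.end > region.start:
            seen.add(aln.read_id)
    return len(seen)


def filter_substrate_regions(
    regions: list[CoverageRegion],
    calls: list[TransversionCall],
    alignments: list[AlignedRead] | None = None,
    min_length: int = 16,
    min_ratio: float = 0.30,
    min_depth: int = 10,
) -> list[SubstrateRecord]:
    """Join regions to their best transversion and apply the substrate filter.

    Best call per region = maximum ratio, ties toward higher depth then
    smaller position.  A record passes iff region length > ``min_length``
    (strict) and best ratio >= ``min_ratio`` and best-call depth >=
    ``min_depth`` (both inclusive).  Regions without any call yield a
    failing record with reason "no transversion".
    """
    if min_length <= 0 or min_ratio <= 0 or min_depth <= 0:
        raise ValueError("thresholds must be positive")
    by_region: dict[tuple[str, int, int], list[TransversionCall]] = {}
    for call in calls:
        for reg in regions:
            if reg.ref_id == call.ref_id and reg.start <= call.position < reg.end:
                by_region.setdefault((reg.ref_id, reg.start, reg.end), []).append(call)
    records: list[SubstrateRecord] = []
    for reg in regions:
        in_region = by_region.get((reg.ref_id, reg.start, reg.end), [])
        read_count = _reads_overlapping(alignments, reg) if alignments is not None else 0
        if not in_region:
            records.append(SubstrateRecord(reg, None, read_count, False, "no transversion"))
            continue
        best = min(in_region, key=lambda c: (-c.ratio, -c.depth, c.position))
        checks = [
            (reg.length > min_length, f"length {reg.length} <= {min_length}"),
            (best.ratio >= min_ratio, f"best ratio {best.ratio:.3f} < {min_ratio}"),
            (best.depth >= min_depth, f"best-site depth {best.depth} < {min_depth}"),
        ]
        failed = [msg for ok, msg in checks if not ok]
        records.append(
            SubstrateRecord(
                reg, best, read_count,
                passes=not failed,
                reason="pass" if not failed else "; ".join(failed),
            )
        )
    return records


def transcript_position(record: ReferenceRecord, genome_position: int) -> int:
    """Map a 0-based genomic position on a gene to its 1-based transcript position."""
    if record.genome_strand == "-":
        return len(record) - genome_position
    return genome_position + 1


def write_regions_bed(regions: list[CoverageRegion], path) -> None:
    """Regions as BED6 (0-based half-open; score = rounded mean coverage)."""
    with open(path, "w") as bed:
        for r in regions:
            bed.write(f"{r.ref_id}\t{r.start}\t{r.end}\tregion\t{round(r.mean_coverage)}\t+\n")


def write_calls_tsv(calls: list[TransversionCall], path) -> None:
    with open(path, "w") as tsv:
        tsv.write("ref_id\tposition_1based\tref_base\talt_base\tdepth\talt_count\tratio\n")
        for c in calls:
            tsv.write(
                f"{c.ref_id}\t{c.position + 1}\t{c.ref_base}\t{c.alt_base}\t{c.depth}\t{c.alt_count}\t{c.ratio:.6f}\n"
            )


SUBSTRATE_COLUMNS = (
    "ref_id", "region_start", "region_end", "region_length", "mean_coverage",
    "max_coverage", "best_position_1based", "best_ref_base", "best_alt_base",
    "best_depth", "best_alt_count", "best_ratio", "read_count", "passes",
    "reason", "category", "rpkm", "tpm",
)


def write_substrates_tsv(records: list[SubstrateRecord], path) -> None:
    with open(path, "w") as tsv:
        tsv.write("\t".join(SUBSTRATE_COLUMNS) + "\n")
        for rec in records:
            b = rec.best_call
            tsv.write(
                "\t".join(
                    str(x)
                    for x in (
                        rec.region.ref_id, rec.region.start, rec.region.end,
                        rec.region.length, f"{rec.region.mean_coverage:.3f}",
                        rec.region.max_coverage,
                        b.position + 1 if b else ".", b.ref_base if b else ".",
                        b.alt_base if b else ".", b.depth if b else ".",
                        b.alt_count if b else ".",
                        f"{b.ratio:.6f}" if b else ".",
                        rec.read_count, int(rec.passes), rec.reason,
                        rec.category or ".",
                        f"{rec.rpkm:.4f}" if rec.rpkm is not None else ".",
                        f"{rec.tpm:.4f}" if rec.tpm is not None else ".",
                    )
                )
                + "\n"
            )
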