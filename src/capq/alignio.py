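"""Alignment ingest, contaminant depletion, CCA clipping, fixture aligner.

Real data arrives as SAM from any aligner (the pipeline is aligner-agnostic
by contract); :func:`read_sam` normalizes mapped primary records into
ungapped blocks of per-position observed bases, which is all the pileup
needs.  For self-contained runs :func:`align_simple` is a deliberately
simple, deterministic, ungapped fixture aligner over small panels.
Contaminant depletion mirrors the pre-alignment foreign-read removal step
(reads matching the contaminant set are dropped, everything else passes
through byte-identical and in order), and :func:`clip_cca` removes the
single terminal 3'-CCA tail of mature tRNA reads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pysam

from capq.references import ReferenceRecord

_DNA_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp_dna(seq: str) -> str:
    return seq.translate(_DNA_COMP)[::-1]


@dataclass(frozen=True)
class AlignedRead:
    """One ungapped block of a read placed on a reference.

    ``observed`` pairs each 0-based reference position with the read base
    observed there (reference-sense DNA); positions are consecutive.
    """

    read_id: str
    ref_id: str
    start: int
    strand: str
    observed: tuple[tuple[int, str], ...]
    mapq: int = 60

    @property
    def end(self) -> int:
        return self.start + len(self.observed)


def read_sam(sam_source, references: list[ReferenceRecord]) -> list[AlignedRead]:
    """Parse SAM into ungapped :class:`AlignedRead` blocks.

    Unmapped, secondary and supplementary records are skipped.  CIGAR
    operations M/=/X consume both sequences, S/I consume the read only and
    D/N the reference only, so an indel-containing record yields one block
    per M stretch.  Unknown reference names and malformed CIGARs raise.
    """
    ref_lengths = {r.id: len(r) for r in references}
    out: list[AlignedRead] = []
    with pysam.AlignmentFile(str(sam_source), "r", check_sq=False) as sam:
        for i, rec in enumerate(sam):
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.reference_name not in ref_lengths:
                raise ValueError(f"SAM record {rec.query_name}: reference {rec.reference_name!r} not in panel")
            if rec.cigartuples is None:
                raise ValueError(f"SAM record {i + 1} ({rec.query_name}): missing CIGAR")
            seq = rec.query_sequence or ""
            ref_pos, read_pos = rec.reference_start, 0
            for op, length in rec.cigartuples:
                if op in (0, 7, 8):  # M/=/X
                    block = tuple(
                        (ref_pos + k, seq[read_pos + k].upper()) for k in range(length)
                    )
                    if block and block[-1][0] >= ref_lengths[rec.reference_name]:
                        raise ValueError(
                            f"SAM record {rec.query_name}: block exceeds reference {rec.reference_name}"
                        )
                    out.append(
                        AlignedRead(
                            read_id=rec.query_name,
                            ref_id=rec.reference_name,
                            start=ref_pos,
                            strand="-" if rec.is_reverse else "+",
                            observed=block,
                            mapq=rec.mapping_quality,
                        )
                    )
                    ref_pos += length
                    read_pos += length
                elif op in (4, 1):  # S/I
                    read_pos += length
                elif op in (2, 3):  # D/N
                    ref_pos += length
                elif op == 5:  # H
                    pass
                else:
                    raise ValueError(f"SAM record {i + 1} ({rec.query_name}): unsupported CIGAR op {op}")
    return out


def write_sam(alignments: list[AlignedRead], references: list[ReferenceRecord], path) -> None:
    """Minimal SAM writer for fixtures (one record per ungapped block)."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": r.id, "LN": len(r)} for r in references],
    }
    tid = {r.id: i for i, r in enumerate(references)}
    with pysam.AlignmentFile(str(path), "w", header=header) as sam:
        for aln in alignments:
            rec = pysam.AlignedSegment(sam.header)
            rec.query_name = aln.read_id
            rec.reference_id = tid[aln.ref_id]
            rec.reference_start = aln.start
            rec.mapping_quality = aln.mapq
            rec.flag = 16 if aln.strand == "-" else 0
            seq = "".join(b for _, b in aln.observed)
            rec.query_sequence = seq
            rec.cigarstring = f"{len(seq)}M"
            sam.write(rec)


def clip_cca(read_sequence: str) -> str:
    """Remove one terminal 3'-CCA (DNA or RNA alphabet); at most one clip.

    Partial tails (CC, C) are left alone — only a complete CCA is a tail,
    anything shorter could be genuine 3' sequence.
    """
    if read_sequence[-3:].upper() == "CCA":
        return read_sequence[:-3]
    return read_sequence


class _KmerIndex:
    """Exact k-mer seed index over a sequence set (both strands)."""

    def __init__(self, sequences: list[tuple[str, str]], k: int):
        self.k = k
        self.seqs: list[str] = []
        self.index: dict[str, list[tuple[int, int]]] = {}
        for _, seq in sequences:
            for s in (seq.upper().replace("U", "T"), _revcomp_dna(seq.upper().replace("U", "T"))):
                si = len(self.seqs)
                self.seqs.append(s)
                for pos in range(len(s) - k + 1):
                    self.index.setdefault(s[pos : pos + k], []).append((si, pos))

    def matches(self, read: str, max_mismatch: int) -> bool:
        """True if the read aligns ungapped to any indexed sequence with <= max_mismatch."""
        read = read.upper().replace("U", "T")
        L = len(read)
        if L < self.k:
            return False
        tried: set[tuple[int, int]] = set()
        for off in range(0, L - self.k + 1):
            for si, pos in self.index.get(read[off : off + self.k], ()):
                start = pos - off
                key = (si, start)
                if key in tried:
                    continue
                tried.add(key)
                seq = self.seqs[si]
                if start < 0 or start + L > len(seq):
                    continue
                mism = sum(a != b for a, b in zip(read, seq[start : start + L]))
                if mism <= max_mismatch:
                    return True
        return False


def deplete_contaminants(
    reads: list[tuple[str, str, str]],
    contaminant_references: list[tuple[str, str]],
    k: int = 12,
    max_mismatch: int = 2,
) -> tuple[list[tuple[str, str, str]], list[str]]:
    """Drop reads matching the contaminant set; pass the rest through untouched.

    A read is a contaminant hit when an exact ``k``-mer seed extends to a
    full-length ungapped match with at most ``max_mismatch`` substitutions
    (defaults k=12, m=2 keep a 65-cycle read with two errors matchable).
    Returns ``(retained_reads, removed_read_ids)``; retained reads keep
    their order and bytes.
    """
    if not contaminant_references:
        raise ValueError("contaminant reference set is empty")
    idx = _KmerIndex(contaminant_references, k)
    kept, removed = [], []
    for read in reads:
        if idx.matches(read[1], max_mismatch):
            removed.append(read[0])
        else:
            kept.append(read)
    return kept, removed


class _PanelIndex:
    """Concatenated byte arrays of a panel for vectorized ungapped scanning."""

    def __init__(self, references: list[ReferenceRecord]):
        self.references = references
        dna = [r.sequence.replace("U", "T") for r in references]
        self.offsets = np.cumsum([0] + [len(s) for s in dna])
        self.fwd = np.frombuffer("".join(dna).encode(), dtype="S1")
        self.total = len(self.fwd)
        # window start -> (ref index, position); windows crossing a boundary invalid
        self._window_cache: dict[int, np.ndarray] = {}

    def valid_starts(self, L: int) -> np.ndarray:
        """Boolean mask over concatenated starts where an L-window stays in one reference."""
        key = L
        if key not in self._window_cache:
            mask = np.zeros(max(self.total - L + 1, 0), dtype=bool)
            for i in range(len(self.references)):
                lo, hi = self.offsets[i], self.offsets[i + 1]
                if hi - lo >= L:
                    mask[lo : hi - L + 1] = True
            self._window_cache[key] = mask
        return self._window_cache[key]

    def locate(self, start: int) -> tuple[int, int]:
        i = int(np.searchsorted(self.offsets, start, side="right") - 1)
        return i, start - int(self.offsets[i])


def _scan_best(panel: _PanelIndex, windows_cache: dict, seq: str, max_mismatch: int):
    """Best ungapped placement of ``seq`` over the panel, or None.

    Returns (ref_idx, pos, strand, oriented_ref_sense_seq, mapq).
    """
    L = len(seq)
    if L > panel.total:
        return None
    if L not in windows_cache:
        windows_cache[L] = np.lib.stride_tricks.sliding_window_view(panel.fwd, L)
    windows = windows_cache[L]
    valid = panel.valid_starts(L)
    if not valid.any():
        return None
    best = None  # (mismatches, strand_rank, ref_idx, pos, oriented_seq)
    n_best = 0
    for strand_rank, oriented in ((0, seq), (1, _revcomp_dna(seq))):
        arr = np.frombuffer(oriented.encode(), dtype="S1")
        mism = (windows != arr).sum(axis=1)
        mism = np.where(valid, mism, L + 1)
        m = int(mism.min())
        if m > max_mismatch:
            continue
        starts = np.nonzero(mism == m)[0]
        ref_idx, pos = panel.locate(int(starts[0]))
        cand = (m, strand_rank, ref_idx, pos, oriented)
        if best is None or cand[:4] < best[:4]:
            n_best = len(starts) + (n_best if best is not None and m == best[0] else 0)
            best = cand
        elif m == best[0]:
            n_best += len(starts)
    if best is None:
        return None
    m, strand_rank, ref_idx, pos, oriented = best
    return ref_idx, pos, "-" if strand_rank else "+", oriented, (0 if n_best > 1 else 60)


def align_simple(
    reads: list[tuple[str, str, str]],
    references: list[ReferenceRecord],
    max_mismatch: int = 3,
    min_length: int = 16,
    max_soft_clip_3p: int = 4,
) -> list[AlignedRead]:
    """Deterministic ungapped fixture aligner.

    Every read is scanned against every reference window on both strands;
    the best hit minimizes mismatch count with ties broken toward the plus
    strand, then leftmost reference order, then leftmost position.  Ties at
    the winning mismatch count are flagged ``mapq=0`` (counted once at the
    chosen locus downstream); reads shorter than ``min_length`` or beyond
    ``max_mismatch`` everywhere are dropped.  When a full-length read has no
    acceptable placement, up to ``max_soft_clip_3p`` 3' bases are clipped
    one at a time and the scan retried: reads that run a base or two into a
    partial CCA tail (molecule just longer than the cycle count) would
    otherwise be lost, and a spliced aligner would soft-clip them the same
    way.  Intended for small synthetic panels, not genomes.
    """
    panel = _PanelIndex(references)
    out: list[AlignedRead] = []
    windows_cache: dict[int, np.ndarray] = {}
    # identical read sequences place identically; cache the placement
    placement_cache: dict[str, tuple | None] = {}

    for read_id, seq, _ in reads:
        seq = seq.upper().replace("U", "T")
        if len(seq) < min_length:
            continue
        if seq not in placement_cache:
            hit = None
            for clip in range(0, max_soft_clip_3p + 1):
                sub = seq[: len(seq) - clip] if clip else seq
                if len(sub) < min_length:
                    break
                found = _scan_best(panel, windows_cache, sub, max_mismatch)
                if found is not None:
                    hit = found + (len(sub),)
                    break
            placement_cache[seq] = hit
        hit = placement_cache[seq]
        if hit is None:
            continue
        ref_idx, pos, strand, oriented, mapq, L = hit
        out.append(
            AlignedRead(
                read_id=read_id,
                ref_id=references[ref_idx].id,
                start=pos,
                strand=strand,
                observed=tuple((pos + k, oriented[k]) for k in range(L)),
                mapq=mapq,
            )
        )
    return out
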