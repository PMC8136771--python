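"""Hairpin folding and the anticodon-loop substrate rule.

The minimal recognition element of the queuine tRNA ribosyltransferase is a
U33-G34-U35 sequence presented in a 7-base anticodon loop — an intact tRNA
tertiary structure is dispensable, so short designed stem-loops can be
classified directly.  The fold model is deliberately structural, not
thermodynamic: a single hairpin with one contiguous stem of stacked
Watson–Crick pairs (G·U optional, off by default) closing a loop of at
least 3 unpaired bases, scored by stem length (pair count).
"""

from __future__ import annotations

from dataclasses import dataclass

_WC = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}
_GU = {("G", "U"), ("U", "G")}

MIN_LOOP = 3


@dataclass(frozen=True)
class StemLoopFold:
    """A single-hairpin fold.

    ``loop_start``/``loop_end`` are 1-based inclusive positions of the
    unpaired loop; ``stem_length`` counts stacked base pairs.  ``paired``
    is False when no stem of >=3 bp exists (the other fields are then zero
    or empty).
    """

    stem_length: int
    loop_start: int
    loop_end: int
    loop_sequence: str
    paired: bool

    @property
    def loop_length(self) -> int:
        return self.loop_end - self.loop_start + 1 if self.paired else 0


@dataclass(frozen=True)
class SubstrateVerdict:
    is_substrate: bool
    reason: str
    anticodon: str | None = None


def _pairs(a: str, b: str, allow_gu: bool) -> bool:
    return (a, b) in _WC or (allow_gu and (a, b) in _GU)


def fold_stemloop(sequence: str, allow_gu: bool = False, min_stem: int = 3) -> StemLoopFold:
    """Fold a short oligonucleotide into its best single hairpin.

    Enumerates every contiguous stem: outermost pair (i, j) extended inward
    while bases pair and the enclosed loop stays >= ``MIN_LOOP``.  The fold
    maximizing stem length wins; ties break toward the loop whose centre is
    closest to the sequence centre, then toward the smallest ``loop_start``.

    Parameters
    ----------
    sequence : str
        8–60 nt, RNA or DNA alphabet (T treated as U).
    allow_gu : bool
        Permit G·U pairs in the stem (default off; the designed 19-mers
        fold identically either way).
    min_stem : int
        Folds with fewer stacked pairs are reported unpaired.
    """
    seq = sequence.upper().replace("T", "U")
    n = len(seq)
    if not 8 <= n <= 60:
        raise ValueError(f"sequence length {n} outside supported range 8..60")

    best: tuple | None = None  # (-stem, centrality, loop_start, loop_end)
    centre = (n + 1) / 2
    for i in range(n):  # 0-based outermost pair
        for j in range(i + MIN_LOOP + 1, n):
            if not _pairs(seq[i], seq[j], allow_gu):
                continue
            k = 1
            while (
                i + k < j - k
                and (j - k) - (i + k) - 1 >= MIN_LOOP
                and _pairs(seq[i + k], seq[j - k], allow_gu)
            ):
                k += 1
            loop_start, loop_end = i + k + 1, j - k + 1  # 1-based inclusive
            centrality = abs((loop_start + loop_end) / 2 - centre)
            cand = (-k, centrality, loop_start, loop_end)
            if best is None or cand < best:
                best = cand

    if best is None or -best[0] < min_stem:
        return StemLoopFold(0, 0, 0, "", False)
    stem, _, loop_start, loop_end = best
    return StemLoopFold(-stem, loop_start, loop_end, seq[loop_start - 1 : loop_end], True)


def classify_substrate_loop(fold: StemLoopFold) -> SubstrateVerdict:
    """Apply the U33-G34-U35 / 7-base-loop substrate rule to a fold.

    In a 7-base anticodon loop, loop positions 2–4 are tRNA positions
    33–35 and loop positions 3–5 are the anticodon.  The verdict carries
    the anticodon whenever the loop has length 7, substrate or not.
    """
    if not fold.paired:
        return SubstrateVerdict(False, "no hairpin")
    if fold.loop_length != 7:
        return SubstrateVerdict(False, f"loop length {fold.loop_length}, rule requires 7")
    loop = fold.loop_sequence
    anticodon = loop[2:5]
    if loop[1] == "U" and loop[2] == "G" and loop[3] == "U":
        return SubstrateVerdict(True, "U33-G34-U35 in 7-base loop", anticodon)
    return SubstrateVerdict(False, f"loop positions 2-4 read {loop[1:4]}, rule requires UGU", anticodon)
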