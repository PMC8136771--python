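"""Independent brute-force oracles the implementation is checked against.

Deliberately naive: plain dictionaries and linear scans, no numpy, no reuse
of any code path from the package under test.
"""

from __future__ import annotations

MIN_LOOP = 3
_WC = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}
_GU = {("G", "U"), ("U", "G")}


def brute_fold(sequence: str, allow_gu: bool = False, min_stem: int = 3):
    """Enumerate every contiguous-stem hairpin (i, j, k) and rank like the spec.

    Returns (stem_length, loop_start, loop_end) 1-based, or None if no stem
    of >= min_stem base pairs exists.
    """
    seq = sequence.upper().replace("T", "U")
    n = len(seq)

    def pairs(a, b):
        return (a, b) in _WC or (allow_gu and (a, b) in _GU)

    candidates = []
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(1, n):
                # stem of k stacked pairs: (i, j), (i+1, j-1) ... loop inside
                inner_i, inner_j = i + k - 1, j - k + 1
                if inner_i >= inner_j or inner_j - inner_i - 1 < MIN_LOOP:
                    break
                if not all(pairs(seq[i + t], seq[j - t]) for t in range(k)):
                    break
                if k >= min_stem:
                    loop_start, loop_end = inner_i + 2, inner_j  # 1-based
                    centrality = abs((loop_start + loop_end) / 2 - (n + 1) / 2)
                    candidates.append((-k, centrality, loop_start, loop_end))
    if not candidates:
        return None
    k, _, ls, le = min(candidates)
    return (-k, ls, le)


def brute_pileup(alignments, references):
    """{(ref_id, pos): {base: count}} by direct tally."""
    out = {}
    for aln in alignments:
        for pos, base in aln.observed:
            out.setdefault((aln.ref_id, pos), {}).setdefault(base, 0)
            out[(aln.ref_id, pos)][base] += 1
    return out


def brute_regions(alignments, references, min_coverage):
    """[(ref_id, start, end, mean, max)] by position-by-position scan."""
    tally = brute_pileup(alignments, references)
    regions = []
    for ref in references:
        run = []
        for pos in range(len(ref) + 1):
            depth = sum(tally.get((ref.id, pos), {}).values()) if pos < len(ref) else 0
            if depth >= min_coverage and pos < len(ref):
                run.append((pos, depth))
            elif run:
                depths = [d for _, d in run]
                regions.append(
                    (ref.id, run[0][0], run[-1][0] + 1, sum(depths) / len(depths), max(depths))
                )
                run = []
    return regions


def brute_calls(alignments, references, min_coverage):
    """[(ref_id, pos, ref_base, alt_base, depth, alt_count)] in detected regions."""
    tally = brute_pileup(alignments, references)
    regions = brute_regions(alignments, references, min_coverage)
    diag = {"G": "T", "C": "A"}
    calls = []
    for ref in references:
        dna = ref.sequence.replace("U", "T")
        for ref_id, start, end, _, _ in regions:
            if ref_id != ref.id:
                continue
            for pos in range(start, end):
                counts = tally.get((ref.id, pos), {})
                ref_base = dna[pos]
                alt = diag.get(ref_base)
                if alt and counts.get(alt, 0) > 0:
                    calls.append((ref.id, pos, ref_base, alt, sum(counts.values()), counts[alt]))
    return calls
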