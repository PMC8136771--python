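"""Pileup, coverage-island detection, transversion calls and the substrate filter."""

import numpy as np
import pytest

from capq.alignio import AlignedRead
from capq.references import ReferenceRecord, anticodon_of, is_q_family
from capq.signature import (
    CoverageRegion,
    TransversionCall,
    call_transversions,
    detect_regions,
    filter_substrate_regions,
    pileup,
    transcript_position,
)
from oracles import brute_calls, brute_pileup, brute_regions


def _read(rid, ref_id, start, bases):
    return AlignedRead(rid, ref_id, start, "+", tuple((start + k, b) for k, b in enumerate(bases)))


REF = ReferenceRecord("r1", "GGGGGGGGGG", "other")  # DNA: G at every position


def test_pileup_tallies_bases_per_position():
    reads = [_read("a", "r1", 2, "G"), _read("b", "r1", 2, "G"), _read("c", "r1", 2, "T")]
    columns = pileup(reads, [REF])
    (col,) = columns["r1"]
    assert col.position == 2 and col.depth == 3
    assert col.base_counts == {"G": 2, "T": 1}


def test_pileup_empty_and_out_of_range():
    assert pileup([], [REF]) == {"r1": []}
    with pytest.raises(ValueError, match="outside"):
        pileup([_read("a", "r1", 9, "GG")], [REF])


def test_pileup_conservation_on_simulated_run(pipeline_result):
    refs, _, result = pipeline_result
    depth_total = sum(c.depth for cols in result.columns.values() for c in cols)
    obs_total = sum(len(a.observed) for a in result.alignments)
    assert depth_total == obs_total


def _coverage_reads(depths, ref_id="r1"):
    """One-base reads realizing an exact per-position depth profile."""
    reads = []
    for pos, d in enumerate(depths):
        for i in range(d):
            reads.append(_read(f"{pos}.{i}", ref_id, pos, "G"))
    return reads


def test_detect_regions_from_depth_profile():
    ref = ReferenceRecord("r1", "G" * 5, "other")
    columns = pileup(_coverage_reads([0, 12, 13, 11, 0]), [ref])
    (region,) = detect_regions(columns, [ref], min_coverage=10)
    assert (region.start, region.end, region.length) == (1, 4, 3)
    assert region.mean_coverage == 12.0 and region.max_coverage == 13


def test_detect_regions_floor_is_inclusive_at_10_and_fails_at_9():
    ref = ReferenceRecord("r1", "G" * 4, "other")
    assert detect_regions(pileup(_coverage_reads([9, 9, 9, 9]), [ref]), [ref], 10) == []
    regions = detect_regions(pileup(_coverage_reads([10, 10, 10, 10]), [ref]), [ref], 10)
    assert len(regions) == 1 and regions[0].length == 4


def test_regions_never_merge_across_a_gap():
    ref = ReferenceRecord("r1", "G" * 7, "other")
    columns = pileup(_coverage_reads([12, 12, 12, 0, 11, 11, 11]), [ref])
    regions = detect_regions(columns, [ref], 10)
    assert [(r.start, r.end) for r in regions] == [(0, 3), (4, 7)]


def test_call_transversions_ratio_and_diagnostic_only():
    ref = ReferenceRecord("r1", "GAC", "other")  # DNA G, A, C
    reads = [_read(f"g{i}", "r1", 0, "GAC") for i in range(6)] + [
        _read(f"t{i}", "r1", 0, "TGC") for i in range(4)
    ]
    columns = pileup(reads, [ref])
    regions = detect_regions(columns, [ref], min_coverage=10)
    calls = call_transversions(columns, regions)
    # G->T at pos 0 emitted; A column never called; C->A not present (G observed instead)
    assert [(c.position, c.ref_base, c.alt_base, c.depth, c.alt_count) for c in calls] == [
        (0, "G", "T", 10, 4)
    ]
    assert calls[0].ratio == pytest.approx(0.4)


def test_call_transversions_c_to_a_minus_strand_image():
    ref = ReferenceRecord("r1", "CCC", "other")
    reads = [_read(f"c{i}", "r1", 0, "CCC") for i in range(7)] + [
        _read(f"a{i}", "r1", 0, "CAC") for i in range(5)
    ]
    columns = pileup(reads, [ref])
    calls = call_transversions(columns, detect_regions(columns, [ref], 10))
    assert [(c.position, c.ref_base, c.alt_base, c.alt_count) for c in calls] == [(1, "C", "A", 5)]


def _region(length=20, ref_id="r1"):
    return CoverageRegion(ref_id, 0, length, 50.0, 60)


def _call(ratio, depth=50, position=5, ref_id="r1"):
    return TransversionCall(ref_id, position, "G", "T", depth, round(ratio * depth))


@pytest.mark.parametrize(
    "length, ratio, depth, passes",
    [
        (16, 0.9, 50, False),  # length must be strictly > 16
        (17, 0.9, 50, True),
        (20, 0.30, 10, True),  # ratio and depth thresholds inclusive
        (20, 0.29, 100, False),
        (20, 0.9, 9, False),
    ],
)
def test_filter_boundary_semantics(length, ratio, depth, passes):
    region = _region(length)
    call = TransversionCall("r1", 5, "G", "T", depth, round(ratio * depth))
    (record,) = filter_substrate_regions([region], [call])
    assert record.passes is passes


def test_filter_best_call_selection_and_no_call_reason():
    region = _region(30)
    calls = [
        TransversionCall("r1", 10, "G", "T", 40, 20),  # ratio 0.5
        TransversionCall("r1", 3, "G", "T", 80, 40),  # ratio 0.5, higher depth wins
        TransversionCall("r1", 7, "C", "A", 100, 20),  # ratio 0.2
    ]
    (record,) = filter_substrate_regions([region], calls)
    assert record.best_call.position == 3 and record.best_call.depth == 80
    (empty,) = filter_substrate_regions([_region(30, "r2")], [])
    assert not empty.passes and empty.reason == "no transversion"


def _random_fixture(rng):
    n_refs = rng.integers(1, 4)
    refs = [
        ReferenceRecord(f"f{i}", "".join(rng.choice(list("ACGU"), size=rng.integers(30, 80))), "other")
        for i in range(n_refs)
    ]
    reads = []
    for i in range(int(rng.integers(0, 400))):
        ref = refs[rng.integers(len(refs))]
        L = int(rng.integers(5, 30))
        start = int(rng.integers(0, len(ref) - L + 1))
        bases = list(ref.sequence.replace("U", "T")[start : start + L])
        for k in range(L):  # sprinkle mismatches
            if rng.random() < 0.1:
                bases[k] = "ACGT"[rng.integers(4)]
        reads.append(_read(f"x{i}", ref.id, start, "".join(bases)))
    return refs, reads


def test_pileup_regions_calls_match_bruteforce_oracle():
    rng = np.random.default_rng(2)
    for _ in range(8):
        refs, reads = _random_fixture(rng)
        columns = pileup(reads, refs)
        got_pile = {
            (ref_id, c.position): {b: n for b, n in c.base_counts.items()}
            for ref_id, cols in columns.items()
            for c in cols
        }
        assert got_pile == brute_pileup(reads, refs)
        for floor in (1, 5, 10):
            regions = detect_regions(columns, refs, floor)
            got_regions = [
                (r.ref_id, r.start, r.end, r.mean_coverage, r.max_coverage) for r in regions
            ]
            assert got_regions == [
                (a, b, c, pytest.approx(d), e) for a, b, c, d, e in brute_regions(reads, refs, floor)
            ]
            calls = call_transversions(columns, regions)
            got_calls = sorted((c.ref_id, c.position, c.ref_base, c.alt_base, c.depth, c.alt_count) for c in calls)
            assert got_calls == sorted(brute_calls(reads, refs, floor))


def test_region_maximality_and_disjointness(pipeline_result):
    refs, _, result = pipeline_result
    depth = {r.id: np.zeros(len(r), dtype=int) for r in refs}
    for ref_id, cols in result.columns.items():
        for c in cols:
            depth[ref_id][c.position] = c.depth
    by_ref = {}
    for reg in result.regions:
        by_ref.setdefault(reg.ref_id, []).append(reg)
    for ref_id, regions in by_ref.items():
        regions = sorted(regions, key=lambda r: r.start)
        for a, b in zip(regions, regions[1:]):
            assert a.end <= b.start  # disjoint
        for reg in regions:
            d = depth[ref_id]
            assert (d[reg.start : reg.end] >= 10).all()
            if reg.start > 0:
                assert d[reg.start - 1] < 10
            if reg.end < len(d):
                assert d[reg.end] < 10


def test_threshold_monotonicity_on_random_fixtures():
    rng = np.random.default_rng(3)
    for _ in range(30):
        region = CoverageRegion("r1", 0, int(rng.integers(10, 40)), 30.0, 40)
        depth = int(rng.integers(5, 60))
        calls = [
            TransversionCall("r1", int(p), "G", "T", depth, int(rng.integers(0, depth)) + 1)
            for p in rng.choice(region.length, size=min(3, region.length), replace=False)
        ]
        base = filter_substrate_regions([region], calls)[0].passes
        for kwargs in (
            {"min_length": 25}, {"min_ratio": 0.6}, {"min_depth": 30},
        ):
            stricter = filter_substrate_regions([region], calls, **kwargs)[0].passes
            if stricter:
                assert base  # tightening any threshold can only shrink the passing set


def test_minus_strand_substrate_maps_back_to_position_34(pipeline_result):
    refs, truth, result = pipeline_result
    minus = [
        r for r in refs
        if r.genome_strand == "-" and r.anticodon_start is not None and is_q_family(anticodon_of(r))
    ]
    assert minus, "panel should contain a minus-strand substrate"
    passing = {rec.region.ref_id: rec for rec in result.passing}
    for ref in minus:
        rec = passing[ref.id]
        assert rec.best_call.ref_base == "C" and rec.best_call.alt_base == "A"
        assert transcript_position(ref, rec.best_call.position) == ref.anticodon_start
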