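"""Synthetic capture-release generator: truth bookkeeping and the abasic-site model."""

import math

import numpy as np
import pytest

from capq.pipeline import PipelineConfig, run_pipeline
from capq.references import anticodon_of, is_q_family
from capq.signature import call_transversions, detect_regions, pileup
from capq.alignio import align_simple
from capq.simulate import SimConfig, build_reference_panel, default_config, simulate_capture


def test_panel_counts_and_q_family_membership():
    refs, contaminants = build_reference_panel(4, 2, 2, 1, seed=1)
    assert len(refs) == 9
    gun = [r for r in refs if r.anticodon_start is not None and is_q_family(anticodon_of(r))]
    assert len(gun) == 4
    assert all(60 <= len(r) <= 90 for r in refs if r.category == "tRNA_cyto")
    assert contaminants and all(set(seq) <= set("ACGT") for _, seq in contaminants)


def test_panel_deterministic_under_seed(tmp_path):
    from capq.references import write_references

    for name in ("a", "b"):
        refs, _ = build_reference_panel(3, 1, 1, 1, seed=42)
        write_references(refs, tmp_path / f"{name}.fasta", tmp_path / f"{name}.tsv")
    assert (tmp_path / "a.fasta").read_bytes() == (tmp_path / "b.fasta").read_bytes()
    assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()


def test_simulation_byte_identical_under_seed(panel):
    refs, contaminants = panel
    cfg = default_config(refs, total_molecules=2000, seed=9, contaminant_fraction=0.1)
    r1, t1 = simulate_capture(refs, cfg, contaminants)
    r2, t2 = simulate_capture(refs, cfg, contaminants)
    assert r1 == r2
    assert t1.reads.equals(t2.reads) and t1.references.equals(t2.references)


def test_truth_margins_match_emitted_reads(simulated_run):
    refs, _, _, reads, truth = simulated_run
    assert len(truth.reads) == len(reads)
    per_ref = truth.reads["ref_id"].value_counts()
    for _, row in truth.references.iterrows():
        assert per_ref.get(row.ref_id, 0) == row.reads
    cap = truth.reads[truth.reads.captured].groupby("ref_id").size()
    # cleaved molecules emit two truth rows; captured read rows >= captured molecules
    for _, row in truth.references.iterrows():
        if row.captured:
            assert cap.get(row.ref_id, 0) >= row.captured


def test_full_termination_means_no_read_spans_the_abasic_site(panel):
    refs, _ = panel
    cfg = default_config(
        refs, total_molecules=3000, seed=3, captured_fraction=1.0,
        p_readthrough_T=0.0, p_readthrough_other=0.0, p_terminate=1.0, seq_error_rate=0.0,
    )
    reads, truth = simulate_capture(refs, cfg)
    abasic = {r.id: r.anticodon_start - 1 for r in refs if r.anticodon_start is not None}
    captured = truth.reads[truth.reads.captured]
    assert len(captured) > 0
    for _, row in captured.iterrows():
        a = abasic[row.ref_id]
        assert row.start > a or row.end <= a, "read spans the abasic site"


def test_pure_readthrough_gives_transversion_ratio_one(panel):
    refs, _ = panel
    cfg = default_config(
        refs, total_molecules=1500, seed=4, captured_fraction=1.0,
        p_readthrough_T=1.0, p_readthrough_other=0.0, p_terminate=0.0, seq_error_rate=0.0,
        cca_tail=False,  # the pipeline clips tails; this test aligns raw reads
    )
    reads, truth = simulate_capture(refs, cfg)
    alignments = align_simple(reads, refs)
    columns = pileup(alignments, refs)
    regions = detect_regions(columns, refs, min_coverage=10)
    calls = call_transversions(columns, regions)
    gun = {r.id for r in refs if r.anticodon_start is not None and is_q_family(anticodon_of(r))}
    best = {}
    for c in calls:
        if c.ref_id not in best or c.ratio > best[c.ref_id].ratio:
            best[c.ref_id] = c
    for ref_id in gun:
        assert best[ref_id].ratio == 1.0
        assert best[ref_id].depth >= 100


def test_rt_outcome_fractions_match_configured_probabilities(panel):
    refs, _ = panel
    cfg = default_config(
        refs, total_molecules=5000, seed=7, captured_fraction=1.0,
        p_readthrough_T=0.6, p_terminate=0.3, p_readthrough_other=0.1,
    )
    _, truth = simulate_capture(refs, cfg)
    outcomes = truth.reads[truth.reads.captured]["outcome"]
    n = len(outcomes)
    for outcome, p in (("readthrough_T", 0.6), ("terminated", 0.3), ("readthrough_other", 0.1)):
        frac = (outcomes == outcome).mean()
        se = math.sqrt(p * (1 - p) / n)
        assert abs(frac - p) <= 3 * se, (outcome, frac)


def test_backbone_cleavage_emits_two_fragments_split_at_site(panel):
    refs, _ = panel
    cfg = default_config(
        refs, total_molecules=1000, seed=8, captured_fraction=1.0, p_backbone_cleave=1.0,
        seq_error_rate=0.0,
    )
    reads, truth = simulate_capture(refs, cfg)
    captured = truth.reads[truth.reads.captured]
    assert set(captured["outcome"]) == {"cleaved_5p", "cleaved_3p"}
    abasic = {r.id: r.anticodon_start - 1 for r in refs if r.anticodon_start is not None}
    five = captured[captured.outcome == "cleaved_5p"]
    assert (five["end"] <= five["ref_id"].map(abasic)).all()
    three = captured[captured.outcome == "cleaved_3p"]
    assert (three["start"] == three["ref_id"].map(abasic) + 1).all()


def test_coverage_asymmetry_3prime_exceeds_5prime_with_termination(pipeline_result):
    refs, truth, result = pipeline_result
    gun = {r.id: r for r in refs if r.anticodon_start is not None and is_q_family(anticodon_of(r))}
    for ref_id, ref in gun.items():
        depth = np.zeros(len(ref))
        for col in result.columns[ref_id]:
            depth[col.position] = col.depth
        if ref.genome_strand == "+":
            a = ref.anticodon_start - 1
            five, three = depth[:a], depth[a + 1 :]
        else:  # transcript 3' side is the genomic 5' side
            a = len(ref) - ref.anticodon_start
            five, three = depth[a + 1 :], depth[:a]
        assert three.mean() > five.mean(), ref_id


def test_capture_on_nonsubstrate_reference_rejected(panel):
    refs, _ = panel
    snorna = next(r for r in refs if r.category == "snoRNA")
    non_gun = next(r for r in refs if r.category == "tRNA_cyto" and not is_q_family(anticodon_of(r)))
    for bad in (snorna, non_gun):
        cfg = SimConfig(abundances={bad.id: 100.0}, captured_fraction={bad.id: 0.5})
        with pytest.raises(ValueError, match="non-(tRNA|GUN)"):
            simulate_capture(refs, cfg)


def test_invalid_probability_configuration_rejected():
    with pytest.raises(ValueError, match="sum to"):
        SimConfig(abundances={}, p_readthrough_T=0.6, p_readthrough_other=0.1, p_terminate=0.2).validate()
    with pytest.raises(ValueError, match="outside"):
        SimConfig(abundances={}, seq_error_rate=1.5).validate()


def test_zero_capture_negative_control_yields_no_passing_records(panel):
    refs, contaminants = panel
    cfg = default_config(refs, total_molecules=4000, seed=5, captured_fraction=0.0)
    reads, _ = simulate_capture(refs, cfg, contaminants)
    result = run_pipeline(reads, refs, PipelineConfig(), contaminants=contaminants)
    assert result.passing == []
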