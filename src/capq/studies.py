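"""Synthetic stand-ins for the capture-release study runs.

The assay was applied to three Q-deficient RNA sources — MDA-MB-231 breast
cancer cells, neonatal mouse liver and splenocytes from EAE-diseased mice —
whose captured pools were overwhelmingly GUN tRNA with small snoRNA and 45S
pre-rRNA components.  ``TISSUE_COMPOSITIONS`` encodes those pool
compositions as molecule fractions (GUN tRNA covers cytosolic plus
mitochondrial jointly; the snoRNA and 45S values sit at the reported
per-tissue levels, splenocytes exactly at 4.7% snoRNA / 2.6% 45S with GUN
as the remainder).  ``simulate_tissue_run`` draws a full synthetic run at
one of those compositions and pushes it through the pipeline, so run-level
read percentages can be recomputed from scratch rather than asserted.

These are synthetic stand-ins for sequencing runs that are not otherwise
reproducible at the desk; what they validate is the analysis pipeline's
ability to recover a configured pool composition, not the wet-lab numbers.
"""

from __future__ import annotations

from dataclasses import dataclass

from capq.pipeline import PipelineConfig, PipelineResult, run_pipeline
from capq.references import ReferenceRecord, anticodon_of, is_q_family
from capq.simulate import SimConfig, TruthTable, build_reference_panel, simulate_capture

# molecule fractions of the captured pool: (GUN tRNA, snoRNA, 45S, other)
TISSUE_COMPOSITIONS: dict[str, dict[str, float]] = {
    "mda_mb_231": {"gun_trna": 0.9945, "snorna": 0.0040, "rrna_45s": 0.0005, "other": 0.0010},
    "neonatal_liver": {"gun_trna": 0.9650, "snorna": 0.0150, "rrna_45s": 0.0050, "other": 0.0150},
    "splenocytes": {"gun_trna": 0.9270, "snorna": 0.0470, "rrna_45s": 0.0260, "other": 0.0000},
}


@dataclass
class StudyRun:
    tissue: str
    references: list[ReferenceRecord]
    truth: TruthTable
    result: PipelineResult

    def gun_read_percent(self, denominator: str = "in_regions") -> float:
        """Cytosolic + mitochondrial GUN tRNA reads as a percent of the run."""
        summary = self.result.summary
        if denominator == "in_regions":
            assigned = sum(
                n for c, n in summary.read_counts.items() if c != "unassigned"
            )
            gun = summary.read_counts["tRNA_cyto_GUN"] + summary.read_counts["tRNA_mito"]
            return 100.0 * gun / assigned if assigned else 0.0
        return summary.percents["tRNA_cyto_GUN"] + summary.percents["tRNA_mito"]

    def category_percent(self, category: str, denominator: str = "in_regions") -> float:
        summary = self.result.summary
        if denominator == "in_regions":
            assigned = sum(n for c, n in summary.read_counts.items() if c != "unassigned")
            return 100.0 * summary.read_counts[category] / assigned if assigned else 0.0
        return summary.percents[category]


def simulate_tissue_run(
    tissue: str,
    seed: int,
    total_molecules: int = 20000,
    captured_fraction: float = 0.85,
    contaminant_fraction: float = 0.02,
) -> StudyRun:
    """Simulate one capture-release run at a tissue's pool composition and analyse it.

    The panel holds 4 cytosolic GUN tRNAs, 1 mitochondrial GUN tRNA, 2
    non-GUN tRNAs (the "other" pool), 2 snoRNAs and 1 45S fragment; the
    tissue's molecule fractions are split evenly within each class.
    """
    frac = TISSUE_COMPOSITIONS[tissue]
    refs, contaminants = build_reference_panel(4, 2, 2, 1, seed=seed, n_mito_trna=1)

    classes: dict[str, list[str]] = {"gun_trna": [], "snorna": [], "rrna_45s": [], "other": []}
    captured: dict[str, float] = {}
    for ref in refs:
        if ref.anticodon_start is not None and is_q_family(anticodon_of(ref)):
            classes["gun_trna"].append(ref.id)
            captured[ref.id] = captured_fraction
        elif ref.category == "snoRNA":
            classes["snorna"].append(ref.id)
        elif ref.category == "rRNA_45S":
            classes["rrna_45s"].append(ref.id)
        else:
            classes["other"].append(ref.id)

    abundances: dict[str, float] = {}
    for cls, ids in classes.items():
        if not ids:
            continue
        for ref_id in ids:
            abundances[ref_id] = total_molecules * frac[cls] / len(ids)

    cfg = SimConfig(
        abundances=abundances,
        captured_fraction=captured,
        contaminant_fraction=contaminant_fraction,
        seed=seed,
    )
    reads, truth = simulate_capture(refs, cfg, contaminants)
    result = run_pipeline(reads, refs, PipelineConfig(seed=seed), contaminants=contaminants)
    return StudyRun(tissue=tissue, references=refs, truth=truth, result=result)
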