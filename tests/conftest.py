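import pytest

from capq.pipeline import PipelineConfig, run_pipeline
from capq.simulate import build_reference_panel, default_config, simulate_capture


@pytest.fixture(scope="session")
def panel():
    """Small annotated panel: 4 GUN tRNA, 2 non-GUN tRNA, 2 snoRNA, 1 rRNA."""
    refs, contaminants = build_reference_panel(4, 2, 2, 1, seed=1)
    return refs, contaminants


@pytest.fixture(scope="session")
def simulated_run(panel):
    """One default 20k-molecule capture-release run with 5% contaminants."""
    refs, contaminants = panel
    cfg = default_config(refs, total_molecules=20000, seed=7, contaminant_fraction=0.05)
    reads, truth = simulate_capture(refs, cfg, contaminants)
    return refs, contaminants, cfg, reads, truth


@pytest.fixture(scope="session")
def pipeline_result(simulated_run):
    refs, contaminants, cfg, reads, truth = simulated_run
    result = run_pipeline(reads, refs, PipelineConfig(), contaminants=contaminants)
    return refs, truth, result
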