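import pytest

from ifnsig.design import CohortSpec, StudyDesign, default_design


@pytest.fixture
def tiny_design() -> StudyDesign:
    """Two-cohort design small enough for fast unit tests."""
    d = default_design(seed=42)
    d.restrict_cohorts([
        CohortSpec("hc", 12, "whole_blood", healthy_control=True),
        CohortSpec("sle", 8, "whole_blood"),
    ])
    d.qc_fail_fraction = 0.0
    return d


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full pipeline run on the default design, shared across tests."""
    from ifnsig.pipeline import PipelineConfig, run_pipeline

    outdir = tmp_path_factory.mktemp("default_run")
    config = PipelineConfig(outdir=outdir, seed=11)
    manifest = run_pipeline(config)
    return config, manifest
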