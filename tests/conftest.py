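import pytest

from lncnet import PipelineConfig, SimulationConfig, run_pipeline, simulate_cohort

#: single seed used for every cohort-level check in the suite
COHORT_SEED = 11


@pytest.fixture(scope="session")
def cohort(tmp_path_factory):
    """Default synthetic cohort, generated once per session."""
    outdir = tmp_path_factory.mktemp("cohort")
    return simulate_cohort(SimulationConfig(seed=COHORT_SEED), outdir)


def pipeline_config(cohort, outdir) -> PipelineConfig:
    return PipelineConfig(
        counts=str(cohort.counts_path),
        samples=str(cohort.samples_path),
        gtf=str(cohort.gtf_path),
        tf_gmt=str(cohort.tf_gmt_path),
        terms_gmt=str(cohort.terms_gmt_path),
        mirna=str(cohort.mirna_path),
        ct=str(cohort.ct_path),
        outdir=str(outdir),
        seed=COHORT_SEED,
    )


@pytest.fixture(scope="session")
def pipeline_result(cohort, tmp_path_factory):
    """Full pipeline run on the default cohort, once per session."""
    outdir = tmp_path_factory.mktemp("run")
    return run_pipeline(pipeline_config(cohort, outdir)), outdir
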