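import pytest

from etsar import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def cohort131():
    """Full-size study: 26 planted genes per category, one extra both-up
    gene and 29 AR-bound decoys — 131 genes carry a real category."""
    config = SimulationConfig(
        n_per_category=26, n_extra_both_up=1, n_decoys=29,
        effect_size=1.5, n_tumor_ets_pos=50, n_tumor_ets_neg=50, n_normal=30,
        seed=7,
    )
    return simulate_cohort(config)


@pytest.fixture(scope="session")
def small_cohort():
    """Quick cohort for structural tests (300 genes, 20/20/10 samples)."""
    config = SimulationConfig(
        n_genes=300, n_per_category=5, n_decoys=5,
        n_tumor_ets_pos=20, n_tumor_ets_neg=20, n_normal=10,
        frac_ar_bound=0.3, seed=11,
    )
    return simulate_cohort(config)


@pytest.fixture(scope="session")
def pipeline_run(cohort131, tmp_path_factory):
    """One end-to-end run over the 131-gene study, shared across tests."""
    from etsar import DEConfig, PipelineConfig, run_all

    config = PipelineConfig(
        simulation=cohort131.config,
        de_rnaseq=DEConfig(), de_microarray=DEConfig(),
        n_null=200, seed=7,
    )
    out = tmp_path_factory.mktemp("pipeline")
    summary = run_all(config, out)
    return config, out, summary
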