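import numpy as np
import pandas as pd
import pytest

from imprintseq.io_tables import AlleleCountMatrix
from imprintseq.synthetic import SimConfig, simulate_experiment


@pytest.fixture
def tiny_acm() -> AlleleCountMatrix:
    """Hand-built 2-gene (4 allele rows), 1-time-point reciprocal experiment."""
    samples = pd.DataFrame(
        {
            "maternal_genotype": ["B73", "B73", "W22", "W22"],
            "paternal_genotype": ["W22", "W22", "B73", "B73"],
            "dap": [14, 14, 14, 14],
            "replicate": [1, 2, 1, 2],
        },
        index=pd.Index(["BW_r1", "BW_r2", "WB_r1", "WB_r2"], name="sample_id"),
    )
    counts = pd.DataFrame(
        {
            "BW_r1": [100, 50, 30, 20],
            "BW_r2": [110, 40, 35, 15],
            "WB_r1": [60, 90, 25, 25],
            "WB_r2": [55, 95, 20, 30],
        },
        index=["B73:gA", "W22:W22_gA", "B73:gB", "W22:W22_gB"],
    )
    return AlleleCountMatrix(counts=counts, samples=samples)


@pytest.fixture(scope="session")
def small_sim():
    """A small but class-complete simulated reciprocal time series."""
    cfg = SimConfig(
        n_genes={
            "MEG_constitutive": 30,
            "PEG_constitutive": 15,
            "MEG_transient": 15,
            "PEG_transient": 15,
            "maternal_bias": 15,
            "paternal_bias": 15,
            "biparental": 120,
            "zein_like": 2,
            "silent": 5,
        },
        library_size_mean=2e6,
        seed=421,
    )
    acm, truth = simulate_experiment(cfg)
    return cfg, acm, truth


@pytest.fixture(scope="session")
def small_run(small_sim):
    """Imprinting calls and summaries for the small simulated experiment."""
    from imprintseq.imprinting import run_imprinting

    cfg, acm, truth = small_sim
    calls, summary = run_imprinting(acm)
    return cfg, acm, truth, calls, summary
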