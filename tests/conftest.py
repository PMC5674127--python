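import numpy as np
import pandas as pd
import pytest

from thermotx import SimulationConfig, simulate_expression_experiment
from thermotx.containers import ExpressionExperiment


@pytest.fixture(scope="session")
def default_experiment():
    """A mid-sized simulated experiment with planted effects (seed 11)."""
    cfg = SimulationConfig(seed=11, n_genes=2000, dispersion=0.05)
    return simulate_expression_experiment(cfg)


@pytest.fixture(scope="session")
def small_experiment():
    """A small all-null experiment for fast structural tests."""
    cfg = SimulationConfig(seed=3, n_genes=200, dispersion=0.05)
    return simulate_expression_experiment(
        cfg, class_mix={"null": 1.0, "temp_responsive": 0.0,
                        "rate_linear": 0.0, "mixed": 0.0}
    )


@pytest.fixture()
def tiny_experiment():
    """Hand-built 3-gene, 4-sample experiment with known numbers."""
    counts = pd.DataFrame(
        {
            "s1": [1000, 0, 10],
            "s2": [900, 5, 20],
            "s3": [100, 50, 15],
            "s4": [120, 40, 25],
        },
        index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
    )
    samples = pd.DataFrame(
        {
            "temperature_C": [30.0, 30.0, 65.0, 65.0],
            "growth_rate_per_h": [0.006, 0.006, 0.274, 0.274],
            "replicate": [1, 2, 1, 2],
        },
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"),
    )
    genes = pd.DataFrame(
        {"length_nt": [1000, 500, 2000], "cog_categories": ["J", "C;G", "NC"]},
        index=counts.index,
    )
    return ExpressionExperiment(counts=counts, samples=samples, genes=genes)
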