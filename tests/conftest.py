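import numpy as np
import pandas as pd
import pytest

from ooribo.simulate import (
    SimulationConfig,
    generate_ortholog_transcriptomes,
    simulate_experiment,
)


@pytest.fixture(scope="session")
def tiny_transcriptomes():
    """10 short ortholog pairs at 10% divergence."""
    return generate_ortholog_transcriptomes(
        n_genes=10, length_range=(60, 120), divergence=0.1, seed=11
    )


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_genes=40,
        length_range=(120, 240),
        divergence=0.1,
        reads_per_sample=3000,
        seed=5,
    )


@pytest.fixture(scope="session")
def small_experiment(small_config):
    """Full 3x3x2 design at reduced depth, shared across modules."""
    return simulate_experiment(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(123)


@pytest.fixture
def two_gene_counts():
    """The hand-computed TPM example: counts (10, 10), lengths (100, 200)."""
    counts = pd.DataFrame({"s1": [10, 10]}, index=pd.Index(["gA", "gB"], name="gene"))
    lengths = pd.Series({"gA": 100.0, "gB": 200.0})
    return counts, lengths
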