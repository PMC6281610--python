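import numpy as np
import pandas as pd
import pytest

from crossmr import SyntheticConfig, generate_study
from crossmr.signatures import GeneSignature


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(
        n_genes=300,
        n_regulators=20,
        regulon_size_range=(10, 20),
        n_planted=3,
        n_per_group=6,
        n_patients=60,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return generate_study(small_config)


@pytest.fixture
def toy_signature():
    """Five genes with scores 5..1 (already in rank order)."""
    return GeneSignature.from_scores(
        ["g1", "g2", "g3", "g4", "g5"], [5.0, 4.0, 3.0, 2.0, 1.0]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def two_group_matrix(rng):
    """12-sample noise matrix with labels, for signature tests."""
    genes = [f"g{i:03d}" for i in range(50)]
    samples = [f"s{j}" for j in range(12)]
    X = rng.normal(size=(50, 12))
    matrix = pd.DataFrame(X, index=pd.Index(genes, name="gene"), columns=samples)
    labels = pd.Series(
        ["A"] * 6 + ["B"] * 6, index=pd.Index(samples, name="sample"), name="group"
    )
    return matrix, labels
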