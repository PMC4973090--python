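import numpy as np
import pytest

from absdiff_de import CountMatrix, SimConfig, simulate_counts


@pytest.fixture
def tiny_cm() -> CountMatrix:
    """3 genes x 4 samples, two conditions."""
    return CountMatrix(
        counts=np.array([[10, 12, 30, 28], [0, 1, 0, 2], [100, 90, 95, 105]]),
        gene_ids=["g1", "g2", "g3"],
        sample_ids=["a1", "a2", "b1", "b2"],
        design={"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
    )


@pytest.fixture(scope="session")
def null_sim():
    """Seeded null dataset: 2000 genes, n=5 per group, no DE, no outliers."""
    cfg = SimConfig(n_genes=2000, n_per_group=5, n_de_up=0, n_de_down=0, seed=7)
    return simulate_counts(cfg)


@pytest.fixture(scope="session")
def de_sim():
    """Seeded DE dataset with random outliers: 2000 genes, n=10, 100 up + 100 down."""
    cfg = SimConfig(
        n_genes=2000, n_per_group=10, n_de_up=100, n_de_down=100,
        outlier_mode="random", seed=11,
    )
    return simulate_counts(cfg)
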