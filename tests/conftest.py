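import numpy as np
import pandas as pd
import pytest

from oncostrat import ExpressionMatrix
from oncostrat.simulate import SimulationConfig, simulate_cohort, simulate_gene_sets


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def tiny_matrix():
    """3 genes x 4 samples with hand-checkable values."""
    df = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0],
         [5.0, 5.0, 5.0, 5.0],
         [4.0, 3.0, 2.0, 1.0]],
        index=["GA", "GB", "GC"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return ExpressionMatrix(df)


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared by read-only tests."""
    cfg = SimulationConfig(seed=11)
    expr, clinical, truth = simulate_cohort(cfg)
    onco, tsg = simulate_gene_sets(truth, cfg)
    return {"config": cfg, "expr": expr, "clinical": clinical,
            "truth": truth, "onco": onco, "tsg": tsg}


def random_matrix(rng, n_genes=50, n_samples=20):
    genes = [f"G{i:03d}" for i in range(n_genes)]
    samples = [f"s{i}" for i in range(n_samples)]
    return ExpressionMatrix(
        pd.DataFrame(rng.normal(5, 2, size=(n_genes, n_samples)),
                     index=genes, columns=samples)
    )
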