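import numpy as np
import pandas as pd
import pytest

from metaboflux import synthetic


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def table5_planted():
    return synthetic.table5_planted_fc()


@pytest.fixture(scope="session")
def small_experiment(table5_planted):
    """One seeded pattern experiment shared by read-only tests."""
    cfg = synthetic.SyntheticConfig(n_genes=60, seed=11, planted_fc=table5_planted)
    matrix, design, truth = synthetic.generate_experiment(cfg)
    return cfg, matrix, design, truth


def make_expr(values, genes, samples) -> pd.DataFrame:
    return pd.DataFrame(np.asarray(values, dtype=float), index=genes, columns=samples)
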