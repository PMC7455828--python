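import numpy as np
import pandas as pd
import pytest

from neuralpcos import SimConfig, simulate_expression
from neuralpcos.datatypes import ExpressionMatrix


@pytest.fixture(scope="session")
def small_sim():
    """Small planted-signal study shared by read-only tests."""
    return simulate_expression(
        SimConfig(n_genes=300, n_de=20, effect_logfc=2.0, n_case=10, n_control=10, seed=7)
    )


@pytest.fixture(scope="session")
def screened_sim():
    """Full-size planted-signal study with its DEG screen, for selection tests."""
    from neuralpcos import filter_degs, moderated_t

    sim = simulate_expression(SimConfig(n_genes=2000, n_de=50, effect_logfc=2.0, seed=1))
    table = filter_degs(moderated_t(sim.matrix))
    return sim, table


def make_matrix(values, classes, batches=None, scale="log2"):
    """Tiny ExpressionMatrix from a plain array."""
    values = np.asarray(values, dtype=float)
    g, n = values.shape
    genes = [f"g{i}" for i in range(g)]
    samples = [f"s{i}" for i in range(n)]
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        classes=pd.Series(classes, index=samples),
        batches=pd.Series(batches if batches is not None else ["b1"] * n, index=samples),
        scale=scale,
    )
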