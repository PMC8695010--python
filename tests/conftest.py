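import numpy as np
import pandas as pd
import pytest

from dysmod import ExpressionMatrix, SimulationConfig


def make_matrix(values, n_case, n_control, gene_prefix="G"):
    """Wrap a raw array into an ExpressionMatrix with case-first samples."""
    values = np.asarray(values, dtype=float)
    genes = [f"{gene_prefix}{i:04d}" for i in range(1, values.shape[0] + 1)]
    samples = [f"case{i}" for i in range(n_case)] + [f"ctrl{i}" for i in range(n_control)]
    groups = pd.Series(["case"] * n_case + ["control"] * n_control, index=samples)
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), groups)


@pytest.fixture
def small_config():
    """Fast five-module configuration used by unit-level recovery tests."""
    return SimulationConfig(
        n_genes=600,
        n_case=50,
        n_control=50,
        module_sizes=(120, 100, 80, 60, 40),
        n_regulators=4,
        n_terms=4,
        term_size=30,
        seed=7,
    )
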