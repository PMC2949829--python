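import warnings

import numpy as np
import pandas as pd
import pytest

from dheascreen.pipeline import preprocess_tables
from dheascreen.preprocess import ExpressionMatrix
from dheascreen.simulate import SimConfig, generate_experiment

warnings.filterwarnings("ignore", message="All-NaN slice encountered")


def make_matrix(values: np.ndarray, genes=None, samples=None,
                stage="centered", gene_map=None) -> ExpressionMatrix:
    """Build an ExpressionMatrix straight from an array (test helper)."""
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i + 1}" for i in range(values.shape[0])]
    samples = samples or [f"s{j + 1}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=genes, columns=samples)
    gm = None
    if gene_map is not None:
        gm = pd.Series(gene_map, index=df.index)
    return ExpressionMatrix(values=df, stage=stage, gene_map=gm)


@pytest.fixture(scope="session")
def small_experiment():
    cfg = SimConfig(n_genes=600, n_affected_im=30, n_affected_po=20,
                    n_affected_shared=10, seed=42)
    tables, samples, truth = generate_experiment(cfg)
    return cfg, tables, samples, truth


@pytest.fixture(scope="session")
def small_matrix(small_experiment):
    _, tables, samples, _ = small_experiment
    matrix, qc = preprocess_tables(tables, floor=130.0)
    return matrix, samples, qc
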