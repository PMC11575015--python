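import numpy as np
import pytest

from bfh.pseudobulk import CellData, PseudoBulkTable
from bfh.simulate import SourceParams, generate_source


@pytest.fixture
def rng():
    return np.random.default_rng(20240620)


@pytest.fixture
def small_cells():
    """Two subjects, five cells, three genes, hand-checkable weights."""
    counts = np.array(
        [
            [10, 0, 3, 1, 2],
            [0, 0, 5, 5, 5],
            [1, 1, 0, 0, 0],
        ],
        dtype=float,
    )
    return CellData(
        counts=counts,
        gene_names=["TGFB1", "COL1A1", "MT-CO1"],
        subject_id=np.array(["a", "a", "b", "b", "b"]),
        group={"a": 0, "b": 1},
        weight=np.array([0.8, 0.2, 1.0, 1.0, 1.0]),
    )


@pytest.fixture
def sim_pseudobulk(rng):
    """12 subjects x 30 genes with a known group effect on the first 5 genes."""
    n, n_genes = 12, 30
    group = np.repeat([0.0, 1.0], n // 2)
    x2 = rng.uniform(0.1, 1.0, n)
    beta1 = np.zeros(n_genes)
    beta1[:5] = 1.5
    noise = rng.standard_normal((n, n_genes)) * 0.5
    Y = 2.0 + np.outer(group, beta1) - 0.4 * x2[:, None] + noise
    Y -= Y.min() - 0.1  # keep expression non-negative
    return PseudoBulkTable(
        subjects=[f"s{i}" for i in range(n)],
        gene_names=[f"g{j}" for j in range(n_genes)],
        Y=Y,
        X1=group,
        X2=x2,
        n_cells=np.full(n, 100),
    )


@pytest.fixture(scope="session")
def benchmark_source():
    """Reduced-scale source population shared by the simulation tests."""
    params = SourceParams(n_genes=2000, n_subjects=25, cells_per_subject=300)
    return generate_source(params, seed=11)
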