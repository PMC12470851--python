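import numpy as np
import pandas as pd
import pytest

from dirtnorm.io import CountMatrix, SampleDesign
from dirtnorm.simulate import SimConfig, simulate_counts


def make_design(n_c=2, n_t=2, n_vc=0, n_vt=0):
    rows = []
    for i in range(1, n_c + 1):
        rows.append((f"C{i}", "control", "discovery", i))
    for i in range(1, n_t + 1):
        rows.append((f"T{i}", "treated", "discovery", i))
    for i in range(1, n_vc + 1):
        rows.append((f"C{n_c + i}", "control", "validation", i))
    for i in range(1, n_vt + 1):
        rows.append((f"T{n_t + i}", "treated", "validation", i))
    return SampleDesign(pd.DataFrame(
        rows, columns=["sample_id", "condition", "cohort", "pair_index"]))


def make_cm(values, genes=None, samples=None):
    arr = np.asarray(values)
    genes = genes or [f"g{i}" for i in range(1, arr.shape[0] + 1)]
    samples = samples or [f"s{i}" for i in range(1, arr.shape[1] + 1)]
    return CountMatrix(pd.DataFrame(arr, index=genes, columns=samples))


@pytest.fixture
def design_5v5():
    return make_design(5, 5)


@pytest.fixture
def design_full():
    return make_design(5, 5, 4, 4)


@pytest.fixture(scope="session")
def small_sim():
    """50 genes, 10 modules of 4, 5v5 + 4v4, 3 planted DEGs: the shared
    small end-to-end dataset."""
    cfg = SimConfig(n_genes=50, n_modules=10, module_size=4,
                    n_planted_degs=3, batch_gene_fraction=0.08,
                    base_abundance_meanlog=7.0, base_abundance_sdlog=0.8,
                    seed=1234)
    return simulate_counts(cfg)


@pytest.fixture(scope="session")
def recovery_sim():
    """The default recovery scenario (shared across tests; read-only)."""
    return simulate_counts(SimConfig())
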