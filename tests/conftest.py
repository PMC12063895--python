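import numpy as np
import pandas as pd
import pytest

from florascore import synth


@pytest.fixture(scope="session")
def small_panel():
    """500 individuals x 40 SNPs in 8-SNP LD blocks (latent rho 0.5)."""
    return synth.simulate_genotypes(500, 40, block_size=8, rho=0.5, seed=7)


@pytest.fixture(scope="session")
def _nb_cells_base():
    rng = np.random.default_rng(11)
    genes = [f"g{i:03d}" for i in range(200)]
    spec = synth.CellPopSpec(
        cell_types=["A", "B"],
        n_cells_per_type={"A": 150, "B": 150},
        genes=genes,
        base_means=np.exp(rng.normal(0.5, 1.0, 200)),
    )
    return synth.simulate_cells(spec, seed=13)


@pytest.fixture
def nb_cells(_nb_cells_base):
    """Two-type NB count matrix, fresh copy per test."""
    return _nb_cells_base.copy()
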