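import numpy as np
import pandas as pd
import pytest

from sccismr.instruments import LDMatrix
from sccismr.synthetic_data import SimConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def identity_ld():
    def make(variant_ids):
        return LDMatrix(list(variant_ids), np.eye(len(variant_ids)))

    return make


@pytest.fixture
def pairs_frame():
    """Harmonized-pair frame factory."""

    def make(bx, by, sex=0.05, sey=0.02, nx=982, ny=50_000, variant_ids=None):
        bx = np.asarray(bx, dtype=float)
        by = np.asarray(by, dtype=float)
        k = len(bx)
        return pd.DataFrame(
            {
                "variant_id": variant_ids or [f"v{i}" for i in range(k)],
                "bx": bx,
                "sex": np.broadcast_to(sex, k).astype(float),
                "by": by,
                "sey": np.broadcast_to(sey, k).astype(float),
                "px": 1e-8,
                "py": 1e-4,
                "nx": nx,
                "ny": ny,
                "eaf": 0.3,
            }
        )

    return make


@pytest.fixture(scope="session")
def small_dataset():
    """A small but complete simulated dataset shared across tests."""
    cfg = SimConfig(
        n_genes=30,
        n_cell_types=3,
        variants_per_region=60,
        causal_gene_fraction=0.2,
        alpha_spec=("fixed", 0.3),
        seed=77,
    )
    return simulate_dataset(cfg, include_bulk=True)
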