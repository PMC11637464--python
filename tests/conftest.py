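import numpy as np
import pandas as pd
import pytest

from plexscreen import synthdata as sd


@pytest.fixture(scope="session")
def small_screen():
    """A small full screen simulation shared across tests."""
    wells = sd.screen_design(
        n_treatments=5,
        cells_per_well=100,
        planted_hits={"drug_000": {10.0: 3.0, 1.0: 1.5}},
    )
    cfg = sd.SimConfig(
        wells=wells,
        n_genes=150,
        n_cell_types=5,
        markers_per_type=6,
        mean_umis_per_cell=1500,
        marker_fold=12,
        seed=11,
    )
    return sd.simulate_screen(cfg)


@pytest.fixture(scope="session")
def linear_trajectory():
    """Linear-latent trajectory: latent time t, PCs smooth in t plus noise."""
    rng = np.random.default_rng(42)
    n = 1000
    t = np.sort(rng.uniform(0, 30, n))
    pcs = np.column_stack(
        [t, 5.0 * np.sin(t / 6.0), 0.5 * t]
    ) + rng.normal(0, 0.5, (n, 3))
    ids = pd.Index([f"c{i}" for i in range(n)], name="cell_id")
    return t, pcs, ids
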