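import numpy as np
import pandas as pd
import pytest

from phosphonet import quant
from phosphonet.core import SampleDesign
from phosphonet.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def cohort():
    """One default synthetic cohort shared by read-only tests."""
    return simulate_cohort(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def log2_matrix(cohort):
    table, sites, prots, design, _, _ = cohort
    centered = quant.center_normalize(sites)
    corrected = quant.protein_correct(centered, quant.center_normalize(prots), table)
    return quant.log2_transform(corrected)


@pytest.fixture
def toy_design():
    return SampleDesign(
        {"a1": "A", "a2": "A", "a3": "A", "b1": "B", "b2": "B", "b3": "B"},
        group_order=["A", "B"],
    )


@pytest.fixture
def toy_site_table():
    return pd.DataFrame(
        {
            "site_id": ["P1_S10", "P1_T20", "P2_S5"],
            "protein_id": ["P1", "P1", "P2"],
            "residue": ["S", "T", "S"],
            "position": [10, 20, 5],
        }
    )


def random_matrix(rng: np.random.Generator, n_rows=20, n_cols=8, missing_rate=0.15):
    vals = 2.0 ** rng.normal(20, 2, (n_rows, n_cols))
    mask = rng.random(vals.shape) < missing_rate
    # keep at least one present value per row
    mask[np.arange(n_rows), rng.integers(0, n_cols, n_rows)] = False
    vals = np.where(mask, np.nan, vals)
    return pd.DataFrame(
        vals,
        index=[f"S{i}" for i in range(n_rows)],
        columns=[f"c{j}" for j in range(n_cols)],
    )
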