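import numpy as np
import pandas as pd
import pytest

from irapass.io import ClinicalTable, ExpressionTable, PduiTable
from irapass.simulate import SimulationConfig, simulate_cohort


@pytest.fixture
def tiny_pdui() -> PduiTable:
    """3 events x 4 samples, one missing value."""
    data = pd.DataFrame(
        {
            "s1": [0.2, 0.8, 0.5],
            "s2": [0.4, 0.6, 0.5],
            "s3": [np.nan, 0.7, 0.5],
            "s4": [0.3, 0.9, 0.5],
        },
        index=["AIM2|chr1|159062567", "BAX|chr19|48960961", "GENEC|chr2|100"],
    )
    return PduiTable(data)


@pytest.fixture
def small_cohort():
    """A reduced synthetic cohort used across recovery tests."""
    cfg = SimulationConfig(
        seed=11, n_events=300, n_genes=400, n_diff_events=20,
        n_factors=30, n_active_factors=4, n_regulated_per_factor=10,
        hub_factor_targets=30, n_pathways=10, pathway_size=(10, 20),
        n_immune_coupled=8,
    )
    return simulate_cohort(cfg)


@pytest.fixture
def two_group_labels():
    def make(n_a: int, n_b: int) -> pd.Series:
        idx = [f"s{i}" for i in range(n_a + n_b)]
        return pd.Series(["A"] * n_a + ["B"] * n_b, index=idx)

    return make
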