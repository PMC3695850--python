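import numpy as np
import pandas as pd
import pytest

import cepanel as cp


@pytest.fixture(scope="session")
def default_sim():
    """One default-scenario study (n=200, MAR missingness) with truth."""
    return cp.simulate_scenario(cp.default_scenario(200), 42)


@pytest.fixture(scope="session")
def complete_ds(default_sim):
    return default_sim.complete


@pytest.fixture(scope="session")
def observed_ds(default_sim):
    """The observed (missingness-applied) dataset, observed-group subset."""
    ds = default_sim.data
    return ds.subset(np.flatnonzero(~np.isnan(ds.group)))


@pytest.fixture
def toy_panel():
    """Four patients, five measurement points, complete, hand-checkable."""
    eff = np.array([
        [1.0, 0.8, 0.6, 0.5, 0.4],
        [1.2, 1.1, 1.0, 0.9, 0.8],
        [0.5, 0.5, 0.5, 0.5, 0.5],
        [2.0, 1.5, 1.0, 0.5, 0.0],
    ])
    cost = np.array([
        [735.0, 689.0, 185.0, 186.0],
        [800.0, 700.0, 0.0, 250.0],
        [500.0, 0.0, 0.0, 0.0],
        [900.0, 850.0, 300.0, 100.0],
    ])
    cov = pd.DataFrame({
        "age": [30.0, 40.0, 35.0, 28.0],
        "sex": ["f", "m", "f", "f"],
    })
    return cp.PanelDataset(
        patient_ids=np.array([1, 2, 3, 4]),
        nominal_times=np.array([0.0, 3.0, 7.0, 9.0, 12.0]),
        effectiveness=eff,
        interval_costs=cost,
        group_score=np.array([3.9, 4.0, np.nan, 5.2]),
        group=np.full(4, np.nan),
        covariates=cov,
    )
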