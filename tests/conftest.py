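import numpy as np
import pytest

import fsva


@pytest.fixture(scope="session")
def scenario1_data():
    """One scenario-1 database/new-sample pair with no confounding."""
    return fsva.simulate_dataset(1, 0.0, n_db=100, n_new=100, m=1000, seed=42)


@pytest.fixture(scope="session")
def scenario1_fit(scenario1_data):
    ds = scenario1_data
    S = fsva.build_design(ds.outcome_db.astype(str))
    fit = fsva.irwsva_fit(ds.X_db, S, n_sv=1)
    return ds, S, fit


@pytest.fixture(scope="session")
def scenario1_model(scenario1_fit):
    ds, S, fit = scenario1_fit
    return ds, S, fit, fsva.build_frozen_model(ds.X_db, fit)


def make_expression(values, prefix="g"):
    values = np.asarray(values, dtype=float)
    return fsva.ExpressionMatrix(
        values,
        [f"{prefix}{i}" for i in range(values.shape[0])],
        [f"s{j}" for j in range(values.shape[1])],
    )
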