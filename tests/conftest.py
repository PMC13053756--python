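import numpy as np
import pandas as pd
import pytest

import epigrn as eg

#: light tree-ensemble settings used throughout the tests to keep fits fast;
#: recorded in every TargetFit they produce.
FAST_HYPER = {"n_estimators": 50}


@pytest.fixture(scope="session")
def small_net():
    """A small ground-truth network shared across tests."""
    spec = eg.SimulationSpec(n_tf=12, n_targets=15, seed=1234)
    return spec, eg.simulate_network(spec)


@pytest.fixture(scope="session")
def small_expr(small_net):
    spec, net = small_net
    expr = eg.simulate_expression(net, n_cells=150, spec=spec)
    return eg.cpm_normalize(expr)


@pytest.fixture(scope="session")
def planted_regression():
    """Expression with one strong planted regulator: Y = 2*TF1 + noise."""
    rng = np.random.default_rng(77)
    n = 300
    X = rng.normal(size=(5, n))
    y = 2.0 * X[0] + rng.normal(0, 0.2, n)
    vals = pd.DataFrame(
        np.vstack([y, X]),
        index=["Y", "TF1", "TF2", "TF3", "TF4", "TF5"],
        columns=[f"c{i}" for i in range(n)],
    )
    vals = vals - vals.to_numpy().min()  # expression must be non-negative
    return eg.ExpressionMatrix(vals, normalized=True)
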