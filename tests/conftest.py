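import numpy as np
import pytest

from hepaflux.synthetic_data import TraceSimParams, simulate_trace
from hepaflux.trace_analysis import evaluate_protocol

SUIT02_TRUTH = {"L": 8.21, "P": 40.49, "Pc": 43.48, "E": 70.33}


@pytest.fixture(scope="session")
def noiseless_trace():
    """SUIT02 trace with no sensor noise and instant equilibration."""
    return simulate_trace(TraceSimParams(noise_sd=0.0, equilibration_tau=0.0, seed=0))


@pytest.fixture(scope="session")
def noiseless_table(noiseless_trace):
    return evaluate_protocol(noiseless_trace, "SUIT02")


def linear_trace_arrays(flux=40.0, o2_start=250.0, duration=600.0, dt=2.0,
                        mass_density=1.0):
    """Closed-form linear-decline trace: slope = -flux*rho/1000 uM/s."""
    t = np.arange(0.0, duration + dt / 2, dt)
    o2 = o2_start - (flux * mass_density / 1000.0) * t
    return t, o2


def exhaustive_hierarchical_aic(table, outcome, scope):
    """Independent model-selection oracle: enumerate every hierarchical subset
    of the scope and return the AIC-minimal one (ties lexicographic)."""
    from itertools import combinations

    from hepaflux.outcome_model import (
        RSS_FLOOR_FRACTION, _design_matrix, _rss, aic_ls, hierarchy_ok,
    )

    y = table[outcome].to_numpy(dtype=float)
    n = len(table)
    floor = RSS_FLOOR_FRACTION * float(np.sum((y - y.mean()) ** 2))
    best = None
    for r in range(len(scope) + 1):
        for sub in combinations(scope, r):
            if not hierarchy_ok(set(sub)):
                continue
            aic = aic_ls(_rss(_design_matrix(table, list(sub)), y), n,
                         len(sub) + 1, floor)
            key = (aic, tuple(sorted(sub)))
            if best is None or key < best[0]:
                best = (key, sub)
    return [t for t in scope if t in best[1]]


def random_regression_dataset(rng, n=120, strong=(0, 1, 2), n_main=5,
                              with_interaction=True):
    """Well-conditioned random dataset: independent Gaussian predictors, a few
    clearly nonzero coefficients (including, when requested, a planted product
    interaction whose parents are both active), unit noise. On such designs
    single-move stepwise search and global subset search agree; heavily
    collinear designs or signals reachable only through multi-move jumps are
    exactly where greedy selection is known to differ from exhaustive search.
    """
    import pandas as pd

    X = rng.standard_normal((n, n_main))
    cols = {f"x{i}": X[:, i] for i in range(n_main)}
    beta = np.zeros(n_main)
    beta[list(strong)] = rng.choice([-1.0, 1.0], size=len(strong)) * rng.uniform(0.8, 1.5, len(strong))
    y = X @ beta + rng.standard_normal(n)
    scope = [f"x{i}" for i in range(n_main)]
    table = pd.DataFrame(cols)
    if with_interaction:
        table["x0:x1"] = table["x0"] * table["x1"]
        scope.append("x0:x1")
        y = y + rng.choice([-1.0, 1.0]) * rng.uniform(0.8, 1.5) * table["x0:x1"].to_numpy()
    table["y"] = y
    return table, scope
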