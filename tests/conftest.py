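import numpy as np
import pandas as pd
import pytest

from ctnorm import CtTable, GroupDesign, SimScenario, simulate_ct_dataset


@pytest.fixture
def small_table():
    """5 samples × (2 reference + 3 target) hand-built Ct table."""
    values = pd.DataFrame(
        {
            "REFA": [20.0, 21.0, 19.5, 20.5, 22.0],
            "REFB": [18.0, 19.0, 17.5, 18.5, 20.0],
            "T1": [25.0, 26.0, 24.5, 25.5, 27.0],
            "T2": [30.0, 30.5, 29.0, 31.0, 32.0],
            "T3": [22.0, np.nan, 21.0, 23.0, 24.0],
        },
        index=[f"S{i}" for i in range(1, 6)],
    )
    roles = pd.Series({"REFA": "reference", "REFB": "reference",
                       "T1": "target", "T2": "target", "T3": "target"})
    groups = pd.Series(["a", "a", "b", "b", "b"], index=values.index)
    return CtTable(values, roles, groups)


def make_linear_table(b, n=60, n_targets=3, sigma=0.3, seed=0,
                      mu_ref=25.0, a=5.0):
    """Targets linear in a single reference with known slope(s)."""
    rng = np.random.default_rng(seed)
    ref = mu_ref + rng.normal(0, 2.0, n)
    b = np.broadcast_to(np.asarray(b, dtype=float), (n_targets,))
    cols = {"REF": ref}
    for j in range(n_targets):
        cols[f"T{j + 1}"] = a + b[j] * ref + rng.normal(0, sigma, n)
    values = pd.DataFrame(cols, index=[f"S{i:03d}" for i in range(n)])
    roles = pd.Series({"REF": "reference",
                       **{f"T{j + 1}": "target" for j in range(n_targets)}})
    return CtTable(values, roles)


@pytest.fixture
def linear_table():
    return make_linear_table(b=[0.5, 0.8, 1.2], seed=11)


@pytest.fixture
def null_shift_dataset():
    """Small null dataset with a reference group shift (bias scenario)."""
    scenario = SimScenario(n1=20, n2=20, b=0.5, delta_ref=2.0, effect=0.0,
                           n_reps=1, seed=7)
    return simulate_ct_dataset(scenario, seed=7)
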