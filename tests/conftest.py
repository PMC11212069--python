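import numpy as np
import pandas as pd
import pytest

import droughtscreen as ds


@pytest.fixture(scope="session")
def trial():
    """One default simulated trial (35 ecotypes x 2 regimes x 5 blocks)."""
    obs, truth = ds.simulate_trial(ds.GeneratorConfig(seed=1))
    return obs, truth


@pytest.fixture(scope="session")
def fixture_means():
    """Combined per-ecotype means of the packaged reference tables."""
    return ds.ecotype_means()


@pytest.fixture()
def toy_obs():
    """Tiny balanced split-plot dataset: 2 regimes x 3 ecotypes x 2 blocks."""
    rng = np.random.default_rng(7)
    rows = []
    for b in (1, 2):
        for r in ("WS", "WD"):
            for e in ("A", "B", "C"):
                rows.append({
                    "ecotype": e, "water_regime": r, "block": b,
                    "trait": "PH",
                    "value": 10 + 2 * b + (3 if r == "WS" else 0)
                    + {"A": 0, "B": 1, "C": 2}[e] + rng.normal(0, 1),
                })
    return pd.DataFrame(rows)
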