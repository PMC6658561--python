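import numpy as np
import pandas as pd
import pytest

from stressprofiler.profiler import DEFAULT_BATTERY


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_table(rng):
    """Small random animal table with i.i.d. continuous battery metrics."""

    def make(n=40, seed=None):
        g = np.random.default_rng(seed) if seed is not None else rng
        data = {"animal_id": [f"A{i:03d}" for i in range(n)]}
        data["prenatal"] = g.choice(["control", "PNS"], size=n)
        data["adult_exposure"] = "trauma"
        for spec in DEFAULT_BATTERY.tests:
            data[spec.column] = g.normal(size=n)
        return pd.DataFrame(data)

    return make


def brute_force_flags(table: pd.DataFrame, percentile=0.2) -> pd.DataFrame:
    """Independent oracle: sort each metric and flag the boundary-inclusive
    ceil(q*n)-rank extreme set."""
    import math

    out = {}
    for spec in DEFAULT_BATTERY.tests:
        vals = table[spec.column].to_numpy(dtype=float)
        order = np.sort(vals)
        k = max(math.ceil(percentile * len(vals)), 1)
        if spec.direction == "low":
            cut = order[k - 1]
            out[spec.name] = vals <= cut
        else:
            cut = order[len(vals) - k]
            out[spec.name] = vals >= cut
    return pd.DataFrame(out, index=table.index)
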