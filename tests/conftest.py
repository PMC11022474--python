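import numpy as np
import pytest
from hypothesis import settings

import dietscore as ds

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def table():
    return ds.default_scoring_table()


@pytest.fixture(scope="session")
def requirements():
    return ds.example_requirement_table()


@pytest.fixture(scope="session")
def toy():
    """Records, group map and hand-computed expectations for 4 persons."""
    return ds.make_toy_fixture()


@pytest.fixture(scope="session")
def small_population():
    """A 400-person two-recall synthetic population with its ground truth."""
    return ds.simulate_population(ds.SimulationParams(n_persons=400, seed=11))


def random_gram_day(rng, table):
    """Random per-group grams spanning all consumption categories."""
    grams = {}
    for g in table.groups:
        top = g.cutoffs[-1] if g.cutoffs else 10.0
        grams[g.name] = float(rng.choice([0.0, rng.uniform(0, 2.0 * top)]))
    return grams


def random_valid_table(rng):
    """A random scoring table satisfying the per-role point-shape invariants."""
    groups = []
    roles = ["healthy"] * 16 + ["unhealthy"] * 7 + ["unhealthy_excess"] * 2
    for i, role in enumerate(roles):
        ncat = int(rng.integers(2, 5)) if role != "unhealthy_excess" else 3
        cutoffs = np.sort(rng.uniform(1, 200, ncat - 1))
        cutoffs = np.unique(np.round(cutoffs, 2))
        ncat = len(cutoffs) + 1
        if role == "healthy":
            pts = np.sort(np.round(rng.uniform(0, 4, ncat), 2))
        elif role == "unhealthy":
            pts = np.sort(np.round(rng.uniform(0, 4, ncat), 2))[::-1]
        else:  # rise to an interior peak, then fall below it
            peak = round(float(rng.uniform(1.0, 3.0)), 2)
            pts = np.array([round(peak * 0.6, 2), peak, round(peak * 0.2, 2)])
        groups.append(ds.GroupSpec(f"g{i}", role, tuple(cutoffs), tuple(pts)))
    return ds.ScoringTable(tuple(groups))
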