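import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from neoconn.io import Connectome
from neoconn.simulate import SimulationConfig, simulate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def random_connectome(rng, n, density=0.5, subject_id="s"):
    """A random valid connectome: symmetric, nonnegative, zero diagonal."""
    iu, ju = np.triu_indices(n, k=1)
    w = np.zeros((n, n))
    present = rng.random(iu.size) < density
    vals = rng.lognormal(1.0, 0.7, iu.size) * present
    w[iu, ju] = vals
    w = w + w.T
    return Connectome(subject_id, w, [f"n{i:02d}" for i in range(n)])


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def triangle():
    w = np.zeros((3, 3))
    for i, j in ((0, 1), (1, 2), (0, 2)):
        w[i, j] = w[j, i] = 1.0
    return Connectome("tri", w, ["a", "b", "c"])


@pytest.fixture
def path3():
    w = np.zeros((3, 3))
    w[0, 1] = w[1, 0] = 1.0
    w[1, 2] = w[2, 1] = 1.0
    return Connectome("path", w, ["a", "b", "c"])


@pytest.fixture
def planted_cp_graph():
    """4 fully interconnected core nodes (weight 3), 6 periphery nodes linked
    only to the core (weight 1), no periphery-periphery edges."""
    n = 10
    w = np.zeros((n, n))
    for i in range(4):
        for j in range(i + 1, 4):
            w[i, j] = w[j, i] = 3.0
    for p in range(4, n):
        for i in range(4):
            w[p, i] = w[i, p] = 1.0
    return Connectome("planted", w, [f"n{i}" for i in range(n)])


#: connected 12-edge ring alternating core (0-5) and periphery (40-45) nodes
PLANTED_RING = (
    (0, 40), (1, 40), (1, 41), (2, 41), (2, 42), (3, 42),
    (3, 43), (4, 43), (4, 44), (5, 44), (5, 45), (0, 45),
)

NBS_COVARIATES = (
    "ga_birth", "sex", "injury_rating", "cognitive_composite", "imd", "pma_scan",
)


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-subject, 30-node cohort for fast end-to-end exercises."""
    cfg = SimulationConfig(n_subjects=12, n_nodes=30, n_core=11, seed=5)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def planted_cohort():
    cfg = SimulationConfig(
        n_subjects=40, seed=314, effect_edges=PLANTED_RING, effect_beta=-4.0
    )
    return simulate_cohort(cfg)


def make_cohort_frame(n, seed=0):
    """A minimal valid cohort table with plausible values."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "subject_id": [f"s{i:03d}" for i in range(n)],
            "ga_birth": rng.normal(38.6, 0.5, n),
            "pma_scan": rng.normal(39.3, 0.5, n),
            "sex": rng.choice(["male", "female"], n),
            "injury_rating": rng.choice(
                ["none_mild", "moderate_severe"], n, p=[0.86, 0.14]
            ),
            "cognitive_composite": rng.normal(93.6, 10.2, n),
            "imd": rng.lognormal(2.9, 0.6, n),
            "corrected_age_followup": rng.normal(22.1, 0.35, n),
            "internalizing_raw": rng.integers(0, 25, n),
            "externalizing_raw": rng.integers(0, 35, n),
        }
    )
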