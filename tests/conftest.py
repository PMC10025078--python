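import numpy as np
import pandas as pd
import pytest

from antscape.simulate import SimulationConfig, generate_env, generate_survey, generate_traits
from antscape.survey import DEFAULT_GROUPS, RecordingGroup, SeifertPlot, SpeciesCatalog


@pytest.fixture
def full_detection_catalog():
    """Single group detected at every level; pseudo-area = searched area/100."""
    g = RecordingGroup("full", 1.0, 1.0, 1.0)
    return SpeciesCatalog({"full": g}, {"a": "full", "b": "full"})


@pytest.fixture
def default_catalog():
    return SpeciesCatalog(
        dict(DEFAULT_GROUPS),
        {"a": "conspicuous", "b": "intermediate", "c": "cryptic"},
    )


@pytest.fixture
def standard_plot():
    return SeifertPlot("p1", "s1", 64.0, 400.0, 900.0,
                       counts={"a": (1, 2, 1), "b": (2, 3, 0), "c": (1, 0, 0)})


@pytest.fixture(scope="session")
def synthetic_bundle():
    """Default-scale synthetic survey shared across tests (seeded)."""
    cfg = SimulationConfig(env_effect_sd=0.3)
    env = generate_env(cfg, seed=11)
    traits = generate_traits(cfg, seed=12)
    plots, catalog, truth = generate_survey(env, traits, cfg, seed=13)
    return {"config": cfg, "env": env, "traits": traits, "plots": plots,
            "catalog": catalog, "truth": truth}


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def simulate_nb_counts(rng, n, m, mu, theta):
    """Null NB count matrix as a sites x species DataFrame."""
    Y = rng.negative_binomial(theta, theta / (theta + mu), size=(n, m))
    return pd.DataFrame(Y, columns=[f"sp{j}" for j in range(m)])
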