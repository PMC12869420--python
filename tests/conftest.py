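import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

from enggnn import (
    ScenarioSpec,
    SimulationConfig,
    TrainingConfig,
    fit_enggnn,
    run_scenario,
    simulate_dataset,
    summarize_replicates,
)


@pytest.fixture(scope="session")
def toy_sim():
    """Small simulated dataset shared by model-level tests (p=30, n=300)."""
    return simulate_dataset(SimulationConfig(p=30, n=300, pt=0.2, seed=7))


@pytest.fixture(scope="session")
def toy_split(toy_sim):
    from sklearn.model_selection import train_test_split

    idx_tr, idx_te = train_test_split(
        np.arange(toy_sim.data.n),
        test_size=0.2,
        stratify=toy_sim.data.y,
        random_state=7,
    )
    return toy_sim.data.subset(idx_tr), toy_sim.data.subset(idx_te)


@pytest.fixture(scope="session")
def toy_enggnn(toy_sim, toy_split):
    train, _ = toy_split
    return fit_enggnn(train, toy_sim.graph, train_config=TrainingConfig(seed=7))


@pytest.fixture(scope="session")
def toy_benchmark():
    """Five-replicate toy benchmark (n=1000, p=100, pt=0.2) shared across
    the directional classification and feature-selection checks."""
    spec = ScenarioSpec(
        pn=0.1,
        pt=0.2,
        n=1000,
        replicates=5,
        models=("enggnn", "dfn", "boosted_trees"),
        base_seed=0,
    )
    per_rep = run_scenario(spec)
    return per_rep, summarize_replicates(per_rep)
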