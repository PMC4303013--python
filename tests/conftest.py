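"""Shared fixtures: tiny analytic models and a seeded enzyme chain."""

import numpy as np
import pytest

from identestim import Dataset, ErrorModel, KineticModel, make_chain_pathway


@pytest.fixture
def linear_growth_model():
    """Single state with dC/dt = rate_k (so C(t) = C0 + rate_k·t)."""
    return KineticModel(
        state_names=("Y",),
        parameters={"rate_k": 3.0},
        rate_laws={"r": lambda c, p: p["rate_k"]},
        stoichiometry={"r": {"Y": 1}},
        initial_conditions={"Y": 0.0},
    )


@pytest.fixture
def decay_model():
    """Single state dC/dt = −μC via the dilution term only."""
    return KineticModel(
        state_names=("C",),
        parameters={},
        rate_laws={},
        stoichiometry={},
        initial_conditions={"C": 1.0},
        dilution_rate=0.1,
    )


@pytest.fixture(scope="session")
def mm_chain():
    """3-enzyme Michaelis-Menten chain with fixed seed (model, truth)."""
    return make_chain_pathway(3, "michaelis_menten", seed=42)


@pytest.fixture(scope="session")
def chain_dataset(mm_chain):
    """Noise-free observations of the chain at a coarse grid."""
    from identestim import simulate

    model, truth = mm_chain
    times = np.geomspace(1.0, 100.0, 8)
    traj = simulate(model, truth, times)
    records = [
        (float(t), s, float(traj.at[t, s])) for t in traj.index for s in model.state_names
    ]
    return Dataset.from_records(records, ErrorModel(a=0.1, b=1e-5))
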