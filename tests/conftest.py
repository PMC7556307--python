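import numpy as np
import pytest

from ionoflux.contextualization import apply_growth_context
from ionoflux.model_io import MetabolicModel, Metabolite, Reaction
from ionoflux.pathway_extension import build_pathway_spec, extend_model
from ionoflux.synthetic_data import ToyModelConfig, build_toy_model


@pytest.fixture(scope="session")
def toy_config():
    return ToyModelConfig()


@pytest.fixture(scope="session")
def toy_model(toy_config):
    return build_toy_model(toy_config)


@pytest.fixture(scope="session")
def pathway_spec():
    return build_pathway_spec()


@pytest.fixture(scope="session")
def full_spec():
    return build_pathway_spec(allow_single_cleavage=True, allow_c27_sink=True)


@pytest.fixture(scope="session")
def extended_model(toy_model, pathway_spec):
    """Pathway-extended, growth-contextualized toy model (double cleavage only)."""
    return apply_growth_context(extend_model(toy_model, pathway_spec), ngam=0.7)


@pytest.fixture(scope="session")
def extended_model_single(toy_model, full_spec):
    """Extension including the single-cleavage route and the C27 sink."""
    return apply_growth_context(extend_model(toy_model, full_spec), ngam=0.7)


def linear_chain_model(uptake=10.0, internal_ub=1000.0) -> MetabolicModel:
    """A_ex -> A -> B -> B_ex bottleneck chain used across LP tests."""
    m = MetabolicModel()
    m.add_metabolite(Metabolite("A", formula={"C": 1}))
    m.add_metabolite(Metabolite("B", formula={"C": 1}))
    m.add_reaction(Reaction("EX_A", {"A": -1}, -uptake, 0, "exchange"))
    m.add_reaction(Reaction("A2B", {"A": -1, "B": 1}, 0, internal_ub))
    m.add_reaction(Reaction("EX_B", {"B": -1}, 0, 1000.0, "exchange"))
    m.objective_reaction = "EX_B"
    return m


def random_toy_lp(rng: np.random.Generator, max_reactions: int = 8):
    """A random small stoichiometric LP instance (model + numpy arrays)."""
    n = int(rng.integers(3, max_reactions + 1))
    m_rows = int(rng.integers(1, max(2, n - 1)))
    while True:
        S = rng.integers(-2, 3, size=(m_rows, n)).astype(float)
        S[rng.random(S.shape) < 0.4] = 0.0
        if np.all(np.any(S != 0, axis=0)):  # every reaction touches something
            break
    lb = np.round(rng.uniform(-5, 0, size=n), 1)
    ub = np.round(rng.uniform(0, 5, size=n), 1)
    force = rng.random(n) < 0.15  # occasionally force nonzero flux
    lb[force] = np.round(rng.uniform(0.1, 1.0, force.sum()), 1)
    ub[force] = lb[force] + np.round(rng.uniform(0.0, 2.0, force.sum()), 1)

    model = MetabolicModel()
    for i in range(m_rows):
        model.add_metabolite(Metabolite(f"M{i}"))
    for j in range(n):
        stoich = {f"M{i}": S[i, j] for i in range(m_rows) if S[i, j] != 0}
        model.add_reaction(Reaction(f"R{j}", stoich, lb[j], ub[j]))
    objective = f"R{int(rng.integers(0, n))}"
    return model, S, lb, ub, objective
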