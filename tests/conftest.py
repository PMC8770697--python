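"""Shared fixtures: tiny hand-built networks and the seeded toys."""

from __future__ import annotations

import numpy as np
import pytest

from fluxspan.model_core import MetabolicModel, Metabolite, Reaction
from fluxspan.synthetic_data import ToySpec, toy_host, toy_microbe


def build_model(mets, rxns, objective=None, model_id="toy"):
    """Compact model builder: mets is a list of ids, rxns a list of
    (id, stoich, lb, ub[, kind]) tuples."""
    m = MetabolicModel(id=model_id)
    for mid in mets:
        m.add_metabolite(Metabolite(mid))
    for spec in rxns:
        rid, stoich, lb, ub = spec[:4]
        kind = spec[4] if len(spec) > 4 else (
            "exchange" if rid.startswith("EX_")
            else "demand" if rid.startswith("DM_")
            else "sink" if rid.startswith("SK_")
            else "internal"
        )
        m.add_reaction(Reaction(id=rid, stoichiometry=dict(stoich),
                                lb=lb, ub=ub, kind=kind))
    m.objective = dict(objective or {})
    return m


@pytest.fixture
def chain_model():
    """EX_A (uptake <= 10) -> R1: A->B -> EX_B; optimum 10, unique."""
    return build_model(
        ["A[e]", "B[e]"],
        [("EX_A[e]", {"A[e]": -1}, -10, 0),
         ("R1", {"A[e]": -1, "B[e]": 1}, 0, 1000),
         ("EX_B[e]", {"B[e]": -1}, 0, 1000)],
        {"EX_B[e]": 1.0},
    )


@pytest.fixture
def branch_model():
    """A splits to B (objective) or C; at 90% optimality one unit may divert."""
    return build_model(
        ["A[e]", "B[e]", "C[e]"],
        [("EX_A[e]", {"A[e]": -1}, -10, 0),
         ("R1", {"A[e]": -1, "B[e]": 1}, 0, 1000),
         ("R2", {"A[e]": -1, "C[e]": 1}, 0, 1000),
         ("EX_B[e]", {"B[e]": -1}, 0, 1000),
         ("EX_C[e]", {"C[e]": -1}, 0, 1000)],
        {"EX_B[e]": 1.0},
    )


@pytest.fixture
def parallel_model():
    """Two identical routes carrying a total of 10."""
    return build_model(
        ["A[e]", "A[c]", "B[c]", "B[e]"],
        [("EX_A[e]", {"A[e]": -1}, -10, 0),
         ("T_A", {"A[e]": -1, "A[c]": 1}, 0, 1000),
         ("P1", {"A[c]": -1, "B[c]": 1}, 0, 1000),
         ("P2", {"A[c]": -1, "B[c]": 1}, 0, 1000),
         ("T_B", {"B[c]": -1, "B[e]": 1}, 0, 1000),
         ("EX_B[e]", {"B[e]": -1}, 0, 1000)],
        {"EX_B[e]": 1.0},
    )


@pytest.fixture(scope="session")
def microbe():
    return toy_microbe(ToySpec(seed=0))


@pytest.fixture(scope="session")
def host():
    return toy_host(ToySpec(seed=0))


def random_toy_instance(rng: np.random.Generator, n_rxns: int = 8):
    """A random small flux polytope with finite bounds containing 0,
    returned as a MetabolicModel (for solver-vs-oracle checks)."""
    n_mets = int(rng.integers(2, 5))
    m = MetabolicModel(id="rand")
    for i in range(n_mets):
        m.add_metabolite(Metabolite(f"m{i}[c]"))
    for j in range(n_rxns):
        stoich = {}
        for i in range(n_mets):
            coef = int(rng.integers(-2, 3))
            if coef:
                stoich[f"m{i}[c]"] = float(coef)
        if not stoich:
            stoich[f"m{int(rng.integers(0, n_mets))}[c]"] = 1.0
        lb = float(rng.choice([-10.0, -5.0, 0.0]))
        ub = float(rng.choice([5.0, 10.0]))
        m.add_reaction(Reaction(id=f"r{j}", stoichiometry=stoich, lb=lb, ub=ub))
    weights = rng.integers(-2, 3, size=n_rxns)
    if not weights.any():
        weights[0] = 1
    m.objective = {f"r{j}": float(w) for j, w in enumerate(weights) if w}
    return m
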