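"""Shared fixtures: reference model, miniature model, toy-network builders."""

import pytest

from pdacmet import load_reference_network
from pdacmet.synth import mini_network


@pytest.fixture(scope="session")
def reference_model():
    return load_reference_network()


@pytest.fixture()
def mini_model():
    return mini_network()


@pytest.fixture(scope="session")
def ic1(reference_model):
    """Validated initial condition #1 (the baseline steady state)."""
    return dict(reference_model.meta["validated_initial_conditions"]["IC1"])


@pytest.fixture(scope="session")
def ic2(reference_model):
    return dict(reference_model.meta["validated_initial_conditions"]["IC2"])


def toy_config(metabolites, reactions, fixed=None, boundary=None, growth=None,
               panel=None):
    """Assemble a toy network configuration dict for tests.

    ``metabolites`` maps id -> initial concentration; simulation-protocol
    species (GLCx/GLNx boundaries, ATP/GLC/GLN as fixed stand-ins) are filled
    in automatically when missing so that the simulation engine's growth
    coupling resolves.
    """
    fixed = dict(fixed or {})
    boundary = dict(boundary or {})
    for required in ("ATP", "GLC", "GLN"):
        if required not in metabolites and required not in fixed:
            fixed[required] = 1.0
    boundary.setdefault("GLCx", 35.0)
    boundary.setdefault("GLNx", 6.0)
    return {
        "meta": {
            "name": "toy",
            "growth": growth
            or {"alpha_atp": 0.0, "alpha_glc": 0.0, "alpha_gln": 0.0,
                "alpha_d": 0.0, "k_ap": 1.0, "k_gc": 1.0, "k_gn": 1.0,
                "k_cc": 1e9},
        },
        "fold_change_panel": list(panel or []),
        "metabolites": [
            {"id": k, "compartment": "cytosol", "initial_concentration": v}
            for k, v in metabolites.items()
        ],
        "fixed_species": fixed,
        "boundary_species": boundary,
        "reactions": reactions,
    }


@pytest.fixture()
def two_species_linear_config():
    """Boundary-fed linear chain: GLCx -> A -> B -> (sink), mass action."""
    return toy_config(
        metabolites={"A": 2.0, "B": 1.0},
        reactions=[
            {"id": "IN", "stoichiometry": {"GLCx": -1, "A": 1},
             "rate_law": {"form": "mass_action_irrev",
                          "roles": {"substrates": ["GLCx"]}, "parameters": {}},
             "kinetics": {"vf": 0.01}},
            {"id": "MID", "stoichiometry": {"A": -1, "B": 1},
             "rate_law": {"form": "mass_action_irrev",
                          "roles": {"substrates": ["A"]}, "parameters": {}},
             "kinetics": {"vf": 0.05}},
            {"id": "OUT", "stoichiometry": {"B": -1, "CO2": 1},
             "rate_law": {"form": "mass_action_irrev",
                          "roles": {"substrates": ["B"]}, "parameters": {}},
             "kinetics": {"vf": 0.08}},
        ],
        fixed={"CO2": 1.0},
        panel=["A", "B"],
    )
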