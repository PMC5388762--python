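"""Network loading, validation, rate-law algebra and the assembled RHS."""

import math

import numpy as np
import pytest

from pdacmet.network import (
    NetworkValidationError,
    apply_akt_modulation,
    evaluate_flux,
    load_network,
)

from conftest import toy_config


# ---------------------------------------------------------------------------
# independent direct-substitution oracle for every rate-law form
# ---------------------------------------------------------------------------


def oracle_flux(reaction, conc, akt_level=1.0):
    """Direct substitution of the algebraic rate expressions.

    Written independently of the package's compiled evaluator: plain loops
    over the role lists with the textbook formula for each mechanism.
    """
    law = reaction.rate_law
    p = law.parameters
    roles = law.roles
    c = lambda m: max(conc[m], 0.0)
    subs = roles.get("substrates", [])
    prods = roles.get("products", [])
    kin = reaction.kinetics
    vf = kin.vf * (1.0 - kin.knockdown_alpha)
    if kin.akt_modulated:
        vf *= 0.2 + 0.8 * akt_level
    if kin.equilibrium_constrained:
        vr = vf / kin.veq
    else:
        vr = kin.vr if kin.vr is not None else 0.0

    extra = sum(c(m) / p[f"kb_{m}"] for m in roles.get("binding", []))
    form = law.form
    if form == "mass_action_irrev":
        v = vf * math.prod(c(m) for m in subs)
    elif form == "mass_action_rev":
        v = vf * math.prod(c(m) for m in subs) - vr * math.prod(c(m) for m in prods)
    elif form == "mm_irrev":
        v = vf * math.prod(c(m) / (p[f"km_{m}"] + c(m)) for m in subs)
    elif form == "mm_rev_uniuni":
        s = c(subs[0]) / p[f"km_{subs[0]}"]
        q = c(prods[0]) / p[f"km_{prods[0]}"]
        v = (vf * s - vr * q) / (1 + s + q + extra)
    elif form == "mm_rev_bibi":
        a = c(subs[0]) / p[f"km_{subs[0]}"]
        b = c(subs[1]) / p[f"km_{subs[1]}"]
        pp = c(prods[0]) / p[f"km_{prods[0]}"]
        qq = c(prods[1]) / p[f"km_{prods[1]}"]
        v = (vf * a * b - vr * pp * qq) / ((1 + a + pp) * (1 + b + qq) + extra)
    elif form == "hill":
        m0 = subs[0]
        s = c(m0)
        h = p[f"hill_{m0}"]
        v = vf * s**h / (p[f"k_{m0}"] ** h + s**h)
        for m in subs[1:]:
            v *= c(m) / (p[f"km_{m}"] + c(m))
    elif form == "transport_uni":
        s, q = c(subs[0]), c(prods[0])
        ks, kp = p[f"km_{subs[0]}"], p[f"km_{prods[0]}"]
        v = vf * (s - q / p["keq"]) / (ks * (1 + extra) + s + (ks / kp) * q)
    elif form == "antiport":
        a, b = c(subs[0]), c(subs[1])
        pp, qq = c(prods[0]), c(prods[1])
        ka, kb = p[f"km_{subs[0]}"], p[f"km_{subs[1]}"]
        v = vf * (a * b - pp * qq / p["keq"]) / ((ka + a + pp) * (kb + b + qq) + extra)
    elif form == "rev_mm_keq":
        num_s = math.prod(c(m) / p[f"km_{m}"] for m in subs)
        den_s = math.prod(1 + c(m) / p[f"km_{m}"] for m in subs)
        num_p = math.prod(c(m) for m in prods)
        den_p = math.prod(1 + c(m) / p[f"km_{m}"] for m in prods)
        km_s = math.prod(p[f"km_{m}"] for m in subs)
        v = vf * (num_s - num_p / (p["keq"] * km_s)) / (den_s + den_p - 1 + extra)
    else:
        raise AssertionError(form)
    for m in roles.get("inhibitors", []):
        v /= 1 + c(m) / p[f"ki_{m}"]
    for m in roles.get("activators", []):
        a = c(m) / p[f"ka_{m}"]
        v *= (1 + p[f"beta_{m}"] * a) / (1 + a)
    return v


def baseline_state(model):
    out = {m.id: m.initial_concentration for m in model.metabolites}
    out.update(model.fixed_species)
    out.update(model.boundary_species)
    return out


# ---------------------------------------------------------------------------
# loading & validation
# ---------------------------------------------------------------------------


def test_reference_configuration_counts(reference_model):
    counts = reference_model.conformance()
    assert counts["n_metabolites"] == 46
    assert counts["n_reactions"] == 53
    assert counts["n_velocity_parameters"] == 71
    assert counts["n_total_parameters"] == 372
    assert counts["n_state_equations"] == 47


def test_minimal_toy_config_inventory():
    cfg = toy_config(
        metabolites={"A": 1.0, "B": 0.5},
        reactions=[{
            "id": "R1", "stoichiometry": {"A": -1, "B": 1},
            "rate_law": {"form": "mm_rev_uniuni",
                         "roles": {"substrates": ["A"], "products": ["B"]},
                         "parameters": {"km_A": 0.3, "km_B": 0.7}},
            "kinetics": {"vf": 1.0, "vr": 0.5, "veq": 2.0},
        }],
    )
    model = load_network(cfg)
    inv = model.parameter_inventory()
    assert inv == {"R1.Vf": 1.0, "R1.Vr": 0.5, "R1.Veq": 2.0,
                   "R1.km_A": 0.3, "R1.km_B": 0.7}


def test_validation_collects_every_violation():
    cfg = toy_config(
        metabolites={"A": 1.0},
        reactions=[
            {"id": "R1", "stoichiometry": {"A": -1, "Z": 1},
             "rate_law": {"form": "mm_irrev", "roles": {"substrates": ["A"]},
                          "parameters": {"km_A": -1.0}},
             "kinetics": {"vf": 1.0}},
            {"id": "R1", "stoichiometry": {"A": -1},
             "rate_law": {"form": "frobnicate", "roles": {}, "parameters": {}},
             "kinetics": {"vf": 1.0}},
        ],
    )
    with pytest.raises(NetworkValidationError) as err:
        load_network(cfg)
    text = str(err.value)
    assert "R1" in text and "km_A" in text        # negative constant, named
    assert "Z" in text                            # undeclared metabolite
    assert "frobnicate" in text                   # unknown form
    assert "duplicate reaction id" in text
    assert len(err.value.errors) >= 4             # all violations, not the first


# ---------------------------------------------------------------------------
# flux evaluation
# ---------------------------------------------------------------------------


def test_irreversible_mm_saturates_at_vf(reference_model):
    nox = reference_model.reaction("NADPHOX")
    km = nox.rate_law.parameters["km_NADPH"]
    flux = evaluate_flux(nox, {"NADPH": 1000 * km})
    assert flux == pytest.approx(nox.kinetics.vf, rel=1e-3)


def test_reversible_uniuni_vanishes_at_equilibrium(reference_model):
    pgi = reference_model.reaction("PGI")
    p = pgi.rate_law.parameters
    kin = pgi.kinetics
    # product/substrate ratio at which forward and reverse terms cancel
    g6p = 1.0
    f6p = g6p * (kin.vf / p["km_G6P"]) / (kin.vr / p["km_F6P"])
    state = {"G6P": g6p, "F6P": f6p, "6PG": 0.0, "E4P": 0.0, "FBP": 0.0}
    assert evaluate_flux(pgi, state) == pytest.approx(0.0, abs=1e-14)


def test_every_rate_law_matches_direct_substitution_oracle(reference_model):
    """All 53 reference reactions, 10 random states each, 1e-12 relative."""
    rng = np.random.default_rng(42)
    base = baseline_state(reference_model)
    for reaction in reference_model.reactions:
        mets = reaction.rate_law.role_metabolites()
        for _ in range(10):
            state = {m: base[m] * rng.lognormal(0.0, 0.7) for m in mets}
            got = evaluate_flux(reaction, state)
            want = oracle_flux(reaction, state)
            assert got == pytest.approx(want, rel=1e-12, abs=1e-15), reaction.id


def test_zero_vf_kills_forward_flux(reference_model):
    rng = np.random.default_rng(1)
    base = baseline_state(reference_model)
    for rid in ("HK", "GLS", "OXPHOS"):  # irreversible forms
        r = reference_model.copy().reaction(rid)
        r.kinetics.vf = 0.0
        state = {m: base[m] * rng.lognormal(0, 0.5) for m in r.rate_law.role_metabolites()}
        assert evaluate_flux(r, state) == 0.0


def test_missing_and_negative_state_inputs_error(reference_model):
    hk = reference_model.reaction("HK")
    with pytest.raises(KeyError):
        evaluate_flux(hk, {"GLC": 1.0})
    with pytest.raises(ValueError):
        evaluate_flux(hk, {"GLC": -1.0, "ATP": 1.0, "G6P": 0.1, "13BPG": 0.1})


# ---------------------------------------------------------------------------
# AKT modulation
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("akt,expected", [(1.0, 1.0), (0.0, 0.2), (0.5, 0.6)])
def test_akt_modulation_scales_vmax(reference_model, akt, expected):
    before = {r.id: r.kinetics.vf for r in reference_model.reactions}
    modulated = apply_akt_modulation(reference_model, akt)
    for r in modulated.reactions:
        if before[r.id] and r.id in ("GLUT1", "HK", "PFK"):
            assert r.kinetics.vf == pytest.approx(expected * before[r.id])
        else:
            assert r.kinetics.vf == pytest.approx(before[r.id])


def test_akt_level_out_of_range(reference_model):
    with pytest.raises(ValueError):
        apply_akt_modulation(reference_model, 1.5)


# ---------------------------------------------------------------------------
# assembled right-hand side
# ---------------------------------------------------------------------------


def test_closed_cycle_conserves_mass():
    cfg = toy_config(
        metabolites={"A": 2.0, "B": 1.0},
        reactions=[
            {"id": "F", "stoichiometry": {"A": -1, "B": 1},
             "rate_law": {"form": "mass_action_irrev",
                          "roles": {"substrates": ["A"]}, "parameters": {}},
             "kinetics": {"vf": 0.3}},
            {"id": "R", "stoichiometry": {"B": -1, "A": 1},
             "rate_law": {"form": "mass_action_irrev",
                          "roles": {"substrates": ["B"]}, "parameters": {}},
             "kinetics": {"vf": 0.7}},
        ],
    )
    model = load_network(cfg)
    rhs = model.build_rhs()
    index = model.species_index()
    rng = np.random.default_rng(2)
    for _ in range(20):
        y = np.zeros(len(index))
        y[index["A"]], y[index["B"]] = rng.uniform(0, 5, size=2)
        y[index["ATP"]] = y[index["GLC"]] = y[index["GLN"]] = 1.0
        dy = rhs(0.0, y)
        assert dy[index["A"]] + dy[index["B"]] == pytest.approx(0.0, abs=1e-15)


def test_fixed_species_have_zero_derivative(reference_model):
    rhs = reference_model.build_rhs()
    index = reference_model.species_index()
    rng = np.random.default_rng(3)
    y = np.empty(len(index))
    base = baseline_state(reference_model)
    for name, i in index.items():
        y[i] = base[name] * rng.lognormal(0, 0.3)
    dy = rhs(0.0, y)
    for fixed in reference_model.fixed_species:
        assert dy[index[fixed]] == 0.0, fixed
    assert dy[index["mATP"]] == 0.0  # mitochondrial ATP is held constant


def test_rhs_matches_stoichiometric_matrix_oracle(reference_model):
    """dy = S v with S and v assembled independently, 1e-12 relative."""
    rng = np.random.default_rng(4)
    index = reference_model.species_index()
    base = baseline_state(reference_model)
    y = np.array([base[s] for s in reference_model.species_ids()])
    y *= rng.lognormal(0, 0.4, size=y.size)
    state = {s: y[i] for s, i in index.items()}

    # dense matrix-vector oracle built from scratch
    met_ids = reference_model.metabolite_ids
    S = np.zeros((len(met_ids), len(reference_model.reactions)))
    v = np.zeros(len(reference_model.reactions))
    for j, r in enumerate(reference_model.reactions):
        v[j] = oracle_flux(r, state)
        for met, coeff in r.stoichiometry.items():
            if met in met_ids:
                S[met_ids.index(met), j] = coeff
    want = S @ v

    got = reference_model.build_rhs()(0.0, y)[: len(met_ids)]
    np.testing.assert_allclose(got, want, rtol=1e-12, atol=1e-16)


def test_rhs_dimension_mismatch(reference_model):
    rhs = reference_model.build_rhs()
    with pytest.raises(ValueError):
        rhs(0.0, np.ones(5))
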