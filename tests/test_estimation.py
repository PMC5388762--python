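"""WSSR, particle swarm optimization and the two-stage calibration."""

import numpy as np
import pytest

from pdacmet.estimation import (
    FoldChangeDataset,
    GrowthDataset,
    apply_velocity_values,
    fit_growth_parameters,
    fit_reaction_velocities,
    fold_change_prediction,
    free_velocity_names,
    integrate_growth_response,
    particle_swarm_minimize,
    wssr,
)
from pdacmet.growth import GrowthParameters, specific_growth_rate
from pdacmet.synth import make_ground_truth, simulate_training_dataset


# ---------------------------------------------------------------------------
# WSSR
# ---------------------------------------------------------------------------


def test_wssr_perfect_fit_is_zero():
    x = np.array([1.0, 2.0, 3.0])
    assert wssr(x, x) == 0.0


def test_wssr_single_residual():
    assert wssr([3.0], [1.0], [1.0]) == 4.0


def test_wssr_matches_loop_oracle():
    rng = np.random.default_rng(14)
    pred, obs, w = rng.normal(size=14), rng.normal(size=14), rng.uniform(0.5, 2, 14)
    total = 0.0
    for p, o, wi in zip(pred, obs, w):
        total += wi * (p - o) ** 2
    assert wssr(pred, obs, w) == pytest.approx(total, rel=1e-12)


def test_wssr_input_validation():
    with pytest.raises(ValueError):
        wssr([1.0], [1.0, 2.0])
    with pytest.raises(ValueError):
        wssr([1.0], [2.0], [0.0])


# ---------------------------------------------------------------------------
# particle swarm
# ---------------------------------------------------------------------------


def test_pso_finds_quadratic_minimum_and_respects_bounds():
    target = np.array([2.0, 0.5])
    res = particle_swarm_minimize(
        lambda x: float(np.sum((x - target) ** 2)),
        np.array([0.1, 0.1]),
        np.array([10.0, 10.0]),
        n_particles=20,
        n_iterations=80,
        seed=3,
    )
    np.testing.assert_allclose(res.parameters, target, rtol=1e-3)
    assert (res.parameters >= 0.1).all() and (res.parameters <= 10.0).all()
    # best-so-far trace never increases (monotone bookkeeping)
    assert all(a >= b for a, b in zip(res.trace, res.trace[1:]))


def test_pso_raises_when_everything_fails():
    with pytest.raises(RuntimeError):
        particle_swarm_minimize(
            lambda x: 1e12, np.array([0.1]), np.array([1.0]),
            n_particles=4, n_iterations=2, seed=0,
        )


def test_truth_seeded_swarm_reaches_zero_wssr(mini_model):
    """Observations generated at the nominal velocities; nominal in the swarm."""
    study = simulate_training_dataset(mini_model, noise_cv=0.0, seed=2)
    fit = fit_reaction_velocities(
        mini_model, study.fold_changes,
        n_particles=5, n_iterations=3, n_runs=1, seed=4, method="LSODA",
    )
    assert fit.wssr < 1e-8
    assert (fit.parameters >= fit.bounds_lower).all()
    assert (fit.parameters <= fit.bounds_upper).all()
    assert fit.parameter_names == free_velocity_names(mini_model)


# ---------------------------------------------------------------------------
# growth stage
# ---------------------------------------------------------------------------


def test_growth_response_closed_form_matches_ode():
    """Constant lambda: the quadrature solution equals the logistic formula."""
    times = np.linspace(0.0, 7200.0, 2001)
    lam, alpha_d, k = 6e-4, 1.5e-4, 40.0
    cells = integrate_growth_response(times, np.full_like(times, lam), alpha_d, k)
    r = lam - alpha_d
    k_eff = k * r / lam
    expected = k_eff / (1 + (k_eff - 1) * np.exp(-r * times))
    np.testing.assert_allclose(cells, expected, rtol=1e-6)


def test_growth_fit_objective_optimality(mini_model):
    """Noise-free data: recovered WSSR <= WSSR at the generating truth."""
    truth, gp_true = make_ground_truth(mini_model, 0.15, seed=21)
    study = simulate_training_dataset(truth, noise_cv=0.0, seed=1)
    gp_fit, res = fit_growth_parameters(truth, study.growth, n_restarts=8, seed=5)
    # evaluate the objective at the truth through the same pipeline
    _, res_at_truth = fit_growth_parameters(
        truth, study.growth, center=gp_true, n_restarts=1, seed=5
    )
    assert res.wssr <= res_at_truth.wssr + 1e-6


def test_growth_ratio_recovery_in_linear_regime():
    """Glucose is the only time-varying nutrient and k_gc >> GLC: individual
    alpha_glc and k_gc may trade off along the linear Monod regime, but the
    ratio alpha_glc/k_gc is data-constrained and must come back within 10%,
    as must lambda at the synthetic end state."""
    from pdacmet.network import load_network
    from pdacmet.simulate import Protocol, simulate
    from conftest import toy_config

    gp_true = GrowthParameters(
        alpha_atp=1e-4, alpha_glc=2e-4, alpha_gln=1.5e-4, alpha_d=1.2e-4,
        k_ap=2.0, k_gc=50.0, k_gn=0.5, k_cc=50.0,
    )
    cfg = toy_config(
        metabolites={"GLC": 10.0},
        reactions=[{
            "id": "GLUT1", "stoichiometry": {"GLCx": -1, "GLC": 1},
            "rate_law": {"form": "transport_uni",
                         "roles": {"substrates": ["GLCx"], "products": ["GLC"]},
                         "parameters": {"km_GLCx": 9.0, "km_GLC": 9.0, "keq": 1.0}},
            "kinetics": {"vf": 1.0},
        }],
        fixed={"ATP": 5.0, "GLN": 4.0},
        growth=gp_true.to_dict(),
    )
    model = load_network(cfg)

    duration = 7200.0
    t_days = np.arange(0, 6, dtype=float)
    curves = []
    for kds in ([], [("GLUT1", 0.85, 0.0)]):
        proto = Protocol.deprivation_after(1440.0, duration=duration, knockdowns=kds)
        traj = simulate(model, proto, growth=gp_true, atol=1e-12)
        c = np.interp(t_days * 1440.0, traj.times, traj.cell_number)
        c[0] = 1.0
        curves.append(c)
    data = GrowthDataset(
        times_days=t_days, control=curves[0], knockdown=curves[1],
        knockdown_reaction="GLUT1", knockdown_alpha=0.85,
        protocol="deprivation",
    )

    gp_fit, _ = fit_growth_parameters(
        model, data, n_restarts=20, seed=6, atol=1e-12
    )
    assert gp_fit.alpha_glc / gp_fit.k_gc == pytest.approx(
        gp_true.alpha_glc / gp_true.k_gc, rel=0.10
    )
    traj = simulate(model, Protocol.complete_media(), growth=gp_true, atol=1e-12)
    state = [traj.concentration(m)[-1] for m in ("ATP", "GLC", "GLN")]
    lam_true = specific_growth_rate(*state, gp_true)
    lam_fit = specific_growth_rate(*state, gp_fit)
    assert lam_fit == pytest.approx(lam_true, rel=0.10)


def test_growth_fit_reproduces_knockdown_ordering(mini_model):
    """Data with the knockdown curve below control at every time: the fitted
    model preserves that ordering at all observation times."""
    study = simulate_training_dataset(mini_model, noise_cv=0.0, seed=8)
    assert (study.growth.knockdown[1:] < study.growth.control[1:]).all()
    gp_fit, _ = fit_growth_parameters(mini_model, study.growth, n_restarts=5, seed=9)
    from pdacmet.estimation import growth_curve_prediction

    ctrl, kd = growth_curve_prediction(mini_model, gp_fit, study.growth)
    assert (kd[1:] <= ctrl[1:]).all()


# ---------------------------------------------------------------------------
# datasets
# ---------------------------------------------------------------------------


def test_fold_change_dataset_round_trip():
    data = FoldChangeDataset(
        panel=["A", "B"], observed=[1.2, 0.4],
        knockdown_reaction="GLS", knockdown_alpha=0.85,
    )
    again = FoldChangeDataset.from_frame(data.to_frame())
    assert again.panel == data.panel
    np.testing.assert_array_equal(again.observed, data.observed)
    assert again.knockdown_reaction == "GLS"


def test_growth_dataset_round_trip_and_validation():
    data = GrowthDataset(
        times_days=[0, 1, 2], control=[1.0, 2.0, 4.0], knockdown=[1.0, 1.5, 2.0],
    )
    again = GrowthDataset.from_frame(data.to_frame())
    np.testing.assert_array_equal(again.control, data.control)
    with pytest.raises(ValueError):
        GrowthDataset(times_days=[0, 1], control=[1.0, -2.0], knockdown=[1.0, 1.0])
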