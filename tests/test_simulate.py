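"""Simulation engine: protocols, knockdowns, fold-changes, flux reversals."""

import numpy as np
import pytest

from pdacmet.network import load_network
from pdacmet.simulate import (
    Protocol,
    Trajectory,
    apply_knockdown,
    baseline_directions,
    compute_fold_change,
    detect_flux_reversals,
    simulate,
)


# ---------------------------------------------------------------------------
# protocols
# ---------------------------------------------------------------------------


def test_protocol_validation():
    with pytest.raises(ValueError):
        Protocol(media_schedule=[(10.0, 35.0, 6.0)])  # must start at t = 0
    with pytest.raises(ValueError):
        Protocol(knockdowns=[("GOT1", 1.5, 0.0)])
    with pytest.raises(ValueError):
        Protocol(duration=100.0, knockdowns=[("GOT1", 0.5, 500.0)])


def test_media_schedule_lookup():
    p = Protocol.deprivation_after(1440.0)
    assert p.media_at(0.0) == (35.0, 6.0)
    assert p.media_at(2000.0) == (0.0, 0.0)
    assert p.breakpoints() == [0.0, 1440.0, 7200.0]


# ---------------------------------------------------------------------------
# knockdowns
# ---------------------------------------------------------------------------


def test_knockdown_scales_forward_velocity(reference_model):
    vf0 = reference_model.reaction("GOT1").kinetics.vf
    kd = apply_knockdown(reference_model, "GOT1", 0.85)
    assert kd.reaction("GOT1").kinetics.effective_vf() == pytest.approx(0.15 * vf0)
    # alpha = 0 leaves the model identical
    null = apply_knockdown(reference_model, "GOT1", 0.0)
    assert null.reaction("GOT1").kinetics.effective_vf() == pytest.approx(vf0)


def test_complete_knockout_zeroes_forward_flux(reference_model):
    from pdacmet.network import evaluate_flux

    kd = apply_knockdown(reference_model, "GLS", 1.0)
    state = {"GLN": 5.0, "GLU": 0.0}
    assert evaluate_flux(kd.reaction("GLS"), state) == 0.0


def test_equilibrium_constrained_vr_tracks_knockdown(reference_model):
    model = reference_model.copy()
    kin = model.reaction("GOT1").kinetics
    kin.equilibrium_constrained = True
    kin.vr = None
    kd = apply_knockdown(model, "GOT1", 0.85)
    k = kd.reaction("GOT1").kinetics
    assert k.effective_vr() == pytest.approx(k.effective_vf() / k.veq)


def test_unknown_reaction_id(reference_model):
    with pytest.raises(KeyError):
        apply_knockdown(reference_model, "NOPE", 0.5)


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------


def test_zero_duration_returns_initial_state(mini_model):
    traj = simulate(mini_model, Protocol.complete_media(duration=0.0))
    assert traj.times.tolist() == [0.0]
    assert traj.cell_number[0] == 1.0
    assert traj.concentration("GLC")[0] == pytest.approx(10.0)


def test_media_switch_honoured(mini_model):
    traj = simulate(mini_model, Protocol.deprivation_after(720.0, duration=1440.0))
    glcx = traj.concentration("GLCx")
    assert glcx[traj.times < 720.0][0] == 35.0
    assert glcx[-1] == 0.0
    # intracellular glutamine drains once the media empties
    assert traj.concentration("GLN")[-1] < 0.2


def test_output_grid_refinement_does_not_change_solution(mini_model):
    coarse = simulate(mini_model, Protocol.complete_media(duration=1440.0), dt_out=360.0)
    fine = simulate(mini_model, Protocol.complete_media(duration=1440.0), dt_out=90.0)
    assert fine.cell_number[-1] == pytest.approx(coarse.cell_number[-1], rel=1e-6)
    assert fine.concentration("ATP")[-1] == pytest.approx(
        coarse.concentration("ATP")[-1], rel=1e-6
    )


def test_cross_integrator_agreement(reference_model, ic1):
    """BDF solution vs an independent fixed-step classical RK4 over 10 min."""
    from pdacmet.growth import GrowthParameters, cell_number_derivative, specific_growth_rate

    model = reference_model
    growth = GrowthParameters.from_dict(model.meta["growth"])
    index = model.species_index()
    n_dyn = len(model.metabolites)
    S = model.stoichiometric_matrix()
    fluxes = model.build_flux_function()

    y_full = np.empty(len(index))
    for name, i in index.items():
        y_full[i] = {**ic1, **model.fixed_species, **model.boundary_species}[name]
    # nudge off the steady state so the comparison exercises real dynamics
    rng = np.random.default_rng(8)
    y_full[:n_dyn] *= rng.uniform(0.9, 1.1, size=n_dyn)

    def rhs(y):
        buffer = y_full.copy()
        buffer[:n_dyn] = y[:n_dyn]
        dy = np.empty(n_dyn + 1)
        dy[:n_dyn] = S @ fluxes(buffer)
        lam = specific_growth_rate(
            max(buffer[index["ATP"]], 0), max(buffer[index["GLC"]], 0),
            max(buffer[index["GLN"]], 0), growth,
        )
        dy[n_dyn] = cell_number_derivative(max(y[n_dyn], 0.0), lam, growth)
        return dy

    # classical fixed-step RK4, h = 1e-3 min over 10 min
    y = np.concatenate([y_full[:n_dyn], [1.0]])
    h = 1e-3
    for _ in range(10_000):
        k1 = rhs(y)
        k2 = rhs(y + 0.5 * h * k1)
        k3 = rhs(y + 0.5 * h * k2)
        k4 = rhs(y + h * k3)
        y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)

    initial = {name: y_full[index[name]] for name in model.metabolite_ids}
    traj = simulate(model, Protocol.complete_media(duration=10.0), initial=initial, dt_out=10.0)
    bdf = np.concatenate([traj.concentrations[-1, :n_dyn], [traj.cell_number[-1]]])
    rel = np.abs(bdf - y) / np.maximum(np.abs(y), 1e-9)
    assert rel.max() < 1e-4


# ---------------------------------------------------------------------------
# fold changes
# ---------------------------------------------------------------------------


def test_fold_change_identity(mini_model):
    traj = simulate(mini_model, Protocol.complete_media(duration=1440.0))
    fc = compute_fold_change(traj, traj, mini_model.fold_change_panel, 1440.0)
    np.testing.assert_allclose(fc.fold_change, 1.0)


def test_null_knockdown_gives_unit_fold_changes(mini_model):
    ctrl = simulate(mini_model, Protocol.complete_media(duration=1440.0))
    null = simulate(
        mini_model, Protocol.complete_media(duration=1440.0, knockdowns=[("GLS", 0.0, 0.0)])
    )
    fc = compute_fold_change(null, ctrl, mini_model.fold_change_panel, 1440.0)
    np.testing.assert_allclose(fc.fold_change, 1.0, rtol=1e-6)


def test_fold_change_pools_compartments(reference_model, ic1):
    traj = simulate(reference_model, Protocol.complete_media(duration=60.0), dt_out=30.0)
    pooled = traj.pool("MAL")
    assert pooled[0] == pytest.approx(ic1["MAL"] + ic1["mMAL"])
    only_mito = traj.pool("SUC")
    assert only_mito[0] == pytest.approx(ic1["mSUC"])


def test_linear_chain_fold_change_matches_closed_form(two_species_linear_config):
    """Mass-action chain: A(t) solvable in closed form under Vf halving."""
    model = load_network(two_species_linear_config)
    k1, k2 = 0.01, 0.05
    glcx, a0 = 35.0, 2.0
    t_obs = 30.0
    ctrl = simulate(model, Protocol.complete_media(duration=t_obs), dt_out=5.0)
    kd = simulate(
        model,
        Protocol.complete_media(duration=t_obs, knockdowns=[("IN", 0.5, 0.0)]),
        dt_out=5.0,
    )
    fc = compute_fold_change(kd, ctrl, ["A"], t_obs)

    def a_of_t(alpha):
        s_inf = k1 * glcx * (1 - alpha) / k2
        return s_inf + (a0 - s_inf) * np.exp(-k2 * t_obs)

    assert fc.fold_change[0] == pytest.approx(a_of_t(0.5) / a_of_t(0.0), rel=1e-6)


def test_fold_change_requires_covered_time(mini_model):
    traj = simulate(mini_model, Protocol.complete_media(duration=100.0))
    with pytest.raises(ValueError):
        compute_fold_change(traj, traj, ["LAC"], 500.0)


# ---------------------------------------------------------------------------
# flux reversals
# ---------------------------------------------------------------------------


def _cosine_trajectory():
    times = np.linspace(0.0, 4 * np.pi, 2001)
    return Trajectory(
        times=times,
        species_ids=["X"],
        concentrations=np.ones((times.size, 1)),
        reaction_ids=["R"],
        fluxes=np.cos(times)[:, None],
        cell_number=np.ones_like(times),
        protocol=Protocol(duration=float(times[-1])),
    )


def test_reversal_intervals_match_analytic_zero_crossings():
    traj = _cosine_trajectory()
    intervals = dict(detect_flux_reversals(traj, {"R": 1}, deadband=1e-9))["R"]
    assert len(intervals) == 2
    for (start, end), (lo, hi) in zip(
        intervals, [(np.pi / 2, 3 * np.pi / 2), (5 * np.pi / 2, 7 * np.pi / 2)]
    ):
        assert start == pytest.approx(lo, abs=0.02)
        assert end == pytest.approx(hi, abs=0.02)


def test_baseline_self_comparison_is_empty(reference_model):
    traj = simulate(reference_model, Protocol.complete_media(duration=1440.0))
    signs = baseline_directions(reference_model)
    assert detect_flux_reversals(traj, signs, deadband=1e-6) == []


def test_reversal_requires_complete_sign_map():
    traj = _cosine_trajectory()
    with pytest.raises(KeyError):
        detect_flux_reversals(traj, {}, deadband=1e-9)


def test_trajectory_exports(mini_model):
    traj = simulate(mini_model, Protocol.complete_media(duration=720.0), dt_out=360.0)
    tidy = traj.to_tidy_frame()
    assert set(tidy.columns) == {"time_min", "variable", "value"}
    assert "cell_number" in set(tidy["variable"])
    fm = traj.flux_matrix_frame()
    assert list(fm.index) == mini_model.reaction_ids
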