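"""Synthetic studies: ground-truth-known stand-ins for the training data.

The calibration measurements this pipeline was designed around (metabolite
fold-changes and growth curves under an enzyme knockdown) are not shipped
with the package, so end-to-end testing uses synthetic studies: a ground
truth model is created by perturbing a reference model's free velocities,
the truth model is simulated under the experimental protocols, and noisy
observations are generated with multiplicative log-normal noise (fold
changes and cell counts are positive, ratio-scaled quantities).

A compact synthetic miniature network (:func:`mini_network`) is also provided
for fast tests and examples; it shares the reference model's interface
(media-driven glucose/glutamine uptake, ATP balance, growth coupling) at a
fraction of the size, and is not a biological reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .estimation import (
    FoldChangeDataset,
    GrowthDataset,
    fold_change_prediction,
    free_velocity_names,
    apply_velocity_values,
)
from .growth import GrowthParameters
from .network import NetworkModel, load_network
from .simulate import Protocol, simulate

__all__ = [
    "SyntheticStudy",
    "make_ground_truth",
    "simulate_training_dataset",
    "mini_network",
]


@dataclass
class SyntheticStudy:
    """A ground-truth model together with the datasets generated from it."""

    truth: NetworkModel
    truth_growth: GrowthParameters
    fold_changes: FoldChangeDataset
    growth: GrowthDataset
    validation_growth: GrowthDataset
    noise_cv: float
    seed: int


def make_ground_truth(
    model: NetworkModel,
    perturbation_scale: float = 0.3,
    seed: int = 0,
    growth_box: float = 2.0,
) -> tuple[NetworkModel, GrowthParameters]:
    """Perturb a reference model into a distinct ground truth.

    Every free velocity is multiplied by an independent log-normal factor
    with log standard deviation ``perturbation_scale``; the seven growth
    parameters are drawn log-uniformly within ``[p/growth_box, p*growth_box]``
    of the packaged values (the carrying capacity stays fixed).
    """
    if perturbation_scale < 0:
        raise ValueError("perturbation scale must be non-negative")
    rng = np.random.default_rng(int(seed))
    truth = model.copy()
    names = free_velocity_names(truth)
    inventory = truth.parameter_inventory()
    nominal = np.array([inventory[n] for n in names])
    factors = np.exp(rng.normal(0.0, perturbation_scale, size=nominal.size))
    apply_velocity_values(truth, names, nominal * factors)
    base = GrowthParameters.from_dict(model.meta["growth"])
    if perturbation_scale == 0:
        gp = base
    else:
        vals = np.array(base.fitted_values())
        lo, hi = np.log(vals / growth_box), np.log(vals * growth_box)
        gp = GrowthParameters.from_fitted(np.exp(rng.uniform(lo, hi)), k_cc=base.k_cc)
    truth.meta["growth"] = gp.to_dict()
    return truth, gp


def simulate_training_dataset(
    truth: NetworkModel,
    noise_cv: float = 0.1,
    seed: int = 0,
    growth: GrowthParameters | None = None,
    days: int = 5,
    t_obs: float = 1440.0,
    deprivation_switch: float = 1440.0,
    rtol: float = 1e-6,
    atol: float = 1e-11,
) -> SyntheticStudy:
    """Generate fold-change and growth observations from a truth model.

    Three datasets are emitted, mirroring the calibration design:

    * panel fold-changes under the reference knockdown at ``t_obs``;
    * daily relative cell numbers over ``days`` in complete media, for
      control and knockdown cultures;
    * a validation growth dataset where complete media is replaced by
      glucose/glutamine-free media after ``deprivation_switch`` minutes.

    Observations are the noise-free model predictions multiplied by
    independent log-normal factors with coefficient of variation
    ``noise_cv`` (``noise_cv = 0`` reproduces the predictions exactly).
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    rng = np.random.default_rng(int(seed))
    if growth is None:
        growth = GrowthParameters.from_dict(truth.meta["growth"])
    kd_ref = truth.meta.get("knockdown_reference", {"reaction": "GOT1", "alpha": 0.85})
    rid, alpha = str(kd_ref["reaction"]), float(kd_ref["alpha"])

    sigma = np.sqrt(np.log1p(noise_cv**2))  # log-sd giving the requested CV

    def noisy(x: np.ndarray) -> np.ndarray:
        if noise_cv == 0:
            return np.asarray(x, dtype=float)
        return np.asarray(x) * np.exp(rng.normal(0.0, sigma, size=np.shape(x)))

    # fold changes
    fc_data = FoldChangeDataset(
        panel=list(truth.fold_change_panel),
        observed=np.ones(len(truth.fold_change_panel)),
        knockdown_reaction=rid,
        knockdown_alpha=alpha,
        observation_time=t_obs,
    )
    fc_pred = fold_change_prediction(truth, fc_data, rtol=rtol, atol=atol)
    fc_data.observed = noisy(fc_pred)

    # growth curves (daily observations; inoculum day 0 is exact by definition)
    duration = days * 1440.0
    t_days = np.arange(0, days + 1, dtype=float)
    solver = dict(rtol=rtol, atol=atol, dt_out=360.0)

    def cells(protocol: Protocol) -> np.ndarray:
        traj = simulate(truth, protocol, growth=growth, **solver)
        out = np.interp(t_days * 1440.0, traj.times, traj.cell_number)
        out[0] = 1.0  # inoculum is exactly 1 by definition
        return out

    ctrl = cells(Protocol.complete_media(duration=duration))
    kd = cells(Protocol.complete_media(duration=duration, knockdowns=[(rid, alpha, 0.0)]))
    growth_data = GrowthDataset(
        times_days=t_days,
        control=np.concatenate([[ctrl[0]], noisy(ctrl[1:])]),
        knockdown=np.concatenate([[kd[0]], noisy(kd[1:])]),
        knockdown_reaction=rid,
        knockdown_alpha=alpha,
    )

    dep_ctrl = cells(Protocol.deprivation_after(deprivation_switch, duration=duration))
    dep_kd = cells(
        Protocol.deprivation_after(
            deprivation_switch, duration=duration, knockdowns=[(rid, alpha, 0.0)]
        )
    )
    validation = GrowthDataset(
        times_days=t_days,
        control=np.concatenate([[dep_ctrl[0]], noisy(dep_ctrl[1:])]),
        knockdown=np.concatenate([[dep_kd[0]], noisy(dep_kd[1:])]),
        knockdown_reaction=rid,
        knockdown_alpha=alpha,
        protocol="deprivation",
        deprivation_switch_min=deprivation_switch,
    )
    return SyntheticStudy(
        truth=truth,
        truth_growth=growth,
        fold_changes=fc_data,
        growth=growth_data,
        validation_growth=validation,
        noise_cv=noise_cv,
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# synthetic miniature network
# ---------------------------------------------------------------------------

_MINI_CONFIG = {
    "meta": {
        "name": "synthetic-mini-network",
        "description": (
            "Synthetic 8-metabolite miniature with lumped glycolysis, "
            "glutaminolysis and oxidation; used for fast tests and examples, "
            "not a biological reconstruction."
        ),
        "growth": {
            "alpha_atp": 4.0e-4, "alpha_glc": 1.0e-4, "alpha_gln": 3.0e-4,
            "alpha_d": 1.5e-4, "k_ap": 2.0, "k_gc": 1.0, "k_gn": 0.5, "k_cc": 50.0,
        },
        "knockdown_reference": {"reaction": "GLS", "alpha": 0.85},
    },
    "fold_change_panel": ["LAC", "GLU", "AKG", "MAL"],
    "metabolites": [
        {"id": "GLC", "compartment": "cytosol", "initial_concentration": 10.0},
        {"id": "ATP", "compartment": "cytosol", "initial_concentration": 5.0},
        {"id": "ADP", "compartment": "cytosol", "initial_concentration": 2.0},
        {"id": "LAC", "compartment": "cytosol", "initial_concentration": 5.0},
        {"id": "GLN", "compartment": "cytosol", "initial_concentration": 4.0},
        {"id": "GLU", "compartment": "cytosol", "initial_concentration": 2.0},
        {"id": "AKG", "compartment": "cytosol", "initial_concentration": 0.5},
        {"id": "MAL", "compartment": "cytosol", "initial_concentration": 1.0},
    ],
    "fixed_species": {"CO2": 1.2},
    "boundary_species": {"GLCx": 35.0, "GLNx": 6.0, "LACx": 1.0},
    "reactions": [
        {"id": "GLUT1", "stoichiometry": {"GLCx": -1, "GLC": 1},
         "rate_law": {"form": "transport_uni",
                      "roles": {"substrates": ["GLCx"], "products": ["GLC"]},
                      "parameters": {"km_GLCx": 9.0, "km_GLC": 9.0, "keq": 1.0}},
         "kinetics": {"vf": 1.1, "akt_modulated": True}},
        {"id": "GLYC", "stoichiometry": {"GLC": -1, "ADP": -2, "ATP": 2, "LAC": 2},
         "rate_law": {"form": "mm_irrev",
                      "roles": {"substrates": ["GLC", "ADP"]},
                      "parameters": {"km_GLC": 0.5, "km_ADP": 1.0}},
         "kinetics": {"vf": 0.78}},
        {"id": "MCT", "stoichiometry": {"LAC": -1, "LACx": 1},
         "rate_law": {"form": "transport_uni",
                      "roles": {"substrates": ["LAC"], "products": ["LACx"]},
                      "parameters": {"km_LAC": 5.0, "km_LACx": 5.0, "keq": 1.0}},
         "kinetics": {"vf": 3.6}},
        {"id": "GLNT", "stoichiometry": {"GLNx": -1, "GLN": 1},
         "rate_law": {"form": "transport_uni",
                      "roles": {"substrates": ["GLNx"], "products": ["GLN"]},
                      "parameters": {"km_GLNx": 1.5, "km_GLN": 4.0, "keq": 1.0}},
         "kinetics": {"vf": 1.35}},
        {"id": "GLS", "stoichiometry": {"GLN": -1, "GLU": 1},
         "rate_law": {"form": "mm_irrev",
                      "roles": {"substrates": ["GLN"], "inhibitors": ["GLU"]},
                      "parameters": {"km_GLN": 4.0, "ki_GLU": 10.0}},
         "kinetics": {"vf": 0.72}},
        {"id": "GDH", "stoichiometry": {"GLU": -1, "AKG": 1},
         "rate_law": {"form": "mm_rev_uniuni",
                      "roles": {"substrates": ["GLU"], "products": ["AKG"]},
                      "parameters": {"km_GLU": 2.0, "km_AKG": 0.5}},
         "kinetics": {"vf": 1.8, "vr": 0.9, "veq": 2.0}},
        {"id": "OX", "stoichiometry": {"AKG": -1, "ADP": -2, "ATP": 2, "MAL": 1},
         "rate_law": {"form": "mm_irrev",
                      "roles": {"substrates": ["AKG", "ADP"]},
                      "parameters": {"km_AKG": 0.5, "km_ADP": 1.0}},
         "kinetics": {"vf": 0.9}},
        {"id": "MALEX", "stoichiometry": {"MAL": -1, "CO2": 1},
         "rate_law": {"form": "mm_irrev",
                      "roles": {"substrates": ["MAL"]},
                      "parameters": {"km_MAL": 1.0}},
         "kinetics": {"vf": 0.6}},
        {"id": "ATPASE", "stoichiometry": {"ATP": -1, "ADP": 1},
         "rate_law": {"form": "mm_irrev",
                      "roles": {"substrates": ["ATP"]},
                      "parameters": {"km_ATP": 2.0}},
         "kinetics": {"vf": 2.24}},
    ],
}


def mini_network() -> NetworkModel:
    """Build the synthetic miniature network (8 metabolites, 9 reactions)."""
    import copy

    return load_network(copy.deepcopy(_MINI_CONFIG))
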