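"""Two-stage model calibration.

Stage one fits the free reaction velocities to metabolite fold-change data
under a reference enzyme knockdown using particle swarm optimization (PSO)
with velocities searched in log space over a 100-fold box either side of
their nominal values.  Stage two fits the seven growth parameters (three
Monod rates + three half-saturation constants + death rate) to paired
control/knockdown growth curves with restarted trust-region least squares,
restarts drawn log-uniformly over a seven-decade box.  Both stages minimize
the weighted sum of squared residuals (WSSR).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .growth import GrowthParameters
from .network import NetworkModel
from .simulate import Protocol, compute_fold_change, simulate

__all__ = [
    "FoldChangeDataset",
    "GrowthDataset",
    "FitResult",
    "wssr",
    "particle_swarm_minimize",
    "fit_reaction_velocities",
    "fit_growth_parameters",
]

#: objective value assigned to failed simulations inside the swarm
PENALTY = 1e12


# ---------------------------------------------------------------------------
# datasets
# ---------------------------------------------------------------------------


@dataclass
class FoldChangeDataset:
    """Observed metabolite fold-changes under an enzyme knockdown."""

    panel: list[str]
    observed: np.ndarray
    knockdown_reaction: str = "GOT1"
    knockdown_alpha: float = 0.85
    uncertainties: np.ndarray | None = None
    observation_time: float = 1440.0

    def __post_init__(self):
        self.observed = np.asarray(self.observed, dtype=float)
        if len(self.panel) != self.observed.size:
            raise ValueError("panel and observed lengths differ")
        if np.any(self.observed <= 0):
            raise ValueError("fold-changes must be positive")

    @property
    def weights(self) -> np.ndarray:
        if self.uncertainties is None:
            return np.ones_like(self.observed)
        return 1.0 / np.asarray(self.uncertainties, dtype=float) ** 2

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"metabolite": self.panel, "fold_change": self.observed})
        if self.uncertainties is not None:
            df["sd"] = self.uncertainties
        df["knockdown_reaction"] = self.knockdown_reaction
        df["knockdown_alpha"] = self.knockdown_alpha
        df["observation_time_min"] = self.observation_time
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FoldChangeDataset":
        return cls(
            panel=list(df["metabolite"]),
            observed=df["fold_change"].to_numpy(),
            knockdown_reaction=str(df["knockdown_reaction"].iloc[0]),
            knockdown_alpha=float(df["knockdown_alpha"].iloc[0]),
            uncertainties=df["sd"].to_numpy() if "sd" in df else None,
            observation_time=float(df.get("observation_time_min", pd.Series([1440.0])).iloc[0]),
        )


@dataclass
class GrowthDataset:
    """Relative cell numbers over time for control and knockdown cultures."""

    times_days: np.ndarray
    control: np.ndarray
    knockdown: np.ndarray
    knockdown_reaction: str = "GOT1"
    knockdown_alpha: float = 0.85
    control_sd: np.ndarray | None = None
    knockdown_sd: np.ndarray | None = None
    protocol: str = "complete"  # or "deprivation"
    deprivation_switch_min: float = 1440.0

    def __post_init__(self):
        self.times_days = np.asarray(self.times_days, dtype=float)
        self.control = np.asarray(self.control, dtype=float)
        self.knockdown = np.asarray(self.knockdown, dtype=float)
        if np.any(np.diff(self.times_days) <= 0) or np.any(self.times_days < 0):
            raise ValueError("times must be non-negative and increasing")
        if np.any(self.control <= 0) or np.any(self.knockdown <= 0):
            raise ValueError("cell numbers must be positive")

    @property
    def times_min(self) -> np.ndarray:
        return self.times_days * 1440.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_days": np.concatenate([self.times_days, self.times_days]),
                "condition": ["control"] * self.times_days.size
                + ["knockdown"] * self.times_days.size,
                "cell_number": np.concatenate([self.control, self.knockdown]),
                "knockdown_reaction": self.knockdown_reaction,
                "knockdown_alpha": self.knockdown_alpha,
                "protocol": self.protocol,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GrowthDataset":
        ctrl = df[df["condition"] == "control"].sort_values("time_days")
        kd = df[df["condition"] == "knockdown"].sort_values("time_days")
        return cls(
            times_days=ctrl["time_days"].to_numpy(),
            control=ctrl["cell_number"].to_numpy(),
            knockdown=kd["cell_number"].to_numpy(),
            knockdown_reaction=str(df["knockdown_reaction"].iloc[0]),
            knockdown_alpha=float(df["knockdown_alpha"].iloc[0]),
            protocol=str(df.get("protocol", pd.Series(["complete"])).iloc[0]),
        )


@dataclass
class FitResult:
    """Outcome of one optimization stage, with provenance."""

    parameter_names: list[str]
    parameters: np.ndarray
    wssr: float
    seed: int
    bounds_lower: np.ndarray
    bounds_upper: np.ndarray
    n_iterations: int
    n_evaluations: int
    trace: list[float] = field(default_factory=list)

    def as_series(self) -> pd.Series:
        return pd.Series(self.parameters, index=self.parameter_names)


# ---------------------------------------------------------------------------
# objective pieces
# ---------------------------------------------------------------------------


def wssr(predicted, observed, weights=None) -> float:
    """Weighted sum of squared residuals, ``sum(w * (pred - obs)^2)``."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise ValueError("predicted and observed shapes differ")
    if weights is None:
        weights = np.ones_like(observed)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != observed.shape:
        raise ValueError("weights shape differs from observations")
    if np.any(weights <= 0):
        raise ValueError("weights must be positive")
    return float(np.sum(weights * (predicted - observed) ** 2))


# ---------------------------------------------------------------------------
# particle swarm optimizer (global-best topology)
# ---------------------------------------------------------------------------


def particle_swarm_minimize(
    func: Callable[[np.ndarray], float],
    lower: np.ndarray,
    upper: np.ndarray,
    n_particles: int = 50,
    n_iterations: int = 2500,
    seed: int = 0,
    inertia: float = 0.7,
    cognitive: float = 1.5,
    social: float = 1.5,
    log_space: bool = True,
    include: Sequence[np.ndarray] = (),
) -> FitResult:
    """Global-best PSO over a box, optionally searched in log10 coordinates.

    ``include`` seeds specific positions into the initial swarm (e.g. the
    nominal parameter vector).  The returned best is the minimum over every
    particle ever evaluated (monotone bookkeeping).
    """
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    rng = np.random.default_rng(int(seed))
    if log_space:
        lo, hi = np.log10(lower), np.log10(upper)
        decode = lambda z: 10.0**z
        encode = lambda x: np.log10(x)
    else:
        lo, hi = lower, upper
        decode = lambda z: z
        encode = lambda x: x
    d = lo.size
    pos = rng.uniform(lo, hi, size=(n_particles, d))
    for k, x in enumerate(include):
        if k < n_particles:
            pos[k] = np.clip(encode(np.asarray(x, dtype=float)), lo, hi)
    vel = rng.uniform(-(hi - lo), hi - lo, size=(n_particles, d)) * 0.1
    pbest = pos.copy()
    pbest_val = np.array([func(decode(p)) for p in pos])
    g = int(np.argmin(pbest_val))
    gbest, gbest_val = pbest[g].copy(), float(pbest_val[g])
    trace = [gbest_val]
    n_eval = n_particles
    for _ in range(n_iterations):
        r1 = rng.random((n_particles, d))
        r2 = rng.random((n_particles, d))
        vel = inertia * vel + cognitive * r1 * (pbest - pos) + social * r2 * (gbest[None, :] - pos)
        pos = np.clip(pos + vel, lo, hi)
        vals = np.array([func(decode(p)) for p in pos])
        n_eval += n_particles
        improved = vals < pbest_val
        pbest[improved] = pos[improved]
        pbest_val[improved] = vals[improved]
        g = int(np.argmin(pbest_val))
        if pbest_val[g] < gbest_val:
            gbest, gbest_val = pbest[g].copy(), float(pbest_val[g])
        trace.append(gbest_val)
    if not np.isfinite(gbest_val) or gbest_val >= PENALTY:
        raise RuntimeError("all particles infeasible: every objective evaluation failed")
    return FitResult(
        parameter_names=[],
        parameters=decode(gbest),
        wssr=gbest_val,
        seed=seed,
        bounds_lower=lower,
        bounds_upper=upper,
        n_iterations=n_iterations,
        n_evaluations=n_eval,
        trace=trace,
    )


# ---------------------------------------------------------------------------
# stage 1: reaction velocities
# ---------------------------------------------------------------------------


def free_velocity_names(model: NetworkModel) -> list[str]:
    names = []
    for r in model.reactions:
        names.append(f"{r.id}.Vf")
        if r.reversible and not r.kinetics.equilibrium_constrained:
            names.append(f"{r.id}.Vr")
    return names


def apply_velocity_values(model: NetworkModel, names: Sequence[str], values: np.ndarray) -> None:
    for name, v in zip(names, values):
        rid, which = name.split(".")
        kin = model.reaction(rid).kinetics
        if which == "Vf":
            kin.vf = float(v)
        else:
            kin.vr = float(v)


def fold_change_prediction(
    model: NetworkModel,
    data: FoldChangeDataset,
    initial: Mapping[str, float] | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    method: str = "BDF",
) -> np.ndarray:
    """Model-predicted panel fold-changes under the dataset's knockdown."""
    t_obs = data.observation_time
    solver = dict(rtol=rtol, atol=atol, dt_out=t_obs / 4, method=method)
    ctrl = simulate(model, Protocol.complete_media(duration=t_obs), initial=initial, **solver)
    kd = simulate(
        model,
        Protocol.complete_media(
            duration=t_obs,
            knockdowns=[(data.knockdown_reaction, data.knockdown_alpha, 0.0)],
        ),
        initial=initial,
        **solver,
    )
    return compute_fold_change(kd, ctrl, data.panel, t_obs).fold_change


def fit_reaction_velocities(
    model: NetworkModel,
    data: FoldChangeDataset,
    initial: Mapping[str, float] | None = None,
    parameter_names: Sequence[str] | None = None,
    span: float = 100.0,
    n_particles: int = 50,
    n_iterations: int = 2500,
    n_runs: int = 2,
    seed: int = 0,
    include_nominal: bool = True,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    method: str = "BDF",
) -> FitResult:
    """PSO fit of the free reaction velocities to fold-change observations.

    Bounds are ``[v/span, v*span]`` around each velocity's nominal value.
    ``n_runs`` independent swarms are launched (different seeds derived from
    ``seed``) and the best run is returned.  Evaluation failures are
    penalized, not fatal.
    """
    names = list(parameter_names or free_velocity_names(model))
    inventory = model.parameter_inventory()
    nominal = np.array([inventory[n] for n in names])
    lower, upper = nominal / span, nominal * span

    def objective(values: np.ndarray) -> float:
        m = model.copy()
        apply_velocity_values(m, names, values)
        try:
            pred = fold_change_prediction(
                m, data, initial=initial, rtol=rtol, atol=atol, method=method
            )
        except Exception:
            return PENALTY
        return wssr(pred, data.observed, data.weights)

    best: FitResult | None = None
    for run in range(n_runs):
        run_seed = int(seed) + 1000 * run
        result = particle_swarm_minimize(
            objective,
            lower,
            upper,
            n_particles=n_particles,
            n_iterations=n_iterations,
            seed=run_seed,
            include=[nominal] if include_nominal else [],
        )
        if best is None or result.wssr < best.wssr:
            best = result
    best.parameter_names = names
    return best


# ---------------------------------------------------------------------------
# stage 2: growth parameters
# ---------------------------------------------------------------------------


def growth_curve_prediction(
    model: NetworkModel,
    growth: GrowthParameters,
    data: GrowthDataset,
    initial: Mapping[str, float] | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray]:
    """Predicted (control, knockdown) relative cell numbers at the data times."""
    duration = float(data.times_min[-1])
    if data.protocol == "deprivation":
        base = lambda kds: Protocol.deprivation_after(
            data.deprivation_switch_min, duration=duration, knockdowns=kds
        )
    else:
        base = lambda kds: Protocol.complete_media(duration=duration, knockdowns=kds)
    solver = dict(rtol=rtol, atol=atol, dt_out=max(duration / 40, 1.0))
    ctrl = simulate(model, base([]), initial=initial, growth=growth, **solver)
    kd = simulate(
        model,
        base([(data.knockdown_reaction, data.knockdown_alpha, 0.0)]),
        initial=initial,
        growth=growth,
        **solver,
    )
    t = data.times_min
    return (
        np.interp(t, ctrl.times, ctrl.cell_number),
        np.interp(t, kd.times, kd.cell_number),
    )


def integrate_growth_response(
    times: np.ndarray, lam: np.ndarray, alpha_d: float, k_cc: float, c0: float = 1.0
) -> np.ndarray:
    """Exact solution of the logistic-with-death equation for a given lambda(t).

    With ``u = 1/C_N`` the cell-number ODE becomes linear,
    ``du/dt = -(lambda - alpha_d) u + lambda / K_CC``, solved here with
    trapezoidal quadrature on the supplied grid.  Because the metabolite ->
    growth coupling is one-way, this evaluates a growth-parameter trial
    against precomputed metabolite trajectories without re-integrating the
    full system.
    """
    g = np.concatenate([[0.0], np.cumsum(0.5 * (lam[1:] + lam[:-1] - 2 * alpha_d) * np.diff(times))])
    g = np.clip(g, -700.0, 700.0)  # keep exp() finite for extreme trial parameters
    with np.errstate(over="ignore", invalid="ignore"):
        w = lam / k_cc * np.exp(g)
        integral = np.concatenate([[0.0], np.cumsum(0.5 * (w[1:] + w[:-1]) * np.diff(times))])
        u = np.exp(-g) * (1.0 / c0 + integral)
        return 1.0 / u


def fit_growth_parameters(
    model: NetworkModel,
    data: GrowthDataset,
    initial: Mapping[str, float] | None = None,
    center: GrowthParameters | None = None,
    decades: float = 7.0,
    n_restarts: int = 100,
    seed: int = 0,
    k_cc: float | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-11,
) -> tuple[GrowthParameters, FitResult]:
    """Restarted least-squares fit of the seven growth parameters.

    A single parameter set must describe both the control and the knockdown
    growth curves; the combined WSSR over both conditions is minimized.
    Restart points are drawn log-uniformly from a box spanning ``decades``
    orders of magnitude centred (in log space) on the reference values; the
    carrying capacity is a fixed configuration constant, not fitted.

    Because the metabolite -> growth coupling is one-way, the metabolite
    trajectories under both protocols are integrated once up front; each
    growth-parameter trial is then evaluated with the exact solution of the
    cell-number equation along those trajectories
    (:func:`integrate_growth_response`).
    """
    if center is None:
        center = GrowthParameters.from_dict(model.meta["growth"])
    if k_cc is None:
        k_cc = center.k_cc
    names = list(GrowthParameters.FITTED)
    center_vals = np.array(center.fitted_values())
    if np.any(center_vals <= 0):
        raise ValueError("growth-parameter centre must be strictly positive")
    half = decades / 2.0
    lo = np.log10(center_vals) - half
    hi = np.log10(center_vals) + half
    obs = np.concatenate([data.control, data.knockdown])
    sd = None
    if data.control_sd is not None and data.knockdown_sd is not None:
        sd = np.concatenate([data.control_sd, data.knockdown_sd])
    w = np.ones_like(obs) if sd is None else 1.0 / sd**2

    # metabolite trajectories are growth-parameter independent: compute once
    duration = float(data.times_min[-1])
    if data.protocol == "deprivation":
        proto = lambda kds: Protocol.deprivation_after(
            data.deprivation_switch_min, duration=duration, knockdowns=kds
        )
    else:
        proto = lambda kds: Protocol.complete_media(duration=duration, knockdowns=kds)
    solver = dict(rtol=rtol, atol=atol, dt_out=max(duration / 240, 1.0))
    nutrient_curves = []
    for kds in ([], [(data.knockdown_reaction, data.knockdown_alpha, 0.0)]):
        traj = simulate(model, proto(kds), initial=initial, growth=center, **solver)
        nutrient_curves.append(
            (
                traj.times,
                np.clip(traj.concentration("ATP"), 0.0, None),
                np.clip(traj.concentration("GLC"), 0.0, None),
                np.clip(traj.concentration("GLN"), 0.0, None),
            )
        )

    def curves_for(gp: GrowthParameters) -> list[np.ndarray]:
        out = []
        for times, atp, glc, gln in nutrient_curves:
            lam = (
                gp.alpha_atp * atp / (gp.k_ap + atp)
                + gp.alpha_glc * glc / (gp.k_gc + glc)
                + gp.alpha_gln * gln / (gp.k_gn + gln)
            )
            cells = integrate_growth_response(times, lam, gp.alpha_d, gp.k_cc)
            out.append(np.interp(data.times_min, times, cells))
        return out

    def residuals(logp: np.ndarray) -> np.ndarray:
        try:
            gp = GrowthParameters.from_fitted(10.0**logp, k_cc=k_cc)
            ctrl, kd = curves_for(gp)
        except Exception:
            return np.full(obs.size, 1e6)
        res = np.sqrt(w) * (np.concatenate([ctrl, kd]) - obs)
        return np.where(np.isfinite(res), res, 1e6)

    rng = np.random.default_rng(int(seed))
    starts = [np.log10(center_vals)]
    starts += [rng.uniform(lo, hi) for _ in range(max(n_restarts - 1, 0))]
    best_x, best_val, n_eval, n_ok = None, np.inf, 0, 0
    for x0 in starts:
        try:
            sol = least_squares(residuals, x0, bounds=(lo, hi), method="trf", xtol=1e-10)
        except Exception:
            continue
        n_eval += sol.nfev
        val = float(np.sum(sol.fun**2))
        if np.isfinite(val) and val < 1e11:
            n_ok += 1
            if val < best_val:
                best_x, best_val = sol.x, val
    if best_x is None or n_ok == 0:
        raise RuntimeError("all growth-fit restarts diverged")
    gp = GrowthParameters.from_fitted(10.0**best_x, k_cc=k_cc)
    fit = FitResult(
        parameter_names=names,
        parameters=10.0**best_x,
        wssr=best_val,
        seed=seed,
        bounds_lower=10.0**lo,
        bounds_upper=10.0**hi,
        n_iterations=len(starts),
        n_evaluations=n_eval,
    )
    return gp, fit
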