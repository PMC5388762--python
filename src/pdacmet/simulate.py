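"""Simulation engine: protocols, trajectories, fold-changes and flux reversals.

Integrates the coupled 47-equation system (46 metabolite ODEs + relative cell
number) under experimental protocols — piecewise-constant media schedules and
enzyme knockdowns — with a stiff implicit solver.  The solver is restarted at
every schedule breakpoint so that media switches and knockdown onsets never
cross an integration step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .growth import GrowthParameters, cell_number_derivative, specific_growth_rate
from .network import NetworkModel

__all__ = [
    "Protocol",
    "Trajectory",
    "FoldChangeResult",
    "IntegrationError",
    "apply_knockdown",
    "simulate",
    "compute_fold_change",
    "detect_flux_reversals",
    "baseline_directions",
    "COMPLETE_MEDIA_GLC",
    "COMPLETE_MEDIA_GLN",
]

#: complete-media nutrient concentrations (mM)
COMPLETE_MEDIA_GLC = 35.0
COMPLETE_MEDIA_GLN = 6.0

#: boundary-species ids controlled by the media schedule
MEDIA_GLC_ID = "GLCx"
MEDIA_GLN_ID = "GLNx"

#: default relative/absolute solver tolerances
RTOL = 1e-8
ATOL = 1e-10

#: states more negative than this trip an integration error (mM)
NEGATIVE_STATE_TOLERANCE = -1e-9


class IntegrationError(RuntimeError):
    """Raised when the stiff solver fails or the state leaves the feasible set."""

    def __init__(self, message: str, t: float | None = None, state: np.ndarray | None = None):
        self.t = t
        self.state = state
        super().__init__(message)


@dataclass
class Protocol:
    """An experimental protocol for one simulation.

    ``media_schedule`` is a list of ``(t_start_min, glc_mM, gln_mM)`` segments
    that must tile ``[0, duration]`` without gaps (first entry at t = 0);
    ``knockdowns`` is a list of ``(reaction_id, alpha, onset_min)``.
    """

    duration: float = 7200.0  # 5 days
    media_schedule: list[tuple[float, float, float]] = field(
        default_factory=lambda: [(0.0, COMPLETE_MEDIA_GLC, COMPLETE_MEDIA_GLN)]
    )
    knockdowns: list[tuple[str, float, float]] = field(default_factory=list)
    akt_level: float = 1.0

    def __post_init__(self):
        if self.duration < 0:
            raise ValueError("duration must be non-negative")
        if not self.media_schedule or self.media_schedule[0][0] != 0.0:
            raise ValueError("media schedule must start at t = 0")
        starts = [s[0] for s in self.media_schedule]
        if sorted(starts) != starts or len(set(starts)) != len(starts):
            raise ValueError("media schedule segments must have strictly increasing start times")
        if any(s[0] > self.duration for s in self.media_schedule):
            raise ValueError("media schedule segment starts beyond protocol duration")
        for rid, alpha, onset in self.knockdowns:
            if not 0.0 <= alpha <= 1.0:
                raise ValueError(f"knockdown alpha for {rid} must lie in [0, 1], got {alpha}")
            if onset < 0 or onset > self.duration:
                raise ValueError(f"knockdown onset for {rid} outside [0, duration]")
        if not 0.0 <= self.akt_level <= 1.0:
            raise ValueError("akt_level must lie in [0, 1]")

    # -- constructors ------------------------------------------------------
    @classmethod
    def complete_media(cls, duration: float = 7200.0, knockdowns=None, akt_level: float = 1.0):
        """Complete media (35 mM glucose, 6 mM glutamine) for ``duration`` minutes."""
        return cls(duration=duration, knockdowns=list(knockdowns or []), akt_level=akt_level)

    @classmethod
    def deprivation_after(
        cls, switch: float = 1440.0, duration: float = 7200.0, knockdowns=None, akt_level: float = 1.0
    ):
        """Complete media until ``switch`` minutes, then glucose/glutamine-free."""
        return cls(
            duration=duration,
            media_schedule=[(0.0, COMPLETE_MEDIA_GLC, COMPLETE_MEDIA_GLN), (switch, 0.0, 0.0)],
            knockdowns=list(knockdowns or []),
            akt_level=akt_level,
        )

    def media_at(self, t: float) -> tuple[float, float]:
        glc, gln = self.media_schedule[0][1], self.media_schedule[0][2]
        for start, g, q in self.media_schedule:
            if t >= start:
                glc, gln = g, q
        return glc, gln

    def breakpoints(self) -> list[float]:
        pts = {0.0, self.duration}
        pts.update(s[0] for s in self.media_schedule)
        pts.update(onset for _, _, onset in self.knockdowns)
        return sorted(p for p in pts if 0.0 <= p <= self.duration)


@dataclass
class Trajectory:
    """Time-indexed concentrations, fluxes and cell number from one protocol run."""

    times: np.ndarray  # min
    species_ids: list[str]
    concentrations: np.ndarray  # (n_times, n_species), mM; includes fixed/boundary
    reaction_ids: list[str]
    fluxes: np.ndarray  # (n_times, n_reactions), mM/min
    cell_number: np.ndarray  # relative
    protocol: Protocol

    def __post_init__(self):
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory times must be strictly increasing")

    def concentration(self, species: str) -> np.ndarray:
        return self.concentrations[:, self.species_ids.index(species)]

    def pool(self, metabolite: str) -> np.ndarray:
        """Compartment-summed pool (cytosolic + mitochondrial duplicate).

        Metabolites present in only one compartment (e.g. mitochondrial
        succinate) resolve to that single pool.
        """
        total = None
        for name in (metabolite, f"m{metabolite}"):
            if name in self.species_ids:
                c = self.concentration(name)
                total = c.copy() if total is None else total + c
        if total is None:
            raise KeyError(f"metabolite {metabolite!r} not present in trajectory")
        return total

    def flux(self, reaction: str) -> np.ndarray:
        return self.fluxes[:, self.reaction_ids.index(reaction)]

    def at(self, t: float, values: np.ndarray) -> float:
        return float(np.interp(t, self.times, values))

    def cell_number_at(self, t: float) -> float:
        return self.at(t, self.cell_number)

    # -- exports -----------------------------------------------------------
    def to_tidy_frame(self) -> pd.DataFrame:
        """Tidy (time, variable, value) table of concentrations and cell number."""
        frames = [
            pd.DataFrame(
                {
                    "time_min": np.repeat(self.times, len(self.species_ids)),
                    "variable": np.tile(self.species_ids, len(self.times)),
                    "value": self.concentrations.ravel(),
                }
            ),
            pd.DataFrame(
                {"time_min": self.times, "variable": "cell_number", "value": self.cell_number}
            ),
        ]
        return pd.concat(frames, ignore_index=True)

    def flux_matrix_frame(self) -> pd.DataFrame:
        """Reaction x time flux matrix (signed, mM/min) mirroring a flux heatmap."""
        return pd.DataFrame(self.fluxes.T, index=self.reaction_ids, columns=self.times)


@dataclass
class FoldChangeResult:
    """Knockdown/control concentration ratios for a metabolite panel."""

    panel: list[str]
    fold_change: np.ndarray
    observation_time: float
    pooled: bool = True

    def as_series(self) -> pd.Series:
        return pd.Series(self.fold_change, index=self.panel, name="fold_change")


def apply_knockdown(
    model: NetworkModel, reaction_ids: str | Sequence[str], alpha: float
) -> NetworkModel:
    """Return a copy with ``Vf -> Vf * (1 - alpha)`` for each target reaction.

    Equilibrium-constrained reverse velocities follow automatically
    (``Vr = Vf_eff / Veq``); independent reverse velocities are untouched.
    Re-applying the same knockdown overwrites rather than compounds.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"knockdown alpha must lie in [0, 1], got {alpha}")
    if isinstance(reaction_ids, str):
        reaction_ids = [reaction_ids]
    out = model.copy()
    for rid in reaction_ids:
        out.reaction(rid).kinetics.knockdown_alpha = alpha
    return out


def _segment_model(model: NetworkModel, protocol: Protocol, t: float) -> NetworkModel:
    active = [(rid, a) for rid, a, onset in protocol.knockdowns if onset <= t]
    if not active:
        return model
    out = model.copy()
    for rid, a in active:
        out.reaction(rid).kinetics.knockdown_alpha = a
    return out


def simulate(
    model: NetworkModel,
    protocol: Protocol,
    initial: Mapping[str, float] | None = None,
    growth: GrowthParameters | None = None,
    c0: float = 1.0,
    dt_out: float = 20.0,
    method: str = "BDF",
    rtol: float = RTOL,
    atol: float = ATOL,
) -> Trajectory:
    """Integrate the coupled metabolite + cell-number system under a protocol.

    Parameters
    ----------
    initial
        Concentration map (mM) for the dynamic metabolites; defaults to the
        baseline initial concentrations stored in the configuration.  Partial
        maps override the defaults entry-wise.
    growth
        Growth parameters; when omitted, the cell-number equation still runs
        with the model's packaged defaults (``model.meta['growth']``).
    dt_out
        Output grid spacing (min).  Solver accuracy is controlled by
        ``rtol``/``atol``, not by the output grid.

    Returns
    -------
    Trajectory
        Concentrations of every species (dynamic, fixed, boundary), all
        reaction fluxes and the relative cell number on the output grid.
    """
    if growth is None:
        if "growth" not in model.meta:
            raise ValueError("no growth parameters supplied and none packaged with the model")
        growth = GrowthParameters.from_dict(model.meta["growth"])

    species = model.species_ids()
    n_dyn = len(model.metabolites)
    index = model.species_index()

    y_full = np.empty(len(species))
    for i, m in enumerate(model.metabolites):
        y_full[i] = m.initial_concentration
    for s, v in model.fixed_species.items():
        y_full[index[s]] = v
    for s, v in model.boundary_species.items():
        y_full[index[s]] = v
    if initial:
        unknown = [k for k in initial if k not in index]
        if unknown:
            raise KeyError(f"initial condition names unknown species {unknown}")
        for k, v in initial.items():
            if v < 0:
                raise ValueError(f"negative initial concentration for {k}")
            y_full[index[k]] = v

    i_atp, i_glc, i_gln = index["ATP"], index["GLC"], index["GLN"]
    S = model.stoichiometric_matrix()

    # Jacobian sparsity of the 47-state system (BDF groups FD columns by it)
    spars = np.zeros((n_dyn + 1, n_dyn + 1), dtype=bool)
    spars[:n_dyn, :n_dyn] = model.rhs_sparsity()
    growth_inputs = [i for i in (i_atp, i_glc, i_gln) if i < n_dyn]
    spars[n_dyn, growth_inputs + [n_dyn]] = True

    breakpoints = protocol.breakpoints()
    if protocol.duration == 0.0:
        flux_fn = model.build_flux_function(protocol.akt_level)
        v0 = flux_fn(y_full)
        return Trajectory(
            times=np.array([0.0]),
            species_ids=species,
            concentrations=y_full[None, :].copy(),
            reaction_ids=model.reaction_ids,
            fluxes=v0[None, :],
            cell_number=np.array([c0]),
            protocol=protocol,
        )

    times_out: list[np.ndarray] = []
    conc_out: list[np.ndarray] = []
    flux_out: list[np.ndarray] = []
    cell_out: list[np.ndarray] = []

    y = np.concatenate([y_full[:n_dyn], [c0]])
    buffer = y_full.copy()

    for t0, t1 in zip(breakpoints[:-1], breakpoints[1:]):
        seg_model = _segment_model(model, protocol, t0)
        flux_fn = seg_model.build_flux_function(protocol.akt_level)
        glc_x, gln_x = protocol.media_at(t0)
        buffer[index[MEDIA_GLC_ID]] = glc_x
        buffer[index[MEDIA_GLN_ID]] = gln_x

        def rhs(t, state, _flux_fn=flux_fn):
            buffer[:n_dyn] = state[:n_dyn]
            dy = np.empty(n_dyn + 1)
            dy[:n_dyn] = S @ _flux_fn(buffer)
            lam = specific_growth_rate(
                max(buffer[i_atp], 0.0), max(buffer[i_glc], 0.0), max(buffer[i_gln], 0.0), growth
            )
            dy[n_dyn] = cell_number_derivative(max(state[n_dyn], 0.0), lam, growth)
            return dy

        n_pts = max(int(round((t1 - t0) / dt_out)), 1)
        t_eval = np.linspace(t0, t1, n_pts + 1)
        options = {"jac_sparsity": spars} if method in ("BDF", "Radau") else {}
        sol = solve_ivp(
            rhs,
            (t0, t1),
            y,
            method=method,
            t_eval=t_eval,
            rtol=rtol,
            atol=atol,
            **options,
        )
        if not sol.success:
            raise IntegrationError(
                f"solver failed in segment [{t0}, {t1}] min: {sol.message}", t=t0, state=y
            )
        if sol.y.min() < NEGATIVE_STATE_TOLERANCE:
            i_bad = int(np.unravel_index(np.argmin(sol.y), sol.y.shape)[1])
            raise IntegrationError(
                f"state fell below {NEGATIVE_STATE_TOLERANCE} mM at t = {sol.t[i_bad]:.1f} min",
                t=float(sol.t[i_bad]),
                state=sol.y[:, i_bad],
            )
        # record, dropping the duplicated segment-start point after the first segment
        start = 1 if times_out else 0
        seg_conc = np.empty((sol.t.size, len(species)))
        seg_flux = np.empty((sol.t.size, len(model.reactions)))
        for k in range(sol.t.size):
            buffer[:n_dyn] = sol.y[:n_dyn, k]
            seg_conc[k] = buffer
            seg_flux[k] = flux_fn(buffer)
        times_out.append(sol.t[start:])
        conc_out.append(seg_conc[start:])
        flux_out.append(seg_flux[start:])
        cell_out.append(sol.y[n_dyn, start:])
        y = sol.y[:, -1].copy()

    return Trajectory(
        times=np.concatenate(times_out),
        species_ids=species,
        concentrations=np.concatenate(conc_out),
        reaction_ids=model.reaction_ids,
        fluxes=np.concatenate(flux_out),
        cell_number=np.concatenate(cell_out),
        protocol=protocol,
    )


def compute_fold_change(
    kd: Trajectory,
    ctrl: Trajectory,
    panel: Sequence[str] | None = None,
    t_obs: float = 1440.0,
) -> FoldChangeResult:
    """Knockdown-over-control concentration ratios at the observation time.

    For each panel metabolite the cytosolic and mitochondrial pools are
    summed before taking the ratio, matching how whole-cell metabolomics
    measures total cellular pools.
    """
    if panel is None:
        raise ValueError("a metabolite panel is required")
    for traj in (kd, ctrl):
        if t_obs > traj.times[-1] or t_obs < traj.times[0]:
            raise ValueError(f"observation time {t_obs} outside trajectory range")
    ratios = np.empty(len(panel))
    for i, met in enumerate(panel):
        ctrl_pool = ctrl.at(t_obs, ctrl.pool(met))
        if ctrl_pool <= 0:
            raise ValueError(f"control pool for {met} is non-positive at t = {t_obs}")
        ratios[i] = kd.at(t_obs, kd.pool(met)) / ctrl_pool
    return FoldChangeResult(panel=list(panel), fold_change=ratios, observation_time=t_obs)


def detect_flux_reversals(
    traj: Trajectory,
    baseline_signs: Mapping[str, int],
    deadband: float = 1e-9,
) -> list[tuple[str, list[tuple[float, float]]]]:
    """Intervals where a reaction's flux opposes its baseline direction.

    Fluxes with magnitude below ``deadband`` (mM/min) are ignored to suppress
    numerical sign chatter near zero.  Returns ``(reaction_id, intervals)``
    for every reaction with at least one reversal interval.
    """
    missing = [r for r in traj.reaction_ids if r not in baseline_signs]
    if missing:
        raise KeyError(f"baseline signs missing for reactions {missing}")
    out = []
    for rid in traj.reaction_ids:
        sign = baseline_signs[rid]
        v = traj.flux(rid)
        opposed = (np.sign(v) == -sign) & (np.abs(v) > deadband)
        if not opposed.any():
            continue
        intervals = []
        t = traj.times
        start = None
        for k, flag in enumerate(opposed):
            if flag and start is None:
                start = t[k]
            elif not flag and start is not None:
                intervals.append((float(start), float(t[k - 1])))
                start = None
        if start is not None:
            intervals.append((float(start), float(t[-1])))
        out.append((rid, intervals))
    return out


def baseline_directions(
    model: NetworkModel, initial: Mapping[str, float] | None = None, akt_level: float = 1.0
) -> dict[str, int]:
    """Sign of each reaction's flux at the baseline starting state.

    Evaluated at the model's stored initial concentrations (optionally
    overridden), under complete media.  Zero fluxes inherit the declared
    ``baseline_direction`` from the configuration, or +1.
    """
    index = model.species_index()
    y = np.empty(len(index))
    for i, m in enumerate(model.metabolites):
        y[i] = m.initial_concentration
    for s, v in model.fixed_species.items():
        y[index[s]] = v
    for s, v in model.boundary_species.items():
        y[index[s]] = v
    if initial:
        for k, v in initial.items():
            y[index[k]] = v
    v = model.build_flux_function(akt_level)(y)
    out = {}
    for j, r in enumerate(model.reactions):
        if v[j] > 0:
            out[r.id] = 1
        elif v[j] < 0:
            out[r.id] = -1
        else:
            out[r.id] = r.baseline_direction or 1
    return out
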