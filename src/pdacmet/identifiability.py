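"""Structural identifiability of forward/reverse velocity pairs.

For every reversible reaction with an independently fitted reverse velocity,
the local sensitivity vectors of the knockdown fold-change objective with
respect to Vf and Vr are compared: when the two Jacobian columns are
(anti-)collinear across an ensemble of initial conditions, the data cannot
separate the pair and the reverse velocity is bound to the forward one
through the equilibrium constant, ``Vr = Vf / Veq``.  The procedure is run
in rounds until no new pair exceeds the correlation threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .network import NetworkModel
from .simulate import Protocol, compute_fold_change, simulate

__all__ = [
    "CorrelationReport",
    "pairwise_velocity_correlation",
    "reduce_by_equilibrium",
    "run_identifiability",
]

#: default absolute-cosine threshold above which a (Vf, Vr) pair is declared
#: correlated and reduced through the equilibrium constant
DEFAULT_THRESHOLD = 0.95

#: relative finite-difference step for the velocity perturbations
FD_STEP = 0.05

#: columns with norm below this fraction of the largest column are degenerate
DEGENERATE_NORM = 1e-12


@dataclass
class CorrelationReport:
    """Normalized Vf/Vr correlation scores for one identifiability round."""

    table: pd.DataFrame  # reaction, score, n_ic, degenerate, round
    round_index: int = 1

    def ranked(self) -> pd.DataFrame:
        return self.table.sort_values("score", ascending=False, ignore_index=True)

    def correlated(self, threshold: float = DEFAULT_THRESHOLD) -> list[str]:
        t = self.table
        mask = (~t["degenerate"]) & (t["score"] >= threshold)
        return list(t.loc[mask, "reaction"])


def _objective(model: NetworkModel, initial: Mapping[str, float], protocol_kwargs) -> np.ndarray:
    """Panel fold-change vector (knockdown over control) for one IC."""
    kd_ref = model.meta.get("knockdown_reference", {"reaction": "GOT1", "alpha": 0.85})
    t_obs = float(protocol_kwargs.get("t_obs", 1440.0))
    solver = dict(
        rtol=protocol_kwargs.get("rtol", 1e-6),
        atol=protocol_kwargs.get("atol", 1e-9),
        dt_out=protocol_kwargs.get("dt_out", t_obs / 4),
    )
    ctrl = simulate(model, Protocol.complete_media(duration=t_obs), initial=initial, **solver)
    kd = simulate(
        model,
        Protocol.complete_media(
            duration=t_obs, knockdowns=[(kd_ref["reaction"], float(kd_ref["alpha"]), 0.0)]
        ),
        initial=initial,
        **solver,
    )
    return compute_fold_change(kd, ctrl, model.fold_change_panel, t_obs).fold_change


def pairwise_velocity_correlation(
    model: NetworkModel,
    ic_sets: pd.DataFrame | Sequence[Mapping[str, float]],
    round_index: int = 1,
    **protocol_kwargs,
) -> CorrelationReport:
    """Correlation score of each free (Vf, Vr) pair over an IC ensemble.

    For every initial condition the Jacobian columns
    ``d(fold-change)/d(ln Vf)`` and ``d(fold-change)/d(ln Vr)`` are estimated
    by forward differences; their absolute cosine similarity is averaged over
    the ensemble, giving a score in [0, 1].  Reactions whose sensitivity is
    numerically degenerate for every IC are reported with ``degenerate=True``
    and an undefined (NaN) score rather than a silent zero.
    """
    if isinstance(ic_sets, pd.DataFrame):
        ic_list = [row.to_dict() for _, row in ic_sets.iterrows()]
    else:
        ic_list = [dict(ic) for ic in ic_sets]
    if len(ic_list) < 2:
        raise ValueError("at least two initial-condition sets are required")
    targets = [
        r.id
        for r in model.reactions
        if r.reversible and not r.kinetics.equilibrium_constrained
    ]
    if not targets:
        raise ValueError("model has no reversible reaction with a free reverse velocity")

    cos_sums = {rid: [] for rid in targets}
    for ic in ic_list:
        base = _objective(model, ic, protocol_kwargs)
        cols: dict[str, dict[str, np.ndarray]] = {}
        for rid in targets:
            cols[rid] = {}
            for which in ("vf", "vr"):
                pert = model.copy()
                kin = pert.reaction(rid).kinetics
                setattr(kin, which, getattr(kin, which) * (1.0 + FD_STEP))
                cols[rid][which] = (_objective(pert, ic, protocol_kwargs) - base) / FD_STEP
        scale = max(
            (np.linalg.norm(v) for d in cols.values() for v in d.values()), default=0.0
        )
        for rid in targets:
            a, b = cols[rid]["vf"], cols[rid]["vr"]
            na, nb = np.linalg.norm(a), np.linalg.norm(b)
            if min(na, nb) <= DEGENERATE_NORM * max(scale, 1.0):
                cos_sums[rid].append(np.nan)
            else:
                cos_sums[rid].append(abs(float(a @ b) / (na * nb)))

    rows = []
    for rid in targets:
        vals = np.asarray(cos_sums[rid], dtype=float)
        ok = vals[~np.isnan(vals)]
        rows.append(
            {
                "reaction": rid,
                "score": float(ok.mean()) if ok.size else np.nan,
                "n_ic": int(ok.size),
                "degenerate": ok.size == 0,
                "round": round_index,
            }
        )
    return CorrelationReport(table=pd.DataFrame(rows), round_index=round_index)


def reduce_by_equilibrium(
    model: NetworkModel,
    report: CorrelationReport,
    threshold: float = DEFAULT_THRESHOLD,
) -> tuple[NetworkModel, list[str]]:
    """Bind ``Vr = Vf / Veq`` for every reaction scoring at or above threshold.

    Returns the constrained model copy and the list of newly constrained
    reaction ids.  Constrained reverse velocities are removed from the free
    parameter list and track Vf under any later knockdown or refit.
    """
    if not 0.0 < threshold:
        raise ValueError("threshold must be positive")
    out = model.copy()
    constrained = []
    for rid in report.correlated(threshold):
        kin = out.reaction(rid).kinetics
        if kin.veq is None:
            raise ValueError(f"reaction {rid} lacks an equilibrium constant Veq")
        kin.equilibrium_constrained = True
        kin.vr = None
        constrained.append(rid)
    return out, constrained


def run_identifiability(
    model: NetworkModel,
    ic_sets: pd.DataFrame | Sequence[Mapping[str, float]],
    threshold: float = DEFAULT_THRESHOLD,
    max_rounds: int = 5,
    **protocol_kwargs,
) -> tuple[NetworkModel, list[CorrelationReport]]:
    """Iterate correlation analysis + equilibrium reduction until stable.

    Each round recomputes the correlation scores for the still-free pairs of
    the current (partially constrained) model; the loop stops when a round
    constrains nothing new or when no free pair remains.
    """
    reports: list[CorrelationReport] = []
    current = model
    for round_index in range(1, max_rounds + 1):
        free = [
            r.id
            for r in current.reactions
            if r.reversible and not r.kinetics.equilibrium_constrained
        ]
        if not free:
            break
        report = pairwise_velocity_correlation(
            current, ic_sets, round_index=round_index, **protocol_kwargs
        )
        reports.append(report)
        current, constrained = reduce_by_equilibrium(current, report, threshold)
        if not constrained:
            break
    return current, reports
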