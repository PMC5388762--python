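"""In-silico enzyme-knockdown screens and nutrient-availability grids.

Every screen runs the trained model under the complete-media five-day
protocol and reads out the relative cell number.  Combination screens pair a
target enzyme with the reference knockdown (GOT1 at 85%) and classify the
outcome into three behaviour classes:

* ``A`` — the target alone is weaker than the reference but the combination
  is synergistic (lower than either single knockdown);
* ``B`` — target and reference are comparably effective and the combination
  adds further benefit;
* ``C`` — the target alone is dominant and the combination adds nothing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .network import NetworkModel
from .simulate import Protocol, Trajectory, simulate

__all__ = [
    "ScreenResult",
    "knockdown_dose_response",
    "combination_screen",
    "classify_combination",
    "nutrient_grid",
]

#: default relative tolerance for the behaviour classification
CLASSIFICATION_EPSILON = 0.05

#: default screen endpoint (five days, min)
SCREEN_DURATION = 7200.0

CONDITIONS = ("control", "target", "reference", "combination")


@dataclass
class ScreenResult:
    """Day-indexed relative cell numbers for the four screen conditions."""

    target: str
    reference: str
    alpha: float
    days: np.ndarray
    cell_numbers: dict[str, np.ndarray]  # condition -> day-indexed values
    behavior_class: str = "unclassified"
    epsilon: float = CLASSIFICATION_EPSILON

    def day5(self, condition: str) -> float:
        return float(self.cell_numbers[condition][-1])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cond in CONDITIONS:
            for d, v in zip(self.days, self.cell_numbers[cond]):
                rows.append(
                    {
                        "target": self.target,
                        "condition": cond,
                        "day": d,
                        "cell_number": v,
                        "class": self.behavior_class,
                    }
                )
        return pd.DataFrame(rows)


def _day5_run(
    model: NetworkModel,
    knockdowns,
    initial: Mapping[str, float] | None,
    duration: float,
    rtol: float,
    atol: float,
) -> Trajectory:
    return simulate(
        model,
        Protocol.complete_media(duration=duration, knockdowns=knockdowns),
        initial=initial,
        rtol=rtol,
        atol=atol,
        dt_out=duration / 40 if duration > 0 else 20.0,
    )


def knockdown_dose_response(
    model: NetworkModel,
    reaction_id: str,
    levels: Sequence[float],
    initial: Mapping[str, float] | None = None,
    duration: float = SCREEN_DURATION,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> pd.Series:
    """Day-5 relative cell number as a function of knockdown fraction.

    ``levels`` are knockdown fractions in [0, 1]; level 0 reproduces the
    control run.  Simulation failures propagate as NaN for that level.
    """
    model.reaction(reaction_id)  # raises for unknown ids
    out = {}
    for level in levels:
        if not 0.0 <= level <= 1.0:
            raise ValueError(f"knockdown level {level} outside [0, 1]")
        kds = [(reaction_id, float(level), 0.0)] if level > 0 else []
        try:
            traj = _day5_run(model, kds, initial, duration, rtol, atol)
            out[level] = float(traj.cell_number[-1])
        except Exception:
            out[level] = np.nan
    return pd.Series(out, name=reaction_id).rename_axis("knockdown_level")


def combination_screen(
    model: NetworkModel,
    target: str,
    alpha: float = 0.85,
    reference: str = "GOT1",
    initial: Mapping[str, float] | None = None,
    duration: float = SCREEN_DURATION,
    epsilon: float = CLASSIFICATION_EPSILON,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> ScreenResult:
    """Four-condition screen: control, target, reference, target+reference.

    The same knockdown fraction ``alpha`` is applied to target and reference;
    combining a target with itself is idempotent (the combination equals the
    single knockdown).
    """
    model.reaction(target)
    model.reaction(reference)
    kd_sets = {
        "control": [],
        "target": [(target, alpha, 0.0)],
        "reference": [(reference, alpha, 0.0)],
        "combination": (
            [(target, alpha, 0.0)]
            if target == reference
            else [(target, alpha, 0.0), (reference, alpha, 0.0)]
        ),
    }
    days = None
    curves = {}
    for cond, kds in kd_sets.items():
        traj = _day5_run(model, kds, initial, duration, rtol, atol)
        day_grid = np.arange(0.0, duration / 1440.0 + 1e-9, 1.0)
        curves[cond] = np.interp(day_grid * 1440.0, traj.times, traj.cell_number)
        days = day_grid
    result = ScreenResult(
        target=target,
        reference=reference,
        alpha=alpha,
        days=days,
        cell_numbers=curves,
        epsilon=epsilon,
    )
    result.behavior_class = classify_combination(result, epsilon)
    return result


def classify_combination(result: ScreenResult, epsilon: float = CLASSIFICATION_EPSILON) -> str:
    """Assign the three-class combination behaviour from day-5 cell numbers.

    With ``N_t`` (target alone), ``N_r`` (reference alone) and ``N_c``
    (combination):

    * class A: ``N_t > N_r (1+eps)`` and ``N_c < min(N_t, N_r) (1-eps)``
    * class B: ``|N_t - N_r| <= eps N_r`` and ``N_c < N_r (1-eps)``
    * class C: ``N_t < N_r (1-eps)`` and ``|N_c - N_t| <= eps N_t``
    * otherwise: ``none``
    """
    missing = [c for c in ("target", "reference", "combination") if c not in result.cell_numbers]
    if missing:
        raise ValueError(f"screen result missing conditions {missing}")
    n_t = result.day5("target")
    n_r = result.day5("reference")
    n_c = result.day5("combination")
    if n_t > n_r * (1 + epsilon) and n_c < min(n_t, n_r) * (1 - epsilon):
        return "A"
    if abs(n_t - n_r) <= epsilon * n_r and n_c < n_r * (1 - epsilon):
        return "B"
    if n_t < n_r * (1 - epsilon) and abs(n_c - n_t) <= epsilon * n_t:
        return "C"
    return "none"


def nutrient_grid(
    model: NetworkModel,
    glucose_levels: Sequence[float],
    glutamine_levels: Sequence[float],
    horizon_days: float = 5.0,
    initial: Mapping[str, float] | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> pd.DataFrame:
    """Relative cell number at the horizon over a media-composition grid.

    Rows are glucose levels (mM), columns glutamine levels (mM).  Failed
    grid points propagate as NaN.
    """
    duration = horizon_days * 1440.0
    grid = np.full((len(glucose_levels), len(glutamine_levels)), np.nan)
    for i, glc in enumerate(glucose_levels):
        for j, gln in enumerate(glutamine_levels):
            if glc < 0 or gln < 0:
                raise ValueError("nutrient levels must be non-negative")
            protocol = Protocol(duration=duration, media_schedule=[(0.0, float(glc), float(gln))])
            try:
                traj = simulate(
                    model, protocol, initial=initial, rtol=rtol, atol=atol,
                    dt_out=max(duration / 40, 1.0),
                )
                grid[i, j] = traj.cell_number[-1]
            except Exception:
                pass
    return pd.DataFrame(
        grid,
        index=pd.Index(glucose_levels, name="glucose_mM"),
        columns=pd.Index(glutamine_levels, name="glutamine_mM"),
    )
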