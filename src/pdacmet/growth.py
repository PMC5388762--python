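"""Nutrient-coupled cell growth: logistic proliferation with Monod kinetics.

The relative cell number ``C_N`` obeys

    dC_N/dt = lambda * (1 - C_N / K_CC) * C_N - alpha_d * C_N

with the specific growth rate a sum of three Monod terms on intracellular
ATP, glucose and glutamine:

    lambda = alpha_atp * ATP/(k_ap + ATP)
           + alpha_glc * Glc/(k_gc + Glc)
           + alpha_gln * Gln/(k_gn + Gln)

All rate parameters (alpha_*) are in 1/min; the half-saturation constants
(k_*) are in mM.  The coupling is one-way: metabolite concentrations drive
growth, but cell number does not feed back onto the metabolite balances.
Cell number is relative to the inoculum (C_N(0) = 1).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Mapping

__all__ = ["GrowthParameters", "CellState", "specific_growth_rate", "cell_number_derivative"]


@dataclass
class GrowthParameters:
    """The seven fitted growth/death constants plus the carrying capacity.

    ``k_cc`` (carrying capacity, relative cell units) is a configuration
    constant, not one of the seven parameters exposed to the growth-fitting
    stage (those are the four rates and three half-saturation constants).
    """

    alpha_atp: float  # 1/min
    alpha_glc: float  # 1/min
    alpha_gln: float  # 1/min
    alpha_d: float  # 1/min
    k_ap: float  # mM
    k_gc: float  # mM
    k_gn: float  # mM
    k_cc: float = 50.0  # relative cell number

    #: names of the parameters exposed to the growth-fitting stage
    FITTED = ("alpha_atp", "alpha_glc", "alpha_gln", "alpha_d", "k_ap", "k_gc", "k_gn")

    def __post_init__(self):
        for name in self.FITTED:
            if getattr(self, name) < 0:
                raise ValueError(f"growth parameter {name} must be non-negative")
        if self.k_cc <= 0:
            raise ValueError("carrying capacity k_cc must be positive")

    def fitted_values(self) -> list[float]:
        return [getattr(self, n) for n in self.FITTED]

    @classmethod
    def from_fitted(cls, values, k_cc: float) -> "GrowthParameters":
        return cls(**dict(zip(cls.FITTED, map(float, values))), k_cc=float(k_cc))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "GrowthParameters":
        return cls(**{k: float(v) for k, v in d.items()})


@dataclass
class CellState:
    """Relative cell number (dimensionless, >= 0)."""

    c_n: float = 1.0

    def __post_init__(self):
        if self.c_n < 0:
            raise ValueError("cell number must be non-negative")


def specific_growth_rate(atp: float, glc_in: float, gln_in: float, p: GrowthParameters) -> float:
    """Monod-sum specific growth rate (1/min).

    Monotone non-decreasing in each concentration and bounded by
    ``alpha_atp + alpha_glc + alpha_gln``.
    """
    if min(atp, glc_in, gln_in) < 0:
        raise ValueError("concentrations must be non-negative")
    lam = 0.0
    for alpha, k, c in (
        (p.alpha_atp, p.k_ap, atp),
        (p.alpha_glc, p.k_gc, glc_in),
        (p.alpha_gln, p.k_gn, gln_in),
    ):
        if c > 0:
            lam += alpha * c / (k + c)
        # c == 0 contributes 0 even when k == 0
    return lam


def cell_number_derivative(c: CellState | float, lam: float, p: GrowthParameters) -> float:
    """Time derivative of the relative cell number (1/min)."""
    c_n = c.c_n if isinstance(c, CellState) else float(c)
    if c_n < 0:
        raise ValueError("cell number must be non-negative")
    return lam * (1.0 - c_n / p.k_cc) * c_n - p.alpha_d * c_n
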