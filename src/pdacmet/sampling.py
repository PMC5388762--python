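"""Initial-condition ensembles: Latin hypercube and truncated-Gaussian sampling.

Two designs are used in the calibration workflow:

* Latin hypercube sampling over published concentration bounds, to explore the
  physiologically possible range of starting metabolite levels (each of the
  ``n`` equal-probability strata of every metabolite's range is sampled
  exactly once);
* Gaussian Monte Carlo around a validated baseline, for robustness analysis:
  each metabolite is drawn from a normal with mean equal to the baseline and
  standard deviation one sixth of the mean, truncated at +/-50% of the mean
  (i.e. +/-3 sd).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import qmc, truncnorm

__all__ = [
    "ConcentrationBounds",
    "lhs_initial_conditions",
    "gaussian_initial_conditions",
    "load_reference_bounds",
    "write_ensemble",
]


@dataclass
class ConcentrationBounds:
    """Per-metabolite lower/upper concentration bounds (mM)."""

    lower: dict[str, float]
    upper: dict[str, float]

    def __post_init__(self):
        if set(self.lower) != set(self.upper):
            raise ValueError("lower and upper bounds must cover the same metabolites")
        bad = [m for m in self.lower if not 0 < self.lower[m] <= self.upper[m]]
        if bad:
            raise ValueError(f"bounds must satisfy 0 < lower <= upper; violated for {bad}")

    @property
    def metabolites(self) -> list[str]:
        return list(self.lower)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ConcentrationBounds":
        return cls(
            lower=dict(zip(df.iloc[:, 0], df.iloc[:, 1].astype(float))),
            upper=dict(zip(df.iloc[:, 0], df.iloc[:, 2].astype(float))),
        )


def load_reference_bounds() -> ConcentrationBounds:
    """The packaged initial-condition bounds of the reference model."""
    path = Path(__file__).parent / "data" / "initial_condition_bounds.csv"
    return ConcentrationBounds.from_frame(pd.read_csv(path))


def _mirror_groups(names: Sequence[str]) -> dict[str, str]:
    """Map each mitochondrial duplicate to its cytosolic counterpart.

    Compartment duplicates are assumed to start at the same concentration, so
    they share one sampled value.
    """
    out = {}
    for n in names:
        if n.startswith("m") and n[1:] in names:
            out[n] = n[1:]
    return out


def lhs_initial_conditions(
    bounds: ConcentrationBounds, n: int, seed: int, tie_compartments: bool = True
) -> pd.DataFrame:
    """Latin hypercube sample of ``n`` initial-condition sets.

    For every metabolite the range ``[lower, upper]`` is divided into ``n``
    equal-width strata and each stratum is sampled exactly once (uniformly
    within the stratum).  When ``tie_compartments`` is set, mitochondrial
    duplicates (``mX``) copy the sample of their cytosolic counterpart ``X``.

    Returns
    -------
    DataFrame with one row per sample and one column per metabolite (mM).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    names = bounds.metabolites
    mirror = _mirror_groups(names) if tie_compartments else {}
    primary = [m for m in names if m not in mirror]
    sampler = qmc.LatinHypercube(d=len(primary), seed=int(seed))
    unit = sampler.random(n)
    lo = np.array([bounds.lower[m] for m in primary])
    hi = np.array([bounds.upper[m] for m in primary])
    values = qmc.scale(unit, lo, hi)
    df = pd.DataFrame(values, columns=primary)
    for twin, source in mirror.items():
        df[twin] = df[source]
    return df[names]


def gaussian_initial_conditions(
    baseline: Mapping[str, float],
    n: int,
    seed: int,
    sd_fraction: float = 1.0 / 6.0,
    truncation: float = 0.5,
) -> pd.DataFrame:
    """Truncated-Gaussian Monte Carlo ensemble around a validated baseline.

    Each metabolite is drawn independently from a normal distribution with
    mean equal to its baseline concentration and standard deviation
    ``sd_fraction`` of the mean, truncated to
    ``[(1 - truncation) * mean, (1 + truncation) * mean]`` — with the default
    sd of mean/6 the truncation at +/-50% sits exactly at three standard
    deviations, so virtually no probability mass is clipped.

    ``sd_fraction = 0`` degenerates to copies of the baseline.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    bad = [m for m, v in baseline.items() if v <= 0]
    if bad:
        raise ValueError(f"baseline must be strictly positive; violated for {bad}")
    rng = np.random.default_rng(int(seed))
    names = list(baseline)
    out = np.empty((n, len(names)))
    for j, m in enumerate(names):
        mu = float(baseline[m])
        if sd_fraction == 0.0:
            out[:, j] = mu
            continue
        sd = sd_fraction * mu
        a = (mu * (1 - truncation) - mu) / sd
        b = (mu * (1 + truncation) - mu) / sd
        out[:, j] = truncnorm.rvs(a, b, loc=mu, scale=sd, size=n, random_state=rng)
    return pd.DataFrame(out, columns=names)


def write_ensemble(df: pd.DataFrame, path: str | Path, metadata: Mapping) -> None:
    """Write an ensemble table plus a JSON sidecar with seed/bounds provenance."""
    path = Path(path)
    df.to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(json.dumps(dict(metadata), indent=2, sort_keys=True))
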