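"""Extended Fourier Amplitude Sensitivity Test (eFAST).

Variance-based global sensitivity analysis: each parameter in turn is driven
along a high-frequency search curve while all others oscillate at low
complementary frequencies; the Fourier spectrum of the model output then
decomposes the output variance into the share explained by the parameter
alone (first-order index ``S1``) and by the parameter including all its
interactions (total index ``ST``).  A dummy parameter that the model ignores
is injected automatically as a negative control.

The implementation follows the standard resampled eFAST scheme (random phase
shifts, interference factor ``M``); reaction-velocity bounds default to two
orders of magnitude either side of the nominal value, sampled log-uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .network import NetworkModel
from .simulate import Protocol, compute_fold_change, simulate

__all__ = ["SensitivityResult", "efast_indices", "efast"]

#: name of the injected inert parameter
DUMMY = "_dummy"


@dataclass
class SensitivityResult:
    """First-order and total eFAST indices per (parameter, output) pair."""

    table: pd.DataFrame  # parameter, output, S1, ST
    n_samples: int
    n_resamples: int
    interference: int
    seed: int
    failures: int = 0

    def pivot(self, value: str = "S1") -> pd.DataFrame:
        return self.table.pivot(index="parameter", columns="output", values=value)


def _search_curve(n_params: int, index: int, n_samples: int, m: int, rng) -> np.ndarray:
    """Unit-cube eFAST sample block for one parameter of interest (n_s x p)."""
    omega_max = (n_samples - 1) // (2 * m)
    if omega_max < 2:
        raise ValueError("sample size too small for the interference factor")
    # complementary frequencies spread over [1, omega_max / (2 m)]
    omega_c_max = max(omega_max // (2 * m), 1)
    others = [j for j in range(n_params) if j != index]
    freqs = np.empty(n_params)
    freqs[index] = omega_max
    if others:
        # descending from the top of the complementary band: distinct, mostly
        # coprime frequencies cover the joint space far better than 1, 2, ...
        freqs[others] = omega_c_max - (np.arange(len(others)) % omega_c_max)
    s = (2.0 * np.pi / n_samples) * np.arange(n_samples) - np.pi
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n_params)
    x = 0.5 + np.arcsin(np.sin(freqs[None, :] * s[:, None] + phases[None, :])) / np.pi
    return np.clip(x, 0.0, 1.0)


def _spectrum_indices(y: np.ndarray, omega_max: int, omega_c_max: int, m: int) -> tuple[float, float]:
    n = y.size
    s = (2.0 * np.pi / n) * np.arange(n) - np.pi
    yc = y - y.mean()
    harmonics = np.arange(1, (n - 1) // 2 + 1)
    A = np.array([np.mean(yc * np.cos(w * s)) for w in harmonics])
    B = np.array([np.mean(yc * np.sin(w * s)) for w in harmonics])
    power = A**2 + B**2
    total = power.sum()
    if total <= 0.0:
        return 0.0, 0.0
    main = sum(power[p * omega_max - 1] for p in range(1, m + 1) if p * omega_max - 1 < power.size)
    complementary = power[: omega_max // 2].sum()
    s1 = float(main / total)
    st = float(1.0 - complementary / total)
    return s1, st


def efast_indices(
    func: Callable[[np.ndarray], np.ndarray],
    n_params: int,
    output_names: Sequence[str],
    n_samples: int = 257,
    n_resamples: int = 5,
    interference: int = 4,
    seed: int = 0,
) -> SensitivityResult:
    """Core eFAST estimator on the unit hypercube.

    ``func`` maps a matrix of unit-cube samples (n_s x p) to an output matrix
    (n_s x n_outputs).  Returns per-parameter, per-output S1/ST averaged over
    the phase-shift resamples.  Rows of NaN output are excluded and counted
    as failures.
    """
    rng = np.random.default_rng(int(seed))
    omega_max = (n_samples - 1) // (2 * interference)
    omega_c_max = max(omega_max // (2 * interference), 1)
    n_out = len(output_names)
    s1 = np.zeros((n_params, n_out))
    st = np.zeros((n_params, n_out))
    counts = np.zeros((n_params, n_out))
    failures = 0
    for i in range(n_params):
        for _ in range(n_resamples):
            x = _search_curve(n_params, i, n_samples, interference, rng)
            y = np.asarray(func(x), dtype=float)
            if y.ndim == 1:
                y = y[:, None]
            bad = ~np.isfinite(y)
            if bad.any():
                failures += int(bad.any(axis=1).sum())
                col_mean = np.nanmean(np.where(bad, np.nan, y), axis=0)
                y = np.where(bad, col_mean[None, :], y)
            for k in range(n_out):
                a, b = _spectrum_indices(y[:, k], omega_max, omega_c_max, interference)
                s1[i, k] += a
                st[i, k] += b
                counts[i, k] += 1
    s1 /= np.maximum(counts, 1)
    st /= np.maximum(counts, 1)
    rows = []
    for i in range(n_params):
        for k, out in enumerate(output_names):
            rows.append({"parameter": i, "output": out, "S1": s1[i, k], "ST": st[i, k]})
    return SensitivityResult(
        table=pd.DataFrame(rows),
        n_samples=n_samples,
        n_resamples=n_resamples,
        interference=interference,
        seed=seed,
        failures=failures,
    )


def efast(
    model: NetworkModel,
    parameter_names: Sequence[str] | None = None,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    outputs: Sequence[str] | None = None,
    initial: Mapping[str, float] | None = None,
    span: float = 100.0,
    n_samples: int = 65,
    n_resamples: int = 2,
    interference: int = 4,
    seed: int = 0,
    t_obs: float = 1440.0,
    include_dummy: bool = True,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> SensitivityResult:
    """eFAST indices of panel fold-changes with respect to reaction velocities.

    Parameters default to every free velocity (``RID.Vf`` plus unconstrained
    ``RID.Vr``), sampled log-uniformly over ``[value/span, value*span]``.
    Outputs default to the knockdown fold-changes of the panel metabolites.
    A dummy parameter is appended as an estimator control.  Failed
    simulations are excluded (mean-imputed in the spectrum) and counted.

    The default sample sizes are deliberately small — this analysis costs two
    stiff integrations per sample point; scale ``n_samples``/``n_resamples``
    up for production runs.
    """
    if parameter_names is None:
        parameter_names = []
        for r in model.reactions:
            parameter_names.append(f"{r.id}.Vf")
            if r.reversible and not r.kinetics.equilibrium_constrained:
                parameter_names.append(f"{r.id}.Vr")
    parameter_names = list(parameter_names)
    inventory = model.parameter_inventory()
    if bounds is None:
        bounds = {
            name: (inventory[name] / span, inventory[name] * span) for name in parameter_names
        }
    if outputs is None:
        outputs = list(model.fold_change_panel)
    kd_ref = model.meta.get("knockdown_reference", {"reaction": "GOT1", "alpha": 0.85})

    names = parameter_names + ([DUMMY] if include_dummy else [])
    lo = np.array([bounds[n][0] for n in parameter_names])
    hi = np.array([bounds[n][1] for n in parameter_names])

    def set_params(m: NetworkModel, values: np.ndarray) -> None:
        for name, v in zip(parameter_names, values):
            rid, which = name.split(".")
            kin = m.reaction(rid).kinetics
            if which == "Vf":
                kin.vf = float(v)
            else:
                kin.vr = float(v)

    solver = dict(rtol=rtol, atol=atol, dt_out=t_obs / 4)

    def func(x_unit: np.ndarray) -> np.ndarray:
        out = np.full((x_unit.shape[0], len(outputs)), np.nan)
        values = lo[None, :] * (hi / lo)[None, :] ** x_unit[:, : len(parameter_names)]
        for row in range(x_unit.shape[0]):
            m = model.copy()
            set_params(m, values[row])
            try:
                ctrl = simulate(m, Protocol.complete_media(duration=t_obs), initial=initial, **solver)
                kd = simulate(
                    m,
                    Protocol.complete_media(
                        duration=t_obs,
                        knockdowns=[(kd_ref["reaction"], float(kd_ref["alpha"]), 0.0)],
                    ),
                    initial=initial,
                    **solver,
                )
                out[row] = compute_fold_change(kd, ctrl, outputs, t_obs).fold_change
            except Exception:
                pass
        return out

    result = efast_indices(
        func,
        n_params=len(names),
        output_names=list(outputs),
        n_samples=n_samples,
        n_resamples=n_resamples,
        interference=interference,
        seed=seed,
    )
    result.table["parameter"] = result.table["parameter"].map(dict(enumerate(names)))
    return result
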