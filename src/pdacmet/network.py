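"""Metabolic reaction network: species, rate laws, stoichiometry and the ODE right-hand side.

The network couples glycolysis, the pentose phosphate pathway, glutaminolysis,
the TCA cycle and the cytosol/mitochondria shuttle reactions of a pancreatic
cancer cell.  The single source of truth is a structured YAML configuration
(see :func:`load_network` and the packaged reference configuration); kinetic
constants are never hard-coded here.

Species fall into three classes:

* dynamic metabolites — one ODE each (46 in the reference network);
* fixed species — held constant during integration (mitochondrial ATP/ADP);
* boundary species — extracellular pools imposed by the experimental protocol
  (media glucose/glutamine, exported lactate/glutamate/alanine sinks).

Fixed and boundary species resolve in stoichiometries and rate-law roles but
carry no mass balance: their derivative is identically zero.
"""

from __future__ import annotations

import copy as _copy
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "Metabolite",
    "RateLaw",
    "ReactionKinetics",
    "Reaction",
    "NetworkModel",
    "NetworkValidationError",
    "load_network",
    "evaluate_flux",
    "apply_akt_modulation",
    "AKT_BASAL_FRACTION",
]

#: Basal fraction of activity retained by AKT-modulated enzymes (GLUT1, HK,
#: PFK) when AKT signalling is fully absent; the remaining 80% of the maximal
#: velocity is proportional to the AKT activation level.
AKT_BASAL_FRACTION = 0.2

COMPARTMENTS = ("cytosol", "mitochondria", "extracellular")


class NetworkValidationError(ValueError):
    """Raised when a network configuration violates its invariants.

    Carries the full list of violations, not just the first one.
    """

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__(
            "invalid network configuration "
            f"({len(self.errors)} problem{'s' if len(self.errors) != 1 else ''}):\n  - "
            + "\n  - ".join(self.errors)
        )


@dataclass(frozen=True)
class Metabolite:
    """A chemical species of the network.

    Parameters
    ----------
    id
        Short name, e.g. ``G6P`` or ``mMAL`` (mitochondrial duplicates carry
        the ``m`` prefix).
    compartment
        One of ``cytosol``, ``mitochondria``, ``extracellular``.
    initial_concentration
        Baseline starting concentration in mM.
    fixed
        Concentration held constant during integration.
    boundary
        Extracellular species whose concentration is set by the protocol.
    """

    id: str
    compartment: str
    initial_concentration: float = 0.0
    fixed: bool = False
    boundary: bool = False


# ---------------------------------------------------------------------------
# Rate laws
# ---------------------------------------------------------------------------


def _clip(x: float) -> float:
    return x if x > 0.0 else 0.0


@dataclass
class RateLaw:
    """Algebraic form of a reaction rate.

    ``roles`` maps slot names (``substrates``, ``products``, ``inhibitors``,
    ``activators``) to lists of metabolite ids; ``parameters`` holds the named
    kinetic constants (mM, or dimensionless for Hill coefficients, activation
    gains and equilibrium constants).  The supported forms are:

    ``mass_action_irrev``   v = Vf * prod(S)
    ``mass_action_rev``     v = Vf * prod(S) - Vr * prod(P)
    ``mm_irrev``            irreversible Michaelis-Menten, any substrate count
    ``mm_rev_uniuni``       reversible uni-uni Michaelis-Menten
    ``mm_rev_bibi``         random bi-bi with independent Vf and Vr
    ``hill``                allosteric (Hill substrate, MM cosubstrates)
    ``transport_uni``       facilitated carrier, single Vmax, thermodynamic keq
    ``antiport``            two-substrate exchanger, single Vmax, keq
    ``rev_mm_keq``          reversible Michaelis-Menten with Haldane-style keq

    Modifier conventions (all forms): each inhibitor ``I`` multiplies the
    rate by ``1/(1 + I/ki_I)``; each activator ``A`` multiplies by
    ``(1 + beta_A * A/ka_A)/(1 + A/ka_A)`` with gain ``beta_A > 1``.  The
    denominator-based forms additionally accept ``binding`` species — dead-end
    complex terms ``X/kb_X`` added to the denominator, the standard way
    substrate/product inhibition sites enter reversible Michaelis-Menten
    mechanisms.
    """

    form: str
    roles: dict = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)

    # -- role helpers ------------------------------------------------------
    def role(self, name: str) -> list[str]:
        return list(self.roles.get(name, []))

    def role_metabolites(self) -> list[str]:
        out: list[str] = []
        for slot in ("substrates", "products", "inhibitors", "activators", "binding"):
            out.extend(self.role(slot))
        return out

    # -- compilation -------------------------------------------------------
    def build(self, index_of: Callable[[str], int]) -> Callable[[np.ndarray, float, float], float]:
        """Return a fast closure ``f(conc_vector, vf, vr) -> flux`` (mM/min).

        ``index_of`` maps species ids to slots of the full concentration
        vector.  Concentrations are clipped at zero before evaluation so that
        transient solver undershoot cannot produce unphysical rates.
        """
        p = self.parameters
        subs = tuple(index_of(s) for s in self.role("substrates"))
        prods = tuple(index_of(s) for s in self.role("products"))
        sub_ids = self.role("substrates")
        prod_ids = self.role("products")

        def km(prefix: str, met: str) -> float:
            return float(p[f"{prefix}_{met}"])

        # dead-end binding terms (denominator forms) and multiplicative modifiers
        bind = tuple((index_of(m), km("kb", m)) for m in self.role("binding"))
        inh = tuple((index_of(m), km("ki", m)) for m in self.role("inhibitors"))
        act = tuple(
            (index_of(m), km("ka", m), float(p[f"beta_{m}"])) for m in self.role("activators")
        )

        def extra_binding(y: np.ndarray) -> float:
            e = 0.0
            for i, k in bind:
                e += _clip(y[i]) / k
            return e

        if self.form == "mass_action_irrev":

            def core(y, vf, vr):
                s = 1.0
                for i in subs:
                    s *= _clip(y[i])
                return vf * s

        elif self.form == "mass_action_rev":

            def core(y, vf, vr):
                s = 1.0
                for i in subs:
                    s *= _clip(y[i])
                q = 1.0
                for i in prods:
                    q *= _clip(y[i])
                return vf * s - vr * q

        elif self.form == "mm_irrev":
            kms = tuple(km("km", m) for m in sub_ids)

            def core(y, vf, vr):
                v = vf
                for i, k in zip(subs, kms):
                    s = _clip(y[i])
                    v *= s / (k + s)
                return v

        elif self.form == "mm_rev_uniuni":
            (i_s,), (i_p,) = subs, prods
            ks, kp = km("km", sub_ids[0]), km("km", prod_ids[0])

            def core(y, vf, vr):
                s, q = _clip(y[i_s]) / ks, _clip(y[i_p]) / kp
                return (vf * s - vr * q) / (1.0 + s + q + extra_binding(y))

        elif self.form == "mm_rev_bibi":
            (i_a, i_b), (i_p, i_q) = subs, prods
            ka, kb = km("km", sub_ids[0]), km("km", sub_ids[1])
            kp, kq = km("km", prod_ids[0]), km("km", prod_ids[1])

            def core(y, vf, vr):
                a, b = _clip(y[i_a]) / ka, _clip(y[i_b]) / kb
                pp, qq = _clip(y[i_p]) / kp, _clip(y[i_q]) / kq
                return (vf * a * b - vr * pp * qq) / (
                    (1.0 + a + pp) * (1.0 + b + qq) + extra_binding(y)
                )

        elif self.form == "hill":
            i_h = subs[0]
            k_h, n_h = km("k", sub_ids[0]), float(p[f"hill_{sub_ids[0]}"])
            cosubs = tuple((i, km("km", m)) for i, m in zip(subs[1:], sub_ids[1:]))

            def core(y, vf, vr):
                s = _clip(y[i_h])
                sh = s**n_h
                v = vf * sh / (k_h**n_h + sh)
                for i, k in cosubs:
                    c = _clip(y[i])
                    v *= c / (k + c)
                return v

        elif self.form == "transport_uni":
            (i_s,), (i_p,) = subs, prods
            ks, kp = km("km", sub_ids[0]), km("km", prod_ids[0])
            keq = float(p["keq"])

            def core(y, vf, vr):
                s, q = _clip(y[i_s]), _clip(y[i_p])
                return vf * (s - q / keq) / (ks * (1.0 + extra_binding(y)) + s + (ks / kp) * q)

        elif self.form == "antiport":
            (i_a, i_b), (i_p, i_q) = subs, prods
            ka, kb = km("km", sub_ids[0]), km("km", sub_ids[1])
            keq = float(p["keq"])

            def core(y, vf, vr):
                a, b = _clip(y[i_a]), _clip(y[i_b])
                pp, qq = _clip(y[i_p]), _clip(y[i_q])
                return vf * (a * b - pp * qq / keq) / (
                    (ka + a + pp) * (kb + b + qq) + extra_binding(y)
                )

        elif self.form == "rev_mm_keq":
            kms = tuple(km("km", m) for m in sub_ids)
            kmp = tuple(km("km", m) for m in prod_ids)
            keq = float(p["keq"])
            km_s_prod = math.prod(kms)

            def core(y, vf, vr):
                num_s = 1.0
                den_s = 1.0
                for i, k in zip(subs, kms):
                    s = _clip(y[i])
                    num_s *= s / k
                    den_s *= 1.0 + s / k
                num_p = 1.0
                den_p = 1.0
                for i, k in zip(prods, kmp):
                    q = _clip(y[i])
                    num_p *= q
                    den_p *= 1.0 + q / k
                return (
                    vf
                    * (num_s - num_p / (keq * km_s_prod))
                    / (den_s + den_p - 1.0 + extra_binding(y))
                )

        else:  # pragma: no cover - guarded by validation
            raise NetworkValidationError([f"unknown rate-law form {self.form!r}"])

        if not inh and not act:
            return core

        def rate(y, vf, vr):
            v = core(y, vf, vr)
            for i, k in inh:
                v /= 1.0 + _clip(y[i]) / k
            for i, k, beta in act:
                a = _clip(y[i]) / k
                v *= (1.0 + beta * a) / (1.0 + a)
            return v

        return rate

    def evaluate(self, conc: Mapping[str, float], vf: float, vr: float = 0.0) -> float:
        """Evaluate the flux at a concentration map (mM), for one-off use."""
        ids = sorted({*self.role_metabolites()})
        missing = [m for m in ids if m not in conc]
        if missing:
            raise KeyError(f"state is missing metabolites {missing} required by the rate law")
        neg = [m for m in ids if conc[m] < 0.0]
        if neg:
            raise ValueError(f"negative concentration input for {neg}")
        index = {m: i for i, m in enumerate(ids)}
        y = np.array([float(conc[m]) for m in ids])
        return self.build(lambda m: index[m])(y, vf, vr)

    def validate(self, rid: str) -> list[str]:
        errors = []
        if self.form not in RATE_LAW_FORMS:
            errors.append(f"reaction {rid}: unknown rate-law form {self.form!r}")
            return errors
        for name, value in self.parameters.items():
            if not (isinstance(value, (int, float)) and value > 0.0):
                errors.append(
                    f"reaction {rid}: kinetic constant {name} = {value!r} must be strictly positive"
                )
        return errors


RATE_LAW_FORMS = (
    "mass_action_irrev",
    "mass_action_rev",
    "mm_irrev",
    "mm_rev_uniuni",
    "mm_rev_bibi",
    "hill",
    "transport_uni",
    "antiport",
    "rev_mm_keq",
)

#: forms carrying an independent reverse maximal velocity Vr
EXPLICIT_VR_FORMS = ("mass_action_rev", "mm_rev_uniuni", "mm_rev_bibi")


@dataclass
class ReactionKinetics:
    """Velocity parameters of a reaction.

    ``vf``/``vr`` are the forward/reverse maximal velocities (mM/min); ``veq``
    is the equilibrium constant used by the identifiability reduction, which
    re-binds ``vr = vf / veq`` whenever ``equilibrium_constrained`` is set.
    ``knockdown_alpha`` is the fraction of forward activity currently removed
    (shRNA-style knockdown scales ``vf`` by ``1 - alpha``).
    """

    vf: float
    vr: float | None = None
    veq: float | None = None
    akt_modulated: bool = False
    knockdown_alpha: float = 0.0
    equilibrium_constrained: bool = False

    def effective_vf(self, akt_level: float = 1.0) -> float:
        v = self.vf * (1.0 - self.knockdown_alpha)
        if self.akt_modulated:
            v *= AKT_BASAL_FRACTION + (1.0 - AKT_BASAL_FRACTION) * akt_level
        return v

    def effective_vr(self, akt_level: float = 1.0) -> float:
        if self.vr is None and not self.equilibrium_constrained:
            return 0.0
        if self.equilibrium_constrained:
            if self.veq is None:
                raise ValueError("equilibrium-constrained kinetics require veq")
            return self.effective_vf(akt_level) / self.veq
        return self.vr


@dataclass
class Reaction:
    """One enzymatic or transport step of the network."""

    id: str
    stoichiometry: dict[str, float]
    kinetics: ReactionKinetics
    rate_law: RateLaw
    baseline_direction: int | None = None
    pathway: str = ""

    @property
    def reversible(self) -> bool:
        return self.rate_law.form in EXPLICIT_VR_FORMS


class NetworkModel:
    """The full reaction network.

    Attributes
    ----------
    metabolites
        Dynamic metabolites (one ODE each); 46 in the reference configuration.
    fixed_species
        Species held at constant concentration (mM), e.g. mitochondrial
        ATP/ADP.
    boundary_species
        Extracellular pools with their default (complete-media) concentrations;
        protocols override these during simulation.
    reactions
        The enzymatic/transport steps; 53 in the reference configuration.
    """

    def __init__(
        self,
        metabolites: Sequence[Metabolite],
        reactions: Sequence[Reaction],
        fixed_species: Mapping[str, float] | None = None,
        boundary_species: Mapping[str, float] | None = None,
        fold_change_panel: Sequence[str] | None = None,
        meta: Mapping | None = None,
    ):
        self.metabolites = list(metabolites)
        self.reactions = list(reactions)
        self.fixed_species = dict(fixed_species or {})
        self.boundary_species = dict(boundary_species or {})
        self.fold_change_panel = list(fold_change_panel or [])
        self.meta = dict(meta or {})
        self.validate()

    # -- bookkeeping -------------------------------------------------------
    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def species_ids(self) -> list[str]:
        """Dynamic metabolites followed by fixed then boundary species."""
        return self.metabolite_ids + list(self.fixed_species) + list(self.boundary_species)

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(f"unknown reaction id {rid!r}")

    def n_velocity_parameters(self) -> int:
        return sum(2 if r.reversible else 1 for r in self.reactions)

    def free_velocity_count(self) -> int:
        """Velocities still fitted independently (constrained Vr excluded)."""
        n = 0
        for r in self.reactions:
            n += 1  # Vf always free
            if r.reversible and not r.kinetics.equilibrium_constrained:
                n += 1
        return n

    def parameter_inventory(self) -> dict[str, float]:
        """Flat map of every kinetic constant and velocity, ``RID.name``-keyed."""
        inv: dict[str, float] = {}
        for r in self.reactions:
            inv[f"{r.id}.Vf"] = r.kinetics.vf
            if r.reversible:
                inv[f"{r.id}.Vr"] = (
                    r.kinetics.vr
                    if not r.kinetics.equilibrium_constrained
                    else r.kinetics.effective_vr()
                )
                if r.kinetics.veq is not None:
                    inv[f"{r.id}.Veq"] = r.kinetics.veq
            for name, value in r.rate_law.parameters.items():
                inv[f"{r.id}.{name}"] = float(value)
        return inv

    def conformance(self) -> dict[str, int]:
        return {
            "n_metabolites": len(self.metabolites),
            "n_reactions": len(self.reactions),
            "n_velocity_parameters": self.n_velocity_parameters(),
            "n_total_parameters": len(self.parameter_inventory()),
            "n_state_equations": len(self.metabolites) + 1,  # + cell number
        }

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        errors: list[str] = []
        seen: set[tuple[str, str]] = set()
        for m in self.metabolites:
            if m.compartment not in COMPARTMENTS:
                errors.append(f"metabolite {m.id}: unknown compartment {m.compartment!r}")
            if m.initial_concentration < 0:
                errors.append(f"metabolite {m.id}: negative initial concentration")
            key = (m.id, m.compartment)
            if key in seen:
                errors.append(f"duplicate metabolite id {m.id!r} in compartment {m.compartment}")
            seen.add(key)
        known = set(self.species_ids())
        rids: set[str] = set()
        for r in self.reactions:
            if r.id in rids:
                errors.append(f"duplicate reaction id {r.id!r}")
            rids.add(r.id)
            if not r.stoichiometry:
                errors.append(f"reaction {r.id}: empty stoichiometry")
            for met in r.stoichiometry:
                if met not in known:
                    errors.append(f"reaction {r.id}: stoichiometry references undeclared metabolite {met!r}")
            errors.extend(r.rate_law.validate(r.id))
            for met in r.rate_law.role_metabolites():
                if met not in known:
                    errors.append(f"reaction {r.id}: rate-law role references undeclared metabolite {met!r}")
            if r.kinetics.vf < 0:
                errors.append(f"reaction {r.id}: Vf must be non-negative")
            if r.kinetics.vr is not None and r.kinetics.vr < 0:
                errors.append(f"reaction {r.id}: Vr must be non-negative")
            if r.reversible and r.kinetics.vr is None and not r.kinetics.equilibrium_constrained:
                errors.append(f"reaction {r.id}: reversible form {r.rate_law.form} requires Vr")
            if r.baseline_direction not in (None, 1, -1):
                errors.append(f"reaction {r.id}: baseline_direction must be +1 or -1")
        if errors:
            raise NetworkValidationError(errors)

    # -- transforms --------------------------------------------------------
    def copy(self) -> "NetworkModel":
        return _copy.deepcopy(self)

    # -- numerics ----------------------------------------------------------
    def species_index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.species_ids())}

    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense S (dynamic metabolites x reactions); fixed/boundary rows omitted."""
        idx = {m: i for i, m in enumerate(self.metabolite_ids)}
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for met, coeff in r.stoichiometry.items():
                if met in idx:
                    S[idx[met], j] = coeff
        return S

    def build_flux_function(self, akt_level: float = 1.0) -> Callable[[np.ndarray], np.ndarray]:
        """Compile ``fluxes(y_full) -> v`` over the full species vector.

        ``y_full`` is ordered as :meth:`species_ids` (dynamic, then fixed,
        then boundary).  Velocities are bound at compile time, including AKT
        modulation, knockdown factors and equilibrium-constrained reverse
        velocities, so re-compile after changing kinetics.
        """
        if not 0.0 <= akt_level <= 1.0:
            raise ValueError(f"akt_level must lie in [0, 1], got {akt_level}")
        index = self.species_index()
        rates = []
        for r in self.reactions:
            fn = r.rate_law.build(lambda m: index[m])
            rates.append((fn, r.kinetics.effective_vf(akt_level), r.kinetics.effective_vr(akt_level)))
        n = len(rates)

        def fluxes(y_full: np.ndarray) -> np.ndarray:
            v = np.empty(n)
            for j, (fn, vf, vr) in enumerate(rates):
                v[j] = fn(y_full, vf, vr)
            return v

        return fluxes

    def build_rhs(self, akt_level: float = 1.0) -> Callable[[float, np.ndarray], np.ndarray]:
        """Compile the metabolite ODE right-hand side ``f(t, y_full) -> dy``.

        The returned derivative vector has one entry per *full* species slot;
        fixed and boundary entries are exactly zero.  The cell-number equation
        lives in :mod:`pdacmet.growth` and is appended by the simulation
        engine.
        """
        S = self.stoichiometric_matrix()
        fluxes = self.build_flux_function(akt_level)
        n_dyn = len(self.metabolites)
        n_full = len(self.species_ids())

        def rhs(t: float, y_full: np.ndarray) -> np.ndarray:
            if y_full.shape[-1] != n_full:
                raise ValueError(
                    f"state dimension {y_full.shape[-1]} does not match species count {n_full}"
                )
            dy = np.zeros(n_full)
            dy[:n_dyn] = S @ fluxes(y_full)
            return dy

        return rhs

    def rhs_sparsity(self) -> np.ndarray:
        """Conservative Jacobian sparsity of the dynamic subsystem (46 x 46)."""
        idx = {m: i for i, m in enumerate(self.metabolite_ids)}
        n = len(self.metabolites)
        J = np.zeros((n, n), dtype=bool)
        for r in self.reactions:
            touched = [idx[m] for m in r.stoichiometry if m in idx]
            inputs = [idx[m] for m in r.rate_law.role_metabolites() if m in idx]
            for i in touched:
                for j in inputs:
                    J[i, j] = True
                J[i, i] = True
        return J


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def evaluate_flux(reaction: Reaction, state: Mapping[str, float], akt_level: float = 1.0) -> float:
    """Signed net flux (mM/min) of one reaction at a concentration map."""
    k = reaction.kinetics
    return reaction.rate_law.evaluate(state, k.effective_vf(akt_level), k.effective_vr(akt_level))


def apply_akt_modulation(model: NetworkModel, akt_level: float) -> NetworkModel:
    """Return a copy of the model with AKT-modulated maximal velocities rescaled.

    Each reaction flagged ``akt_modulated`` (GLUT1, HK and PFK in the
    reference network) has effective Vmax ``nominal * (0.2 + 0.8 * akt_level)``;
    all other reactions are untouched.  The scaling is folded into the stored
    ``vf`` and the flag cleared, so the returned model can be composed freely.
    """
    if not 0.0 <= akt_level <= 1.0:
        raise ValueError(f"akt_level must lie in [0, 1], got {akt_level}")
    out = model.copy()
    hit = 0
    for r in out.reactions:
        if r.kinetics.akt_modulated:
            r.kinetics.vf *= AKT_BASAL_FRACTION + (1.0 - AKT_BASAL_FRACTION) * akt_level
            r.kinetics.akt_modulated = False
            hit += 1
    if hit == 0:
        raise ValueError("model declares no AKT-modulated reactions")
    return out


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------


def _parse_reaction(spec: Mapping) -> Reaction:
    kin = dict(spec.get("kinetics", {}))
    kinetics = ReactionKinetics(
        vf=float(kin.get("vf", 0.0)),
        vr=(float(kin["vr"]) if "vr" in kin and kin["vr"] is not None else None),
        veq=(float(kin["veq"]) if kin.get("veq") is not None else None),
        akt_modulated=bool(kin.get("akt_modulated", False)),
        knockdown_alpha=float(kin.get("knockdown_alpha", 0.0)),
        equilibrium_constrained=bool(kin.get("equilibrium_constrained", False)),
    )
    law_spec = spec.get("rate_law", {})
    law = RateLaw(
        form=str(law_spec.get("form", "")),
        roles={k: list(v) for k, v in dict(law_spec.get("roles", {})).items()},
        parameters={k: float(v) for k, v in dict(law_spec.get("parameters", {})).items()},
    )
    bd = spec.get("baseline_direction")
    return Reaction(
        id=str(spec["id"]),
        stoichiometry={str(k): float(v) for k, v in dict(spec.get("stoichiometry", {})).items()},
        kinetics=kinetics,
        rate_law=law,
        baseline_direction=(int(bd) if bd is not None else None),
        pathway=str(spec.get("pathway", "")),
    )


def load_network(config_source: str | Path | Mapping) -> NetworkModel:
    """Load and validate a network from a YAML file, YAML text, or a mapping.

    Raises
    ------
    NetworkValidationError
        Listing *every* violation found (unknown rate-law form, non-positive
        kinetic constant, stoichiometry referencing an undeclared metabolite,
        duplicate reaction ids, ...).
    """
    if isinstance(config_source, Mapping):
        cfg = config_source
    else:
        path = Path(config_source)
        if path.exists():
            text = path.read_text()
        else:
            text = str(config_source)
        cfg = yaml.safe_load(text)
    if not isinstance(cfg, Mapping):
        raise NetworkValidationError(["configuration did not parse to a mapping"])
    mets = [
        Metabolite(
            id=str(m["id"]),
            compartment=str(m.get("compartment", "cytosol")),
            initial_concentration=float(m.get("initial_concentration", 0.0)),
        )
        for m in cfg.get("metabolites", [])
    ]
    fixed = {str(k): float(v) for k, v in dict(cfg.get("fixed_species", {})).items()}
    boundary = {str(k): float(v) for k, v in dict(cfg.get("boundary_species", {})).items()}
    reactions = [_parse_reaction(r) for r in cfg.get("reactions", [])]
    return NetworkModel(
        metabolites=mets,
        reactions=reactions,
        fixed_species=fixed,
        boundary_species=boundary,
        fold_change_panel=cfg.get("fold_change_panel", []),
        meta=cfg.get("meta", {}),
    )


def reference_network_path() -> Path:
    """Path of the packaged reference configuration (46/53/71/372)."""
    return Path(__file__).parent / "data" / "network.yaml"


def load_reference_network() -> NetworkModel:
    """Load the packaged reference pancreatic cancer metabolism network."""
    return load_network(reference_network_path())
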