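"""Structural compartmental model for L-DOPA and its striatal metabolites.

The full system has nine compartments: three describing L-DOPA in plasma
(central + two peripherals), one brain-ECF L-DOPA compartment per cerebral
hemisphere (control and rotenone-treated/diseased), and one compartment per
metabolite per hemisphere (DOPAC and HVA, formed from L-DOPA via dopamine,
which is collapsed into the formation rate constants because dopamine itself
is unquantifiable in dialysate).

State conventions
-----------------
* Plasma and brain-ECF L-DOPA compartments hold *amounts* in ng; their
  concentrations follow from the associated volumes of distribution
  (V1..V5, mL).
* Metabolite compartments have no estimable volume and are modelled directly
  as *concentrations* in pmol/mL: formation is first order in the parent ECF
  concentration (expressed in pmol/mL) and loss is first order in the
  metabolite concentration.
* Endogenous L-DOPA synthesis enters each brain-ECF compartment as a
  zero-order input ``Kin`` (ng/min).  This is the only reading under which a
  linear system sustains the observed nonzero pre-dose ECF baselines; the
  historically printed unit label (1/min) is kept as metadata.

Between dose-event switch points the system is linear and time invariant,
so both simulation and estimation work from the rate matrix ``A``, the
endogenous input vector ``b`` and the unit dose-input vector returned by
:func:`build_ode_system`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .units import MOLAR_MASS

__all__ = [
    "PopModelSpec",
    "DoseEvent",
    "LinearSystem",
    "ConfigurationError",
    "DomainError",
    "build_ode_system",
    "build_matrices",
    "steady_state",
    "plasma_model",
    "parent_model",
    "metabolite_model",
    "full_model",
]

HEMISPHERES = ("control", "diseased")
METABOLITES = ("DOPAC", "HVA")

# (analyte, hemisphere) -> (formation constant, elimination constant)
_MET_PARAMS = {
    ("DOPAC", "control"): ("k46", "k60"),
    ("HVA", "control"): ("k47", "k70"),
    ("DOPAC", "diseased"): ("k58", "k80"),
    ("HVA", "diseased"): ("k59", "k90"),
}
_ECF_PARAMS = {
    "control": ("V4", "Q4", "k40"),
    "diseased": ("V5", "Q5", "k50"),
}
# symmetry ties: constrained (diseased-side) parameter -> control-side source
SYMMETRY_TIES = {"Q5": "Q4", "V5": "V4", "k50": "k40"}

# ng -> pmol for the parent driving metabolite formation
_LDOPA_NG_TO_PMOL = 1000.0 / MOLAR_MASS["L-DOPA"]


class ConfigurationError(ValueError):
    """Model/parameter configuration is inconsistent or incomplete."""


class DomainError(ValueError):
    """A parameter value or system state is outside its admissible domain."""


@dataclass(frozen=True)
class DoseEvent:
    """A constant-rate intravenous infusion into the central compartment.

    The study design uses a single 20-min infusion starting at t = 0.
    """

    start: float = 0.0  # min
    duration: float = 20.0  # min
    rate: float = 0.0  # ng/min
    compartment: str = "plasma"

    def __post_init__(self):
        if self.duration <= 0:
            raise DomainError("infusion duration must be > 0")
        if self.rate < 0:
            raise DomainError("infusion rate must be >= 0")
        if self.compartment != "plasma":
            raise ConfigurationError("doses are intravenous: target must be 'plasma'")

    @property
    def end(self) -> float:
        return self.start + self.duration

    @classmethod
    def iv_infusion(cls, dose_mg_per_kg: float, body_weight_kg: float, duration: float = 20.0) -> "DoseEvent":
        amount_ng = dose_mg_per_kg * body_weight_kg * 1.0e6
        return cls(start=0.0, duration=duration, rate=amount_ng / duration)


@dataclass(frozen=True)
class PopModelSpec:
    """Which blocks of the nine-compartment system are active.

    ``peripherals`` selects 0-2 plasma distribution compartments,
    ``hemispheres`` which brain-ECF L-DOPA compartments exist, and
    ``metabolites`` which (analyte, hemisphere) metabolite compartments are
    appended.  ``constraints`` lists hemisphere-symmetry ties applied to the
    diseased-side L-DOPA parameters; each tie removes one free parameter.
    """

    peripherals: int = 2
    hemispheres: tuple[str, ...] = ()
    metabolites: tuple[tuple[str, str], ...] = ()
    constraints: tuple[str, ...] = ()

    def __post_init__(self):
        if self.peripherals not in (0, 1, 2):
            raise ConfigurationError("peripherals must be 0, 1 or 2")
        for h in self.hemispheres:
            if h not in HEMISPHERES:
                raise ConfigurationError(f"unknown hemisphere {h!r}")
        for analyte, hemi in self.metabolites:
            if (analyte, hemi) not in _MET_PARAMS:
                raise ConfigurationError(f"unknown metabolite compartment {(analyte, hemi)!r}")
            if hemi not in self.hemispheres:
                raise ConfigurationError(
                    f"metabolite {(analyte, hemi)!r} requires the {hemi} ECF compartment"
                )
        for c in self.constraints:
            if c not in SYMMETRY_TIES:
                raise ConfigurationError(f"unknown symmetry constraint {c!r}")
            if "diseased" not in self.hemispheres:
                raise ConfigurationError("symmetry constraints need both hemispheres")

    # -- compartment bookkeeping -------------------------------------------
    @property
    def compartments(self) -> tuple[str, ...]:
        comps = ["plasma"]
        comps += [f"periph{i+1}" for i in range(self.peripherals)]
        comps += [f"ecf_{h}" for h in self.hemispheres]
        comps += [f"{a.lower()}_{h}" for a, h in self.metabolites]
        return tuple(comps)

    def comp_index(self, name: str) -> int:
        try:
            return self.compartments.index(name)
        except ValueError:
            raise ConfigurationError(f"compartment {name!r} not in model {self.compartments}")

    @property
    def n_compartments(self) -> int:
        return len(self.compartments)

    # -- parameter bookkeeping ---------------------------------------------
    @property
    def parameter_names(self) -> tuple[str, ...]:
        names = ["Cl", "V1"]
        if self.peripherals >= 1:
            names += ["V2", "Q2"]
        if self.peripherals >= 2:
            names += ["V3", "Q3"]
        if self.hemispheres:
            names.append("Kin")
        for h in self.hemispheres:
            names += list(_ECF_PARAMS[h])
        for key in self.metabolites:
            names += list(_MET_PARAMS[key])
        return tuple(names)

    @property
    def tied_parameters(self) -> dict[str, str]:
        return {c: SYMMETRY_TIES[c] for c in self.constraints}

    @property
    def free_parameter_names(self) -> tuple[str, ...]:
        tied = set(self.tied_parameters)
        return tuple(n for n in self.parameter_names if n not in tied)

    def param_index(self, name: str) -> int:
        try:
            return self.parameter_names.index(name)
        except ValueError:
            raise ConfigurationError(f"parameter {name!r} not in model; expected one of {self.parameter_names}")

    def apply_constraints(self, values: np.ndarray) -> np.ndarray:
        """Copy tied diseased-side values from their control-side source.

        ``values`` has the parameter axis last, ordered as
        ``parameter_names``.
        """
        out = np.array(values, dtype=float, copy=True)
        for target, source in self.tied_parameters.items():
            out[..., self.param_index(target)] = out[..., self.param_index(source)]
        return out

    def params_to_vector(self, params: Mapping[str, float]) -> np.ndarray:
        vec = np.empty(len(self.parameter_names))
        tied = self.tied_parameters
        for i, name in enumerate(self.parameter_names):
            key = tied.get(name, name)
            if key in params:
                vec[i] = params[key]
            elif name in params:
                vec[i] = params[name]
            else:
                raise ConfigurationError(f"missing parameter {key!r}")
        return self.apply_constraints(vec)

    # -- observation mapping -----------------------------------------------
    def observation_compartment(self, dvid: str, hemisphere: str | None = None) -> str:
        """Map an observation type to its compartment name."""
        if dvid == "plasma_LDOPA":
            return "plasma"
        if dvid == "ecf_LDOPA":
            return f"ecf_{hemisphere}"
        if dvid == "dial_DOPAC":
            return f"dopac_{hemisphere}"
        if dvid == "dial_HVA":
            return f"hva_{hemisphere}"
        raise ConfigurationError(f"unknown observation type {dvid!r}")

    @staticmethod
    def error_model(dvid: str) -> str:
        """Residual-error model per observation type.

        L-DOPA (plasma and ECF) carries a proportional error; the metabolite
        dialysate concentrations carry an additive error.
        """
        if dvid in ("plasma_LDOPA", "ecf_LDOPA"):
            return "proportional"
        if dvid in ("dial_DOPAC", "dial_HVA"):
            return "additive"
        raise ConfigurationError(f"unknown observation type {dvid!r}")


@dataclass
class LinearSystem:
    """dx/dt = A x + b_endo + rate(t) * dose_vec, between dose switch points."""

    spec: PopModelSpec
    A: np.ndarray
    b_endo: np.ndarray
    dose_vec: np.ndarray
    params: np.ndarray  # natural-scale vector ordered as spec.parameter_names

    @property
    def volumes(self) -> np.ndarray:
        """Per-compartment divisor turning state into concentration.

        Amount compartments divide by their volume (-> ng/mL); metabolite
        compartments are already concentrations (divisor 1, pmol/mL).
        """
        return _volume_vector(self.spec, self.params)


_POSITIVE_VOLUMES = ("V1", "V2", "V3", "V4", "V5")


def _volume_vector(spec: PopModelSpec, params: np.ndarray) -> np.ndarray:
    p = {n: params[..., i] for i, n in enumerate(spec.parameter_names)}
    vols = [p["V1"]]
    for i in range(spec.peripherals):
        vols.append(p[f"V{i+2}"])
    for h in spec.hemispheres:
        vols.append(p[_ECF_PARAMS[h][0]])
    for _ in spec.metabolites:
        vols.append(np.ones_like(p["V1"]))
    return np.stack(vols, axis=-1)


def build_matrices(spec: PopModelSpec, params: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised rate-matrix builder.

    ``params`` has shape ``(..., n_params)`` on the natural scale with
    symmetry constraints already applied.  Returns ``A`` of shape
    ``(..., n, n)``, the endogenous input ``b`` of shape ``(..., n)`` and the
    unit-rate dose input vector of shape ``(n,)``.
    """
    params = np.asarray(params, dtype=float)
    names = spec.parameter_names
    p = {n: params[..., i] for i, n in enumerate(names)}
    batch = params.shape[:-1]
    n = spec.n_compartments
    A = np.zeros(batch + (n, n))
    b = np.zeros(batch + (n,))

    i_pl = spec.comp_index("plasma")
    Cl, V1 = p["Cl"], p["V1"]
    A[..., i_pl, i_pl] -= Cl / V1

    for k in range(spec.peripherals):
        Q, V = p[f"Q{k+2}"], p[f"V{k+2}"]
        i = spec.comp_index(f"periph{k+1}")
        A[..., i_pl, i_pl] -= Q / V1
        A[..., i, i_pl] += Q / V1
        A[..., i, i] -= Q / V
        A[..., i_pl, i] += Q / V

    for h in spec.hemispheres:
        Vb, Qb, kel = (p[x] for x in _ECF_PARAMS[h])
        i = spec.comp_index(f"ecf_{h}")
        A[..., i_pl, i_pl] -= Qb / V1
        A[..., i, i_pl] += Qb / V1
        A[..., i, i] -= Qb / Vb + kel
        A[..., i_pl, i] += Qb / Vb
        b[..., i] += p["Kin"]

    for (analyte, h) in spec.metabolites:
        kform, kel = _MET_PARAMS[(analyte, h)]
        i = spec.comp_index(f"{analyte.lower()}_{h}")
        i_ecf = spec.comp_index(f"ecf_{h}")
        Vb = p[_ECF_PARAMS[h][0]]
        # formation from parent ECF concentration expressed in pmol/mL
        A[..., i, i_ecf] += p[kform] * _LDOPA_NG_TO_PMOL / Vb
        A[..., i, i] -= p[kel]

    dose_vec = np.zeros(n)
    dose_vec[i_pl] = 1.0
    return A, b, dose_vec


def build_ode_system(spec: PopModelSpec, params: Mapping[str, float] | np.ndarray) -> LinearSystem:
    """Assemble the linear compartmental system for one parameter set.

    ``params`` is either a mapping of parameter name to value (symmetry ties
    may be given through their control-side source only) or an already
    ordered vector.  Raises :class:`ConfigurationError` for a missing symbol
    and :class:`DomainError` for out-of-domain values.
    """
    if isinstance(params, Mapping):
        vec = spec.params_to_vector(params)
    else:
        vec = spec.apply_constraints(np.asarray(params, dtype=float))
        if vec.shape != (len(spec.parameter_names),):
            raise ConfigurationError(
                f"expected {len(spec.parameter_names)} parameters, got shape {vec.shape}"
            )
    for i, name in enumerate(spec.parameter_names):
        v = vec[i]
        if not np.isfinite(v):
            raise DomainError(f"parameter {name} is not finite")
        if name in _POSITIVE_VOLUMES:
            if v <= 0:
                raise DomainError(f"volume {name} must be > 0, got {v}")
        elif v < 0:
            raise DomainError(f"parameter {name} must be >= 0, got {v}")
    A, b, dose_vec = build_matrices(spec, vec)
    return LinearSystem(spec=spec, A=A, b_endo=b, dose_vec=dose_vec, params=vec)


def steady_state(system: LinearSystem) -> dict[str, dict[str, float]]:
    """Endogenous-input-only steady state, ``0 = A x + b``.

    Returns per-compartment baseline amounts and concentrations.  With no
    endogenous input the baseline is identically zero; a compartment driven
    by ``Kin`` with no elimination path makes the system singular and raises
    :class:`DomainError`.

    The plasma baseline that results from endogenous brain synthesis leaking
    back across the BBB is retained; at the study's parameter values it lies
    orders of magnitude below the 1 ng/mL plasma quantification limit, i.e.
    effectively zero, matching the unmeasurable endogenous plasma levels.
    """
    if not np.any(system.b_endo):
        x = np.zeros(system.spec.n_compartments)
    else:
        try:
            x = np.linalg.solve(system.A, -system.b_endo)
        except np.linalg.LinAlgError:
            raise DomainError("no steady state: singular system (zero elimination with nonzero input)")
        if not np.all(np.isfinite(x)) or np.linalg.cond(system.A) > 1e12:
            raise DomainError("no steady state: singular system (zero elimination with nonzero input)")
    conc = x / system.volumes
    out: dict[str, dict[str, float]] = {}
    for i, name in enumerate(system.spec.compartments):
        unit = "pmol/mL" if name.split("_")[0] in ("dopac", "hva") else "ng/mL"
        out[name] = {"amount": float(x[i]), "concentration": float(conc[i]), "unit": unit}
    return out


# -- convenience spec factories -------------------------------------------

def plasma_model(peripherals: int = 2) -> PopModelSpec:
    """Plasma-only disposition model (three-compartment by default)."""
    return PopModelSpec(peripherals=peripherals)


def parent_model(
    hemispheres: Sequence[str] = HEMISPHERES,
    constraints: Iterable[str] = (),
    peripherals: int = 2,
) -> PopModelSpec:
    """Plasma + brain-ECF L-DOPA model (compartments 1-5)."""
    return PopModelSpec(
        peripherals=peripherals,
        hemispheres=tuple(hemispheres),
        constraints=tuple(constraints),
    )


def metabolite_model(analyte: str, hemisphere: str, constraints: Iterable[str] = ()) -> PopModelSpec:
    """Parent model for one hemisphere plus a single metabolite compartment.

    Used by the sequential metabolite fits: the parent L-DOPA disposition is
    carried over (fixed per subject) while the hemisphere's formation,
    parent-elimination and metabolite-elimination constants are estimated.
    """
    return PopModelSpec(
        peripherals=2,
        hemispheres=(hemisphere,),
        metabolites=((analyte, hemisphere),),
        constraints=tuple(constraints),
    )


def full_model(constraints: Iterable[str] = ()) -> PopModelSpec:
    """The complete nine-compartment parent + metabolite system."""
    mets = tuple((a, h) for h in HEMISPHERES for a in METABOLITES)
    return PopModelSpec(
        peripherals=2,
        hemispheres=HEMISPHERES,
        metabolites=mets,
        constraints=tuple(constraints),
    )
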