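"""Kinetic model of mitochondrial membrane potential (MMP) under OXPHOS inhibition.

Two state variables: the mitochondrial oxygen level ``[O]`` and the membrane
potential ``Psi`` (both in arbitrary units).  Oxygen is supplied at a constant
rate and consumed by electron-transport-chain (ETC) activity; the consumption
term is the oxygen consumption rate (OCR) and is reduced by ETC inhibitors via
Michaelis-Menten inhibition.  The MMP is built up by proton pumping
(proportional to the OCR) and dissipated by ATP synthesis through complex V
(Michaelis-Menten in Psi, inhibitable) and by uncoupler-mediated proton
backflow.

Model variants
--------------
``basic``
    Constant effective compound concentration.
``pk_decay``
    The effective concentration decays exponentially at rate ``gamma``
    (intracellular pharmacokinetic decay).
``pk_decay_leakage``
    As ``pk_decay`` plus a linear ion-leakage flux ``alpha * (Psi - Psi_ss)``
    active after exposure; only meaningful for ATP-synthase inhibitors
    (oligomycin-style hyperpolarisation).
``conc_dep_decay``
    Concentration-dependent decay: a fast rate ``gamma_L`` for the lowest
    applied concentrations and a slow rate ``gamma_H`` for the highest.

Time is measured in hours; exposure starts at t = 0 and the Heaviside gate
uses H(0) = 1, so the effective concentration equals the applied effective
dose at the moment of exposure.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "ModelParameters",
    "ModelVariant",
    "State",
    "TARGET_CLASSES",
    "VARIANT_NAMES",
    "steady_state",
    "steady_state_gradient",
    "ocr",
    "oxygen_rhs",
    "mmp_rhs",
    "leakage_rhs",
    "effective_concentration",
    "observe",
    "decay_rate_for_dose",
]

TARGET_CLASSES = ("etc_inhibitor", "atp_synthase_inhibitor", "uncoupler")
VARIANT_NAMES = ("basic", "pk_decay", "pk_decay_leakage", "conc_dep_decay")

#: parameters that must be strictly positive
_POSITIVE = ("supply", "K_E", "K_Ei", "C_f", "V_A", "K_A", "K_Ai", "V_U", "K_U", "r", "c1")
#: parameters that must be non-negative
_NONNEGATIVE = ("alpha", "gamma", "gamma_L", "gamma_H")


class ParameterDomainError(ValueError):
    """Raised when a parameter set violates the model's admissibility domain."""


@dataclass(frozen=True)
class ModelParameters:
    """All rate, affinity and scaling constants for one compound.

    Units: concentrations in uM, time in hours, everything else in the
    arbitrary units induced by the intensity readout.  ``supply`` (the constant
    oxygen supply rate) defaults to 0.6 and ``V_U = K_U = 1`` are fixed by
    convention; ``K_E = K_Ei = 1`` by default because they are absorbed into
    the arbitrary units and are not separately constrained by MMP data.
    """

    supply: float = 0.6
    K_E: float = 1.0
    K_Ei: float = 1.0
    C_f: float = 1.0
    V_A: float = 1.2
    K_A: float = 1.0
    K_Ai: float = 1.0
    V_U: float = 1.0
    K_U: float = 1.0
    r: float = 1.0
    c1: float = 1.0
    c0: float = 0.0
    alpha: float = 0.0
    gamma: float = 0.0
    gamma_L: float = 0.0
    gamma_H: float = 0.0
    D0: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        for name in _POSITIVE:
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ParameterDomainError(f"{name} must be finite and > 0, got {v}")
        for name in _NONNEGATIVE:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ParameterDomainError(f"{name} must be finite and >= 0, got {v}")
        if not np.isfinite(self.c0):
            raise ParameterDomainError(f"c0 must be finite, got {self.c0}")
        object.__setattr__(self, "D0", tuple(float(d) for d in self.D0))
        if any(d < 0 or not np.isfinite(d) for d in self.D0):
            raise ParameterDomainError("all effective dose entries D0 must be >= 0")
        if self.V_A <= self.supply * self.C_f:
            raise ParameterDomainError(
                "V_A must exceed supply*C_f for a positive MMP steady state "
                f"(V_A={self.V_A}, supply*C_f={self.supply * self.C_f})"
            )

    # -- derived steady-state quantities ---------------------------------
    @property
    def o_ss(self) -> float:
        """Baseline oxygen level (supply balanced against uninhibited OCR)."""
        return self.supply / self.K_E

    @property
    def psi_o(self) -> float:
        """Baseline MMP Psi_ss = supply*C_f*K_A / (V_A - supply*C_f)."""
        sc = self.supply * self.C_f
        return sc * self.K_A / (self.V_A - sc)

    # -- vector view used by the calibration layer -----------------------
    def get(self, name: str) -> float:
        if name.startswith("D0_"):
            return self.D0[int(name[3:])]
        return getattr(self, name)

    def with_values(self, names: Sequence[str], values: Sequence[float]) -> "ModelParameters":
        """Return a copy with the named entries replaced (``D0_<i>`` addresses a dose)."""
        plain: dict[str, float] = {}
        d0 = list(self.D0)
        for name, v in zip(names, values):
            if name.startswith("D0_"):
                d0[int(name[3:])] = float(v)
            else:
                plain[name] = float(v)
        return replace(self, D0=tuple(d0), **plain)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["D0"] = list(self.D0)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        d = dict(d)
        d["D0"] = tuple(d.get("D0", ()))
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelParameters":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


@dataclass(frozen=True)
class ModelVariant:
    """A model variant together with the inhibitor class it acts on.

    ``n_low`` is only used by ``conc_dep_decay`` and gives the number of
    lowest dose indices decaying at ``gamma_L``; all higher indices decay at
    ``gamma_H`` (default split: 4 lowest vs the rest, the oligomycin design).
    """

    name: str
    target_class: str
    n_low: int = 4

    def __post_init__(self) -> None:
        if self.name not in VARIANT_NAMES:
            raise ValueError(f"unknown variant {self.name!r}; expected one of {VARIANT_NAMES}")
        if self.target_class not in TARGET_CLASSES:
            raise ValueError(
                f"unknown target_class {self.target_class!r}; expected one of {TARGET_CLASSES}"
            )
        if self.name in ("pk_decay_leakage", "conc_dep_decay") and (
            self.target_class != "atp_synthase_inhibitor"
        ):
            raise ValueError(f"variant {self.name!r} is only admitted for atp_synthase_inhibitor")

    @property
    def has_decay(self) -> bool:
        return self.name in ("pk_decay", "pk_decay_leakage", "conc_dep_decay")

    @property
    def has_leakage(self) -> bool:
        return self.name == "pk_decay_leakage"


@dataclass(frozen=True)
class State:
    """Instantaneous model state: oxygen level and MMP."""

    O: float
    Psi: float


def steady_state(params: ModelParameters) -> State:
    """Pre-exposure steady state (all compound concentrations zero).

    Setting both right-hand sides to zero gives the closed forms
    ``O_ss = supply / K_E`` and ``Psi_ss = supply*C_f*K_A / (V_A - supply*C_f)``;
    parameter validation guarantees ``V_A > supply*C_f`` so Psi_ss > 0.
    """
    return State(O=params.o_ss, Psi=params.psi_o)


def steady_state_gradient(params: ModelParameters, names: Sequence[str]) -> np.ndarray:
    """Partial derivatives of the steady state w.r.t. the named parameters.

    Returns an array of shape (2, len(names)) with rows (dO_ss, dPsi_ss).
    Used to initialise the forward sensitivity system.
    """
    s, ke, cf, va, ka = params.supply, params.K_E, params.C_f, params.V_A, params.K_A
    q = va - s * cf
    grad = np.zeros((2, len(names)))
    for k, name in enumerate(names):
        if name == "supply":
            grad[0, k] = 1.0 / ke
            grad[1, k] = cf * ka * va / q**2
        elif name == "K_E":
            grad[0, k] = -s / ke**2
        elif name == "C_f":
            grad[1, k] = s * ka * va / q**2
        elif name == "V_A":
            grad[1, k] = -s * cf * ka / q**2
        elif name == "K_A":
            grad[1, k] = s * cf / q
        # all other parameters leave the steady state unchanged
    return grad


def ocr(state: State, dose_E: float, params: ModelParameters) -> float:
    """Oxygen consumption rate ``K_E * O * K_Ei / (K_Ei + D_E)``."""
    if dose_E < 0:
        raise ValueError("dose_E must be >= 0")
    return params.K_E * state.O * params.K_Ei / (params.K_Ei + dose_E)


def oxygen_rhs(state: State, dose_E: float, params: ModelParameters) -> float:
    """d[O]/dt = r * (supply - OCR)."""
    return params.r * (params.supply - ocr(state, dose_E, params))


def mmp_rhs(
    state: State,
    dose_E: float,
    dose_A: float,
    dose_U: float,
    params: ModelParameters,
) -> float:
    """dPsi/dt for the basic model.

    ``r * (C_f*OCR - V_A*Psi/(K_A+Psi) * K_Ai/(K_Ai+D_A) - V_U*D_U/(K_U+D_U) * Psi)``
    """
    if min(dose_E, dose_A, dose_U) < 0:
        raise ValueError("doses must be >= 0")
    p = params
    production = p.C_f * ocr(state, dose_E, p)
    atp = p.V_A * state.Psi / (p.K_A + state.Psi) * p.K_Ai / (p.K_Ai + dose_A)
    unc = p.V_U * dose_U / (p.K_U + dose_U) * state.Psi
    return p.r * (production - atp - unc)


def leakage_rhs(Psi: float, dose_A: float, t: float, params: ModelParameters) -> float:
    """dPsi/dt for the ion-leakage extension (ATP-synthase inhibitors only).

    Oxygen stays at steady state in this variant (no ETC inhibitor), so the
    production term is the constant ``supply * C_f``.  The leakage flux
    ``alpha * (Psi - Psi_ss)`` is gated by a Heaviside step (H(t)=1 for t>=0)
    and vanishes at the baseline MMP, preserving the unexposed steady state.
    """
    p = params
    atp = p.V_A * Psi / (p.K_A + Psi) * p.K_Ai / (p.K_Ai + dose_A)
    leak = p.alpha * (Psi - p.psi_o) if t >= 0 else 0.0
    return p.r * (p.supply * p.C_f - atp - leak)


def effective_concentration(D0, gamma: float, t):
    """Effective concentration ``D0 * exp(-gamma*t) * H(t)`` (H(0) = 1).

    Accepts scalar or array ``t``; ``gamma = 0`` gives a constant step.
    """
    if np.any(np.asarray(D0) < 0) or gamma < 0:
        raise ValueError("D0 and gamma must be >= 0")
    t = np.asarray(t, dtype=float)
    out = D0 * np.exp(-gamma * np.where(t >= 0, t, 0.0)) * (t >= 0)
    return float(out) if out.ndim == 0 else out


def decay_rate_for_dose(variant: ModelVariant, params: ModelParameters, dose_index: int) -> float:
    """Decay rate acting on a given dose index under the variant's PK rule."""
    if not variant.has_decay:
        return 0.0
    if variant.name == "conc_dep_decay":
        return params.gamma_L if dose_index < variant.n_low else params.gamma_H
    return params.gamma


def observe(Psi, params: ModelParameters):
    """Linear observation map ``y = c1*Psi + c0`` from MMP to normalized intensity."""
    return params.c1 * np.asarray(Psi) + params.c0 if np.ndim(Psi) else params.c1 * Psi + params.c0
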