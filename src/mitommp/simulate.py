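"""Numerical integration of the MMP model variants and forward sensitivities.

The right-hand sides are compiled with numba; the augmented (state +
sensitivity) system propagates analytic partial derivatives of the vector
field, which the calibration layer uses as an exact least-squares Jacobian
("sensitivity equations").  Integration starts at t = 0 from the analytic
steady state with the post-exposure vector field, so the Heaviside switch at
exposure start needs no event handling.

Default solver tolerances are rtol=1e-8, atol=1e-10 with LSODA (stiff-capable;
the hyperpolarisation phase under ATP-synthase inhibition can be stiff).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy.integrate import ODEintWarning, odeint

from .model import (
    ModelParameters,
    ModelVariant,
    decay_rate_for_dose,
    effective_concentration,
    steady_state,
    steady_state_gradient,
)

__all__ = [
    "Trajectory",
    "IntegrationError",
    "simulate",
    "simulate_sensitivities",
    "predict_ocr",
    "DEFAULT_TIMES",
    "RTOL",
    "ATOL",
]

#: hourly measurement grid, 23 points starting 1 h post-exposure
DEFAULT_TIMES = np.arange(1.0, 24.0)

RTOL = 1e-8
ATOL = 1e-10

_CHANNELS = {"etc_inhibitor": 0, "atp_synthase_inhibitor": 1, "uncoupler": 2}

# integer codes the compiled kernels use to identify free parameters
_CODES = {
    "supply": 0, "K_E": 1, "K_Ei": 2, "C_f": 3, "V_A": 4, "K_A": 5, "K_Ai": 6,
    "V_U": 7, "K_U": 8, "r": 9, "c1": 10, "c0": 11, "alpha": 12,
}
_GAMMA_ACTIVE, _GAMMA_INACTIVE, _D0_ACTIVE, _D0_OTHER = 13, 14, 15, 16


class IntegrationError(RuntimeError):
    """ODE integration failed for a parameter set / variant combination."""


@dataclass
class Trajectory:
    """Simulated series on a measurement grid for one condition."""

    times: np.ndarray
    O: np.ndarray
    Psi: np.ndarray
    y: np.ndarray
    doses: np.ndarray  # effective concentration of the active compound channel
    dose_index: int
    variant: str

    def to_frame(self, compound: str = "") -> pd.DataFrame:
        """Tidy export (one row per time point)."""
        return pd.DataFrame(
            {
                "compound": compound,
                "dose_index": self.dose_index,
                "time_h": self.times,
                "O": self.O,
                "Psi": self.Psi,
                "y": self.y,
                "effective_concentration": self.doses,
            }
        )


@njit(cache=True)
def _rhs(z, t, c):
    """Plain 2-state vector field; ``c`` packs all constants (see _pack)."""
    O, Psi = z[0], z[1]
    supply, K_E, K_Ei, C_f, V_A, K_A, K_Ai, V_U, K_U, r = c[0:10]
    alpha, psi_o, D0i, g = c[10], c[11], c[12], c[13]
    channel, leak = int(c[14]), int(c[15])

    D = D0i * np.exp(-g * t)
    dE = D if channel == 0 else 0.0
    dA = D if channel == 1 else 0.0
    dU = D if channel == 2 else 0.0

    e = K_Ei / (K_Ei + dE)
    ocr_ = K_E * O * e
    atp = V_A * Psi / (K_A + Psi) * K_Ai / (K_Ai + dA)
    unc = V_U * dU / (K_U + dU) * Psi

    dO = r * (supply - ocr_)
    dP = r * (C_f * ocr_ - atp - unc)
    if leak == 1:
        dP -= r * alpha * (Psi - psi_o)
    out = np.empty(2)
    out[0] = dO
    out[1] = dP
    return out


@njit(cache=True)
def _rhs_aug(z, t, c, codes, dpsi0):
    """Augmented vector field: state plus forward sensitivities.

    ``codes`` maps each free parameter to an integer case; ``dpsi0`` holds
    d(Psi_ss)/d(theta_k), needed because the leakage flux references the
    parameter-dependent steady state.
    """
    p = codes.shape[0]
    O, Psi = z[0], z[1]
    supply, K_E, K_Ei, C_f, V_A, K_A, K_Ai, V_U, K_U, r = c[0:10]
    alpha, psi_o, D0i, g = c[10], c[11], c[12], c[13]
    channel, leak = int(c[14]), int(c[15])

    D = D0i * np.exp(-g * t)
    dE = D if channel == 0 else 0.0
    dA = D if channel == 1 else 0.0
    dU = D if channel == 2 else 0.0

    e = K_Ei / (K_Ei + dE)
    ocr_ = K_E * O * e
    afrac = Psi / (K_A + Psi)
    ai = K_Ai / (K_Ai + dA)
    ufrac = dU / (K_U + dU)
    u = V_U * ufrac

    dO = r * (supply - ocr_)
    dP = r * (C_f * ocr_ - V_A * afrac * ai - u * Psi)
    if leak == 1:
        dP -= r * alpha * (Psi - psi_o)

    # state Jacobian (J01 = 0: the MMP does not feed back on oxygen)
    J00 = -r * K_E * e
    J10 = r * C_f * K_E * e
    J11 = r * (-V_A * ai * K_A / (K_A + Psi) ** 2 - u)
    if leak == 1:
        J11 -= r * alpha

    # partials w.r.t. the active channel's effective concentration
    if channel == 0:
        dfO_dD = r * K_E * O * K_Ei / (K_Ei + dE) ** 2
        dfP_dD = -r * C_f * K_E * O * K_Ei / (K_Ei + dE) ** 2
    elif channel == 1:
        dfO_dD = 0.0
        dfP_dD = r * V_A * afrac * K_Ai / (K_Ai + dA) ** 2
    else:
        dfO_dD = 0.0
        dfP_dD = -r * Psi * V_U * K_U / (K_U + dU) ** 2
    dD_dg = -t * D
    dD_dD0 = np.exp(-g * t)

    out = np.empty(2 + 2 * p)
    out[0] = dO
    out[1] = dP
    for k in range(p):
        code = codes[k]
        g0 = 0.0
        g1 = 0.0
        if code == 0:  # supply
            g0 = r
        elif code == 1:  # K_E
            g0 = -r * O * e
            g1 = r * C_f * O * e
        elif code == 2:  # K_Ei
            de = dE / (K_Ei + dE) ** 2
            g0 = -r * K_E * O * de
            g1 = r * C_f * K_E * O * de
        elif code == 3:  # C_f
            g1 = r * ocr_
        elif code == 4:  # V_A
            g1 = -r * afrac * ai
        elif code == 5:  # K_A
            g1 = r * V_A * Psi / (K_A + Psi) ** 2 * ai
        elif code == 6:  # K_Ai
            g1 = -r * V_A * afrac * dA / (K_Ai + dA) ** 2
        elif code == 7:  # V_U
            g1 = -r * ufrac * Psi
        elif code == 8:  # K_U
            g1 = r * V_U * dU / (K_U + dU) ** 2 * Psi
        elif code == 9:  # r
            g0 = dO / r
            g1 = dP / r
        elif code == 12:  # alpha
            if leak == 1:
                g1 = -r * (Psi - psi_o)
        elif code == 13:  # decay rate governing this condition
            g0 = dfO_dD * dD_dg
            g1 = dfP_dD * dD_dg
        elif code == 15:  # effective dose of this condition
            g0 = dfO_dD * dD_dD0
            g1 = dfP_dD * dD_dD0
        # codes 10, 11 (c1, c0), 14, 16: no effect on the state equations
        if leak == 1:
            # the leakage flux pins Psi to the parameter-dependent steady state
            g1 += r * alpha * dpsi0[k]
        sO = z[2 + k]
        sP = z[2 + p + k]
        out[2 + k] = J00 * sO + g0
        out[2 + p + k] = J10 * sO + J11 * sP + g1
    return out


def _pack(variant: ModelVariant, params: ModelParameters, dose_index: int) -> np.ndarray:
    p = params
    if not (0 <= dose_index < len(p.D0)):
        raise IndexError(f"dose_index {dose_index} outside D0 of length {len(p.D0)}")
    g = decay_rate_for_dose(variant, p, dose_index)
    return np.array(
        [
            p.supply, p.K_E, p.K_Ei, p.C_f, p.V_A, p.K_A, p.K_Ai, p.V_U, p.K_U, p.r,
            p.alpha, p.psi_o, p.D0[dose_index], g,
            float(_CHANNELS[variant.target_class]), float(variant.has_leakage),
        ]
    )


def _codes_for(variant: ModelVariant, dose_index: int, free_names: Sequence[str]) -> np.ndarray:
    codes = np.empty(len(free_names), dtype=np.int64)
    active_gamma = None
    if variant.name in ("pk_decay", "pk_decay_leakage"):
        active_gamma = "gamma"
    elif variant.name == "conc_dep_decay":
        active_gamma = "gamma_L" if dose_index < variant.n_low else "gamma_H"
    for k, name in enumerate(free_names):
        if name in _CODES:
            codes[k] = _CODES[name]
        elif name in ("gamma", "gamma_L", "gamma_H"):
            codes[k] = _GAMMA_ACTIVE if name == active_gamma else _GAMMA_INACTIVE
        elif name.startswith("D0_"):
            codes[k] = _D0_ACTIVE if int(name[3:]) == dose_index else _D0_OTHER
        else:
            raise ValueError(f"unknown parameter name {name!r}")
    return codes


def _grid(times: np.ndarray) -> tuple[np.ndarray, int]:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ValueError("times must be a non-empty 1-d grid")
    if np.any(np.diff(times) <= 0) or times[0] < 0:
        raise ValueError("times must be strictly ascending with times[0] >= 0")
    if times[0] > 0:
        return np.concatenate(([0.0], times)), 1
    return times, 0


def _integrate(func, z0, tt, args, rtol, atol, context, mxstep=10_000):
    if len(tt) == 1:  # output requested only at the initial time
        return np.asarray(z0, dtype=float)[None, :]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ODEintWarning)
        sol, info = odeint(
            func, z0, tt, args=args, rtol=rtol, atol=atol, mxstep=mxstep, full_output=True
        )
    if info["message"] != "Integration successful." or not np.all(np.isfinite(sol)):
        raise IntegrationError(f"ODE integration failed for {context}: {info['message']}")
    return sol


def simulate(
    variant: ModelVariant,
    params: ModelParameters,
    dose_index: int,
    times: np.ndarray = DEFAULT_TIMES,
    rtol: float = RTOL,
    atol: float = ATOL,
    mxstep: int = 10_000,
) -> Trajectory:
    """Integrate one condition from the pre-exposure steady state.

    ``times`` is the output grid (hours, ascending, >= 0); integration always
    starts at t = 0 where exposure begins.
    """
    tt, skip = _grid(times)
    c = _pack(variant, params, dose_index)
    ss = steady_state(params)
    z0 = np.array([ss.O, ss.Psi])
    sol = _integrate(_rhs, z0, tt, (c,), rtol, atol, f"variant={variant.name}", mxstep)
    O, Psi = sol[skip:, 0], sol[skip:, 1]
    g = decay_rate_for_dose(variant, params, dose_index)
    doses = effective_concentration(params.D0[dose_index], g, tt[skip:])
    return Trajectory(
        times=tt[skip:],
        O=O,
        Psi=Psi,
        y=params.c1 * Psi + params.c0,
        doses=np.atleast_1d(doses),
        dose_index=dose_index,
        variant=variant.name,
    )


def simulate_sensitivities(
    variant: ModelVariant,
    params: ModelParameters,
    dose_index: int,
    times: np.ndarray = DEFAULT_TIMES,
    free_names: Sequence[str] = (),
    rtol: float = RTOL,
    atol: float = ATOL,
    mxstep: int = 10_000,
) -> tuple[Trajectory, np.ndarray]:
    """Trajectory plus the sensitivity matrix dy/dtheta, shape (n_times, p).

    Sensitivities of the observed output are propagated with the forward
    (augmented) ODE system, including the dependence of the steady-state
    initial condition on the parameters.
    """
    free_names = list(free_names)
    p = len(free_names)
    tt, skip = _grid(times)
    c = _pack(variant, params, dose_index)
    codes = _codes_for(variant, dose_index, free_names)
    grad0 = steady_state_gradient(params, free_names)  # (2, p)
    ss = steady_state(params)
    z0 = np.concatenate(([ss.O, ss.Psi], grad0[0], grad0[1]))
    sol = _integrate(
        _rhs_aug, z0, tt, (c, codes, np.ascontiguousarray(grad0[1])), rtol, atol,
        f"variant={variant.name} (sensitivities)", mxstep,
    )
    O, Psi = sol[skip:, 0], sol[skip:, 1]
    S_psi = sol[skip:, 2 + p : 2 + 2 * p]
    dy = params.c1 * S_psi
    for k, name in enumerate(free_names):
        if name == "c1":
            dy[:, k] += Psi
        elif name == "c0":
            dy[:, k] += 1.0
    g = decay_rate_for_dose(variant, params, dose_index)
    doses = effective_concentration(params.D0[dose_index], g, tt[skip:])
    traj = Trajectory(
        times=tt[skip:],
        O=O,
        Psi=Psi,
        y=params.c1 * Psi + params.c0,
        doses=np.atleast_1d(doses),
        dose_index=dose_index,
        variant=variant.name,
    )
    return traj, dy


def predict_ocr(params: ModelParameters, dose_E: float, t, rtol: float = RTOL, atol: float = ATOL):
    """Simulated OCR ``K_E * O(t) * K_Ei/(K_Ei + D_E)`` under constant ETC inhibition.

    Used to compare the model against respirometry-style measurements (e.g.,
    OCR 30 min after exposure).  Returns a scalar for scalar ``t``.
    """
    if dose_E < 0:
        raise ValueError("dose_E must be >= 0")
    scalar = np.ndim(t) == 0
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    variant = ModelVariant("basic", "etc_inhibitor")
    p = replace(params, D0=(float(dose_E),))
    traj = simulate(variant, p, 0, np.unique(np.concatenate(([0.0], t_arr))), rtol, atol)
    O_at = np.interp(t_arr, traj.times, traj.O)
    out = params.K_E * O_at * params.K_Ei / (params.K_Ei + dose_E)
    return float(out[0]) if scalar else out
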