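"""Maximum-likelihood calibration of the MMP model to condition trajectories.

The match between model and data for one condition (compound x concentration)
is the weighted sum of squared residuals

    R^2 = sum_i (y_model_i - y_data_i)^2 / sigma_i^2

over the n_t time points, with sigma the standard error among biological
replicates.  The cost minimised over a group of m conditions is the negative
log-likelihood  logL = sum_j R_j^2 / 2.

Optimisation uses bounded least squares (Trust Region Reflective) on the
stacked weighted residuals with the analytic Jacobian from the forward
sensitivity equations, repeated from random multi-starts (log-uniform over a
broad range around nominal values) and ranked by final cost.  A joint mode
shares kinetic parameters (V_A, K_A, r by default) across compounds while the
observation scalings c1, c0 and the effective doses stay compound-specific.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import ks_2samp

from .model import ModelParameters, ModelVariant, ParameterDomainError
from .preprocess import calibration_sigma
from .simulate import ATOL, RTOL, IntegrationError, simulate_sensitivities

__all__ = [
    "FitCondition",
    "CompoundData",
    "FitProblem",
    "FitResult",
    "weighted_ssr",
    "total_cost",
    "fit_multistart",
    "fit_joint",
    "refit",
    "compare_classes",
    "problem_from_summary",
    "DEFAULT_BOUNDS",
]

logger = logging.getLogger(__name__)

#: broad default box constraints; D0 entries fall back to the "D0" entry
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "supply": (1e-3, 1e2),
    "K_E": (1e-3, 1e3),
    "K_Ei": (1e-4, 1e4),
    "C_f": (1e-3, 1e3),
    "V_A": (1e-3, 1e3),
    "K_A": (1e-4, 1e4),
    "K_Ai": (1e-4, 1e4),
    "V_U": (1e-3, 1e3),
    "K_U": (1e-4, 1e4),
    "r": (1e-3, 1e2),
    "c1": (1e-4, 1e3),
    "c0": (-10.0, 10.0),
    "alpha": (1e-6, 1e3),
    "gamma": (1e-6, 20.0),
    "gamma_L": (1e-6, 20.0),
    "gamma_H": (1e-6, 20.0),
    "D0": (1e-8, 1e5),
}

PENALTY_COST = 1e10


@dataclass
class FitCondition:
    """Observed trajectory for one dose index, with calibration weights."""

    dose_index: int
    times: np.ndarray
    y: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not (len(self.times) == len(self.y) == len(self.sigma)):
            raise ValueError("times, y and sigma must share length")
        if np.any(self.sigma <= 0) or not np.all(np.isfinite(self.sigma)):
            raise ValueError("sigma must be strictly positive (apply the SE floor first)")


@dataclass
class CompoundData:
    """All conditions of one compound, with its variant and nominal parameters."""

    name: str
    variant: ModelVariant
    base_params: ModelParameters
    conditions: list[FitCondition]

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ValueError(f"compound {self.name!r} has no conditions")
        for cond in self.conditions:
            if not (0 <= cond.dose_index < len(self.base_params.D0)):
                raise ValueError(
                    f"dose_index {cond.dose_index} outside D0 (len {len(self.base_params.D0)})"
                )


@dataclass
class FitProblem:
    """A (possibly multi-compound) calibration problem.

    ``free_names`` may contain the shorthand ``"D0"`` which expands to all
    dose entries of each compound.  ``shared`` lists the free parameters
    constrained to a single value across compounds (ignored for a single
    compound); everything else is estimated per compound.
    """

    compounds: list[CompoundData]
    free_names: Sequence[str]
    shared: Sequence[str] = ()
    bounds: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    n_starts: int = 100
    seed: int = 0
    rtol: float = RTOL
    atol: float = ATOL
    max_nfev: int = 150
    mxstep: int = 500

    def __post_init__(self) -> None:
        if not self.compounds:
            raise ValueError("problem needs at least one compound")
        if not self.free_names:
            raise ValueError("free_names must be non-empty")
        bad = set(self.shared) - set(self.free_names)
        if bad:
            raise ValueError(f"shared names {sorted(bad)} are not free parameters")
        if "D0" in self.shared:
            raise ValueError("effective doses cannot be shared across compounds")
        for name, (lo, hi) in self.bound_map().items():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"bounds for {name} must be finite with low < high")

    def bound_map(self) -> dict[str, tuple[float, float]]:
        return {**DEFAULT_BOUNDS, **dict(self.bounds)}

    def local_names(self, ci: int) -> list[str]:
        """Free parameter names for compound ``ci`` (D0 shorthand expanded)."""
        out: list[str] = []
        for name in self.free_names:
            if name == "D0":
                out.extend(f"D0_{j}" for j in range(len(self.compounds[ci].base_params.D0)))
            else:
                out.append(name)
        return out


class _Layout:
    """Mapping between the global parameter vector and per-compound parameters."""

    def __init__(self, problem: FitProblem):
        self.problem = problem
        multi = len(problem.compounds) > 1
        shared = set(problem.shared) if multi else set()
        self.global_names: list[str] = []
        self.index: dict[tuple[int, str], int] = {}
        for name in problem.free_names:
            if name != "D0" and name in shared:
                gi = len(self.global_names)
                self.global_names.append(name)
                for ci in range(len(problem.compounds)):
                    self.index[(ci, name)] = gi
        for ci, comp in enumerate(problem.compounds):
            prefix = f"{comp.name}:" if multi else ""
            for name in problem.local_names(ci):
                if (ci, name) in self.index:
                    continue
                self.index[(ci, name)] = len(self.global_names)
                self.global_names.append(prefix + name)
        self.n = len(self.global_names)

    def local_to_global(self, ci: int, local_names: Sequence[str]) -> np.ndarray:
        return np.array([self.index[(ci, n)] for n in local_names], dtype=int)

    def params_for(self, ci: int, theta: np.ndarray) -> ModelParameters:
        names = self.problem.local_names(ci)
        values = theta[self.local_to_global(ci, names)]
        return self.problem.compounds[ci].base_params.with_values(names, values)

    def nominal(self) -> np.ndarray:
        x0 = np.empty(self.n)
        for ci in range(len(self.problem.compounds)):
            base = self.problem.compounds[ci].base_params
            for name in self.problem.local_names(ci):
                x0[self.index[(ci, name)]] = base.get(name)
        return x0

    def bounds_vectors(self) -> tuple[np.ndarray, np.ndarray]:
        bm = self.problem.bound_map()
        lo = np.empty(self.n)
        hi = np.empty(self.n)
        for (ci, name), gi in self.index.items():
            b = bm.get(name) or (bm["D0"] if name.startswith("D0_") else None)
            if b is None:
                raise KeyError(f"no bounds for parameter {name}")
            lo[gi], hi[gi] = b
        # a positive MMP steady state needs V_A > supply*C_f; when supply and
        # C_f are fixed this is a hard feasibility edge worth encoding
        for ci, comp in enumerate(self.problem.compounds):
            local = self.problem.local_names(ci)
            if "V_A" in local and "supply" not in local and "C_f" not in local:
                gi = self.index[(ci, "V_A")]
                base = comp.base_params
                lo[gi] = max(lo[gi], 1.001 * base.supply * base.C_f)
        return lo, hi


class _Objective:
    """Stacked weighted residuals and analytic Jacobian, with last-point cache."""

    def __init__(self, problem: FitProblem):
        self.problem = problem
        self.layout = _Layout(problem)
        self.n_res = sum(
            len(c.times) for comp in problem.compounds for c in comp.conditions
        )
        self._cache_key: bytes | None = None
        self._cache: tuple[np.ndarray, np.ndarray] | None = None

    def _evaluate(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        prob = self.problem
        res = np.empty(self.n_res)
        jac = np.zeros((self.n_res, self.layout.n))
        row = 0
        for ci, comp in enumerate(prob.compounds):
            local = prob.local_names(ci)
            cols = self.layout.local_to_global(ci, local)
            params = self.layout.params_for(ci, theta)
            for cond in comp.conditions:
                traj, dy = simulate_sensitivities(
                    comp.variant, params, cond.dose_index, cond.times, local,
                    rtol=prob.rtol, atol=prob.atol, mxstep=prob.mxstep,
                )
                k = len(cond.times)
                res[row : row + k] = (traj.y - cond.y) / cond.sigma
                jac[row : row + k, cols] = dy / cond.sigma[:, None]
                row += k
        return res, jac

    def _penalty(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        # keeps TRF inside the feasible basin when integration blows up
        lo, hi = self.layout.bounds_vectors()
        mid = 0.5 * (lo + hi)
        pos = (lo > 0) & (hi > 0)
        mid[pos] = np.sqrt(lo[pos] * hi[pos])
        reg = float(np.sum(np.log1p(np.abs(theta - mid))))
        val = np.sqrt(2.0 * (PENALTY_COST + reg) / self.n_res)
        return np.full(self.n_res, val), np.zeros((self.n_res, self.layout.n))

    def _get(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        key = theta.tobytes()
        if key != self._cache_key:
            try:
                self._cache = self._evaluate(theta)
            except (IntegrationError, ParameterDomainError):
                logger.warning("integration failure at theta=%s; penalty applied", theta)
                self._cache = self._penalty(theta)
            self._cache_key = key
        return self._cache

    def fun(self, theta: np.ndarray) -> np.ndarray:
        return self._get(theta)[0]

    def jac(self, theta: np.ndarray) -> np.ndarray:
        return self._get(theta)[1]

    def cost(self, theta: np.ndarray) -> float:
        r = self.fun(theta)
        return 0.5 * float(r @ r)


@dataclass
class FitResult:
    """Outcome of a (multi-start) calibration."""

    theta_names: list[str]
    theta_hat: np.ndarray
    cost: float
    params: dict[str, ModelParameters]
    per_condition_R2: pd.DataFrame
    start_trace: list[tuple[float, bool]]
    n_converged: int
    seed: int
    grad: np.ndarray | None = None  # cost gradient at theta_hat (warm refits)

    def as_dict(self) -> dict:
        return {
            "cost": self.cost,
            "theta": dict(zip(self.theta_names, map(float, self.theta_hat))),
            "n_converged": self.n_converged,
            "seed": self.seed,
            "start_costs": [c for c, _ in self.start_trace],
        }


def weighted_ssr(y_model, y_data, sigma) -> float:
    """Weighted sum of squared residuals R^2 for one condition."""
    y_model = np.asarray(y_model, dtype=float)
    y_data = np.asarray(y_data, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if not (y_model.shape == y_data.shape == sigma.shape):
        raise ValueError("series length mismatch")
    if np.any(sigma <= 0):
        raise ValueError("sigma must be strictly positive")
    return float(np.sum(((y_model - y_data) / sigma) ** 2))


def total_cost(theta, problem: FitProblem) -> float:
    """Negative log-likelihood sum_j R_j^2 / 2 at a global parameter vector."""
    obj = _Objective(problem)
    return obj.cost(np.asarray(theta, dtype=float))


def _sample_starts(layout: _Layout, rng: np.random.Generator, n_starts: int) -> np.ndarray:
    """Log-uniform starts over ~4 decades around nominal values (linear for c0)."""
    lo, hi = layout.bounds_vectors()
    nominal = layout.nominal()
    starts = np.empty((n_starts, layout.n))
    for k, gname in enumerate(layout.global_names):
        name = gname.split(":")[-1]
        nom = nominal[k]
        if name == "c0" or nom <= 0 or lo[k] <= 0:
            a, b = max(lo[k], nom - 1.0), min(hi[k], nom + 1.0)
            starts[:, k] = rng.uniform(a, b, n_starts)
        else:
            a = max(lo[k], nom / 100.0)
            b = min(hi[k], nom * 100.0)
            starts[:, k] = np.exp(rng.uniform(np.log(a), np.log(b), n_starts))
    return starts


def _single_fit(obj: _Objective, x0: np.ndarray, lo: np.ndarray, hi: np.ndarray):
    return least_squares(
        obj.fun, np.clip(x0, lo, hi), jac=obj.jac, bounds=(lo, hi),
        method="trf", ftol=1e-10, xtol=1e-10, gtol=1e-10,
        max_nfev=obj.problem.max_nfev,
    )


def _result_from(obj: _Objective, theta: np.ndarray, cost: float, trace, n_conv, seed,
                 grad=None) -> FitResult:
    layout = obj.layout
    prob = obj.problem
    rows = []
    params = {}
    for ci, comp in enumerate(prob.compounds):
        p = layout.params_for(ci, theta)
        params[comp.name] = p
        for cond in comp.conditions:
            from .simulate import simulate

            traj = simulate(comp.variant, p, cond.dose_index, cond.times, prob.rtol, prob.atol)
            rows.append(
                {
                    "compound": comp.name,
                    "dose_index": cond.dose_index,
                    "R2": weighted_ssr(traj.y, cond.y, cond.sigma),
                }
            )
    return FitResult(
        theta_names=layout.global_names,
        theta_hat=theta,
        cost=cost,
        params=params,
        per_condition_R2=pd.DataFrame(rows),
        start_trace=trace,
        n_converged=n_conv,
        seed=seed,
        grad=grad,
    )


def fit_multistart(problem: FitProblem) -> FitResult:
    """Bounded TRF least squares from ``n_starts`` random starting points.

    Starts are sampled log-uniformly over a broad range around the nominal
    (base) parameter values; the reported optimum is the best converged cost,
    with exact ties broken towards the lexicographically smallest parameter
    vector for determinism.
    """
    obj = _Objective(problem)
    lo, hi = obj.layout.bounds_vectors()
    rng = np.random.default_rng(problem.seed)
    starts = _sample_starts(obj.layout, rng, problem.n_starts)

    trace: list[tuple[float, bool]] = []
    best: tuple[float, np.ndarray] | None = None
    n_conv = 0
    for x0 in starts:
        try:
            sol = _single_fit(obj, x0, lo, hi)
        except Exception as exc:  # numerical blow-up in an unlucky basin
            logger.warning("start failed: %s", exc)
            trace.append((np.inf, False))
            continue
        trace.append((float(sol.cost), bool(sol.success)))
        if sol.success:
            n_conv += 1
        if not np.isfinite(sol.cost):
            continue
        if (
            best is None
            or sol.cost < best[0] * (1 - 1e-12)
            or (abs(sol.cost - best[0]) <= 1e-12 * max(1.0, best[0]) and tuple(sol.x) < tuple(best[1]))
        ):
            best = (float(sol.cost), sol.x.copy())
    if best is None:
        raise RuntimeError("no multistart optimisation converged")
    if n_conv < 0.5 * problem.n_starts:
        logger.warning("only %d/%d starts converged", n_conv, problem.n_starts)
    return _result_from(obj, best[1], best[0], trace, n_conv, problem.seed)


def refit(problem: FitProblem, x0: np.ndarray) -> FitResult:
    """Single warm-started fit (used by profiling and bootstrap resampling)."""
    obj = _Objective(problem)
    lo, hi = obj.layout.bounds_vectors()
    sol = _single_fit(obj, np.asarray(x0, dtype=float), lo, hi)
    return _result_from(obj, sol.x, float(sol.cost), [(float(sol.cost), bool(sol.success))],
                        int(sol.success), problem.seed, grad=sol.grad)


def fit_joint(
    compound_problems: Sequence[FitProblem],
    shared: Sequence[str] = ("V_A", "K_A", "r"),
) -> FitResult:
    """Joint fit across compounds with shared kinetic parameters.

    Each input problem must contain a single compound and the same free
    parameter set; observation scalings and effective doses remain
    compound-specific.  With one input this reduces to ``fit_multistart``.
    """
    if not compound_problems:
        raise ValueError("need at least one compound problem")
    first = compound_problems[0]
    for p in compound_problems[1:]:
        if list(p.free_names) != list(first.free_names):
            raise ValueError("all compounds must share the same free parameter set")
    merged = FitProblem(
        compounds=[c for p in compound_problems for c in p.compounds],
        free_names=first.free_names,
        shared=tuple(shared) if len(compound_problems) > 1 else (),
        bounds=first.bounds,
        n_starts=first.n_starts,
        seed=first.seed,
        rtol=first.rtol,
        atol=first.atol,
        max_nfev=first.max_nfev,
        mxstep=first.mxstep,
    )
    return fit_multistart(merged)


def compare_classes(costs_by_class: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Pairwise two-sample two-sided KS tests on per-compound fit costs.

    Exact p-values for small samples.  Returns one row per class pair.
    """
    for cls, vals in costs_by_class.items():
        if len(vals) == 0:
            raise ValueError(f"class {cls!r} is empty")
    rows = []
    for a, b in combinations(sorted(costs_by_class), 2):
        xa = np.asarray(costs_by_class[a], dtype=float)
        xb = np.asarray(costs_by_class[b], dtype=float)
        method = "exact" if max(len(xa), len(xb)) <= 25 else "auto"
        stat = ks_2samp(xa, xb, alternative="two-sided", method=method)
        rows.append({"class_a": a, "class_b": b,
                     "D": float(stat.statistic), "p_value": float(stat.pvalue)})
    return pd.DataFrame(rows)


def problem_from_summary(
    summary: pd.DataFrame,
    compound: str,
    variant: ModelVariant,
    base_params: ModelParameters,
    free_names: Sequence[str] = ("V_A", "K_A", "D0", "c1", "c0", "r"),
    sigma_floor_frac: float = 0.05,
    **kwargs,
) -> FitProblem:
    """Build a single-compound FitProblem from a condition-summary table.

    Concentrations are ordered ascending to define the dose index; if the
    template's D0 is empty, the applied concentrations serve as nominal
    effective doses.
    """
    sel = summary[summary["compound"] == compound]
    if sel.empty:
        raise KeyError(f"compound {compound!r} not in summary")
    sigma = calibration_sigma(sel, sigma_floor_frac)
    concs = np.sort(sel["concentration_um"].unique())
    if len(base_params.D0) == 0:
        base_params = replace(base_params, D0=tuple(max(float(c), 1e-6) for c in concs))
    elif len(base_params.D0) != len(concs):
        raise ValueError("base_params.D0 length must match the number of concentrations")
    conditions = []
    for j, conc in enumerate(concs):
        mask = np.isclose(sel["concentration_um"], conc)
        rows = sel[mask].sort_values("time_h")
        conditions.append(
            FitCondition(
                dose_index=j,
                times=rows["time_h"].to_numpy(dtype=float),
                y=rows["mean_norm"].to_numpy(dtype=float),
                sigma=sigma[rows.index].to_numpy(dtype=float),
            )
        )
    comp = CompoundData(compound, variant, base_params, conditions)
    return FitProblem(compounds=[comp], free_names=list(free_names), **kwargs)
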