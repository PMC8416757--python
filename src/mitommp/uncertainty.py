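"""Uncertainty quantification: profile likelihood, hierarchical bootstrap, PK ratios.

Profile likelihood (PL): the negative profile likelihood NPL(v) is twice the
re-optimised cost with one parameter (or derived quantity) fixed at v.  The
confidence interval is the set where NPL stays below
``min(NPL) + chi2(confidence, df=1)``; a parameter whose NPL never rises above
that threshold on either side is structurally non-identifiable there.

Bootstrap: two-level resampling mirroring the experimental design — plates
(biological replicates) are resampled with replacement, then within each
selected plate the pooled single cells of each condition x time point are
resampled with replacement, the preprocessing chain is re-applied and the
model re-fitted warm-started at the original MLE.  Quantile CIs (95/99%) are
taken over the bootstrap estimates.

The effective concentration decays exponentially, so the predicted compound
ratio between two measurement times is ``R_T2/T1 = exp(-gamma * (T2 - T1))``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import chi2

from .calibrate import (
    FitProblem,
    FitResult,
    _Objective,
    fit_multistart,
    problem_from_summary,
    refit,
)
from .preprocess import summarize

__all__ = [
    "ProfileCurve",
    "BootstrapResult",
    "DerivedQuantity",
    "pl_threshold",
    "profile_parameter",
    "profile_derived",
    "predict_ratio",
    "predict_ratios",
    "ratio_ci_from_gamma_ci",
    "bootstrap_ci",
    "compare_measured_ratios",
    "DEFAULT_RATIO_PAIRS",
]

logger = logging.getLogger(__name__)

DEFAULT_RATIO_PAIRS = ((2.0, 8.0), (2.0, 24.0), (8.0, 24.0))


def pl_threshold(confidence: float) -> float:
    """chi-squared quantile with one degree of freedom at the given confidence."""
    if not 0 < confidence < 1:
        raise ValueError("confidence must lie in (0, 1)")
    return float(chi2.ppf(confidence, df=1))


@dataclass
class ProfileCurve:
    """NPL curve of one profiled quantity with its threshold-cut CI."""

    profiled_name: str
    values: np.ndarray
    npl: np.ndarray
    delta: float
    mle_value: float
    npl_min: float
    ci_low: float | None
    ci_high: float | None
    identifiable: bool
    degenerate: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"value": self.values, "npl": self.npl})


def _interp_crossing(v0, n0, v1, n1, level) -> float:
    # linear interpolation of the threshold crossing between two grid points
    if n1 == n0:
        return v1
    return v0 + (level - n0) * (v1 - v0) / (n1 - n0)


def _walk_profile(
    refit_at: Callable[[float, np.ndarray], tuple[float, np.ndarray, bool]],
    v_mle: float,
    theta_mle: np.ndarray,
    cost_mle: float,
    delta: float,
    step: float,
    max_decades: float,
    max_points: int,
    lo: float,
    hi: float,
    refine_iters: int = 6,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Adaptive outward walk from the MLE with warm-started refits.

    ``refit_at(v, warm) -> (cost, theta, blocked)`` re-optimises the nuisance
    parameters with the profiled quantity fixed at ``v``; ``blocked`` reports
    a nuisance pinned at a box bound with a descent direction beyond it.
    Multiplicative steps for a positive MLE value, additive otherwise.  Each
    side walks until the NPL exceeds ``2*cost_mle + delta`` (then the crossing
    is refined by bisection), until the configured decade range, or until hard
    bounds.  A crossing reached with a blocked nuisance signals a compensation
    direction truncated by bounds, not by data information, and leaves that
    side open.
    """
    level = 2.0 * cost_mle + delta
    multiplicative = v_mle > 0
    points: list[tuple[float, float]] = [(v_mle, 2.0 * cost_mle)]
    sides: dict[str, dict] = {}
    for direction, label in ((-1, "low"), (+1, "high")):
        theta = theta_mle.copy()
        v = v_mle
        below = (v_mle, 2.0 * cost_mle, theta_mle.copy(), False)
        bracket = None
        for _ in range(max_points):
            if multiplicative:
                v = v * step if direction > 0 else v / step
                if abs(np.log10(v / v_mle)) > max_decades:
                    break
            else:
                v = v + direction * 0.3 * max(abs(v_mle), 1.0)
            if not (lo <= v <= hi):
                break
            cost, theta, sat = refit_at(v, theta)
            if not np.isfinite(cost):
                logger.warning("profile refit failed at value %g; point flagged", v)
                continue
            npl = 2.0 * cost
            points.append((v, npl))
            if npl > level:
                bracket = (below, (v, npl, theta.copy(), sat))
                break
            below = (v, npl, theta.copy(), sat)
        ci = None
        bound_limited = False
        if bracket is not None:
            a, b = bracket
            for _ in range(refine_iters):
                vm = float(np.sqrt(a[0] * b[0])) if multiplicative else 0.5 * (a[0] + b[0])
                cm, thm, sm = refit_at(vm, a[2])
                if not np.isfinite(cm):
                    break
                nm = 2.0 * cm
                points.append((vm, nm))
                if nm > level:
                    b = (vm, nm, thm.copy(), sm)
                else:
                    a = (vm, nm, thm.copy(), sm)
            bound_limited = a[3] or b[3]
            if not bound_limited:
                ci = _interp_crossing(a[0], a[1], b[0], b[1], level)
        sides[label] = {"ci": ci, "crossed": bracket is not None,
                        "bound_limited": bound_limited}
    points.sort()
    values = np.array([p[0] for p in points])
    npl = np.array([p[1] for p in points])
    return values, npl, sides


def _curve_from(name, values, npl, sides, delta, v_mle, cost_mle) -> ProfileCurve:
    npl_min = min(float(np.min(npl)), 2.0 * cost_mle)
    ci_low = sides["low"]["ci"]
    ci_high = sides["high"]["ci"]
    return ProfileCurve(
        profiled_name=name,
        values=values,
        npl=npl,
        delta=delta,
        mle_value=v_mle,
        npl_min=npl_min,
        ci_low=ci_low,
        ci_high=ci_high,
        identifiable=(ci_low is not None and ci_high is not None),
    )


def _bound_blocked(theta: np.ndarray, grad, lo: np.ndarray, hi: np.ndarray,
                   gtol: float = 0.1) -> bool:
    """True when a box bound actively blocks a cost-descent direction.

    A nuisance parameter sitting at a bound only invalidates a profile
    crossing if the cost would keep decreasing beyond the bound (a truncated
    compensation direction).  A flat, incidentally pinned nuisance has a
    vanishing gradient and is harmless.  Gradients are compared on the
    log scale for positive parameters.
    """
    if grad is None:
        return False
    pos = lo > 0
    span = hi - lo
    near_lo = np.where(pos, theta <= lo * 1.0001, theta - lo < 1e-6 * span)
    near_hi = np.where(pos, theta >= hi * 0.9999, hi - theta < 1e-6 * span)
    scale = np.where(pos, np.maximum(np.abs(theta), 1e-8), np.maximum(np.abs(theta), 1.0))
    g = grad * scale
    return bool(np.any((near_hi & (g < -gtol)) | (near_lo & (g > gtol))))


def _flat_names(problem: FitProblem) -> list[str]:
    return problem.local_names(0)


def profile_parameter(
    problem: FitProblem,
    name: str,
    search_range: tuple[float, float] | None = None,
    fit: FitResult | None = None,
    confidence: float = 0.95,
    step: float = 1.3,
    max_decades: float = 6.0,
    max_points: int = 80,
) -> ProfileCurve:
    """Profile one free parameter of a single-compound problem.

    The parameter is fixed on an adaptive grid walking outward from the MLE
    (at most ``max_decades`` each way, clipped to ``search_range`` when
    given); all remaining free parameters are re-optimised at each grid
    value, warm-started from the neighbouring solution.
    """
    if len(problem.compounds) != 1:
        raise ValueError("profiling is defined for single-compound problems")
    flat = _flat_names(problem)
    if name not in flat:
        raise KeyError(f"{name!r} is not a free parameter of the problem")
    if fit is None:
        fit = fit_multistart(problem)
    delta = pl_threshold(confidence)
    comp = problem.compounds[0]
    mle_params = fit.params[comp.name]
    v_mle = mle_params.get(name)
    keep = [n for n in flat if n != name]
    idx_keep = [fit.theta_names.index(n) for n in keep]
    theta_red_mle = fit.theta_hat[idx_keep]

    bm = problem.bound_map()
    lo, hi = bm.get(name) or bm["D0"]
    if search_range is not None:
        lo, hi = max(lo, search_range[0]), min(hi, search_range[1])

    def sub_at(v: float) -> FitProblem:
        base = mle_params.with_values([name], [v])
        return FitProblem(
            compounds=[type(comp)(comp.name, comp.variant, base, comp.conditions)],
            free_names=keep,
            bounds=problem.bounds,
            n_starts=1,
            seed=problem.seed,
            rtol=problem.rtol,
            atol=problem.atol,
            max_nfev=problem.max_nfev,
            mxstep=problem.mxstep,
        )

    from .calibrate import _Layout

    rlo, rhi = _Layout(sub_at(v_mle)).bounds_vectors()

    def refit_at(v: float, warm: np.ndarray) -> tuple[float, np.ndarray, bool]:
        try:
            fr = refit(sub_at(v), warm)
            return fr.cost, fr.theta_hat, _bound_blocked(fr.theta_hat, fr.grad, rlo, rhi)
        except Exception as exc:
            logger.warning("profile refit at %s=%g failed: %s", name, v, exc)
            return np.inf, warm, False

    values, npl, sides = _walk_profile(
        refit_at, v_mle, theta_red_mle, fit.cost, delta, step, max_decades, max_points, lo, hi
    )
    return _curve_from(name, values, npl, sides, delta, v_mle, fit.cost)


@dataclass
class DerivedQuantity:
    """A scalar function of the model parameters to be profiled.

    ``func`` maps a ModelParameters to the quantity.  If the quantity is
    invertible in a single parameter, ``invert = (param_name, g)`` with
    ``g(value, params) -> param_value`` enables profiling by substitution;
    otherwise a quadratic-penalty constraint with escalating weight is used.
    """

    name: str
    func: Callable[..., float]
    invert: tuple[str, Callable[..., float]] | None = None


def profile_derived(
    problem: FitProblem,
    quantity: DerivedQuantity,
    fit: FitResult | None = None,
    confidence: float = 0.95,
    step: float = 1.3,
    max_decades: float = 6.0,
    max_points: int = 80,
) -> ProfileCurve:
    """Profile a derived quantity via substitution or quadratic penalty."""
    if len(problem.compounds) != 1:
        raise ValueError("profiling is defined for single-compound problems")
    if fit is None:
        fit = fit_multistart(problem)
    comp = problem.compounds[0]
    mle_params = fit.params[comp.name]
    q_mle = float(quantity.func(mle_params))
    delta = pl_threshold(confidence)
    flat = _flat_names(problem)

    if quantity.invert is not None:
        pname, g = quantity.invert
        if pname not in flat:
            raise KeyError(f"inversion parameter {pname!r} is not free")
        keep = [n for n in flat if n != pname]
        idx_keep = [fit.theta_names.index(n) for n in keep]
        theta_red_mle = fit.theta_hat[idx_keep]
        bm = problem.bound_map()
        plo, phi = bm.get(pname) or bm["D0"]

        def sub_at(pv: float) -> FitProblem:
            base = mle_params.with_values([pname], [pv])
            return FitProblem(
                compounds=[type(comp)(comp.name, comp.variant, base, comp.conditions)],
                free_names=keep,
                bounds=problem.bounds,
                n_starts=1,
                seed=problem.seed,
                rtol=problem.rtol,
                atol=problem.atol,
                max_nfev=problem.max_nfev,
                mxstep=problem.mxstep,
            )

        from .calibrate import _Layout

        rlo, rhi = _Layout(sub_at(mle_params.get(pname))).bounds_vectors()

        def refit_at(qv: float, warm: np.ndarray) -> tuple[float, np.ndarray, bool]:
            try:
                pv = float(g(qv, mle_params))
            except (ValueError, ZeroDivisionError, FloatingPointError):
                return np.inf, warm, False
            if not np.isfinite(pv) or not (plo <= pv <= phi):
                return np.inf, warm, False
            try:
                fr = refit(sub_at(pv), warm)
                return fr.cost, fr.theta_hat, _bound_blocked(fr.theta_hat, fr.grad, rlo, rhi)
            except Exception:
                return np.inf, warm, False

        values, npl, sides = _walk_profile(
            refit_at, q_mle, theta_red_mle, fit.cost, delta, step, max_decades, max_points,
            -np.inf, np.inf,
        )
        return _curve_from(quantity.name, values, npl, sides, delta, q_mle, fit.cost)

    # penalty route
    obj = _Objective(problem)
    layout = obj.layout

    def q_of_theta(theta: np.ndarray) -> float:
        return float(quantity.func(layout.params_for(0, theta)))

    # detect a (locally) constant quantity
    grad = _fd_gradient(q_of_theta, fit.theta_hat)
    if np.max(np.abs(grad)) < 1e-12:
        logger.warning("derived quantity %s is locally constant; degenerate profile", quantity.name)
        return ProfileCurve(
            profiled_name=quantity.name,
            values=np.array([q_mle]),
            npl=np.array([2.0 * fit.cost]),
            delta=delta,
            mle_value=q_mle,
            npl_min=2.0 * fit.cost,
            ci_low=None,
            ci_high=None,
            identifiable=False,
            degenerate=True,
        )

    lo, hi = layout.bounds_vectors()

    def refit_at(qv: float, warm: np.ndarray) -> tuple[float, np.ndarray, bool]:
        theta = warm.copy()
        weight = 1e4
        tol = 1e-6 * max(abs(qv), 1.0)
        for _ in range(7):
            sw = np.sqrt(2.0 * weight)

            def fun(th):
                return np.concatenate([obj.fun(th), [sw * (q_of_theta(th) - qv)]])

            def jac(th):
                row = sw * _fd_gradient(q_of_theta, th)
                return np.vstack([obj.jac(th), row])

            try:
                sol = least_squares(fun, np.clip(theta, lo, hi), jac=jac, bounds=(lo, hi),
                                    method="trf", x_scale="jac",
                                    ftol=1e-10, xtol=1e-10, gtol=1e-10)
            except Exception:
                return np.inf, warm, False
            theta = sol.x
            if abs(q_of_theta(theta) - qv) <= tol:
                grad_cost = obj.jac(theta).T @ obj.fun(theta)
                return obj.cost(theta), theta, _bound_blocked(theta, grad_cost, lo, hi)
            weight *= 10.0
        return np.inf, warm, False

    keep_theta = fit.theta_hat.copy()
    values, npl, sides = _walk_profile(
        refit_at, q_mle, keep_theta, fit.cost, delta, step, max_decades, max_points,
        -np.inf, np.inf,
    )
    return _curve_from(quantity.name, values, npl, sides, delta, q_mle, fit.cost)


def _fd_gradient(f: Callable[[np.ndarray], float], x: np.ndarray, rel: float = 1e-6) -> np.ndarray:
    g = np.zeros_like(x)
    for k in range(len(x)):
        h = rel * max(abs(x[k]), 1e-8)
        xp, xm = x.copy(), x.copy()
        xp[k] += h
        xm[k] -= h
        g[k] = (f(xp) - f(xm)) / (2.0 * h)
    return g


def predict_ratio(gamma: float, T1: float, T2: float) -> float:
    """Predicted compound ratio between times T2 and T1: exp(-gamma*(T2-T1))."""
    if T1 < 0 or T2 < T1:
        raise ValueError("need T2 >= T1 >= 0")
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    return float(np.exp(-gamma * (T2 - T1)))


def predict_ratios(gamma: float, pairs=DEFAULT_RATIO_PAIRS) -> dict[str, float]:
    """Ratios for the default measurement pairs (2,8), (2,24), (8,24) h."""
    return {f"R_{int(t2)}h_vs_{int(t1)}h": predict_ratio(gamma, t1, t2) for t1, t2 in pairs}


def ratio_ci_from_gamma_ci(
    gamma_ci: tuple[float | None, float | None], T1: float, T2: float
) -> tuple[float, float]:
    """Propagate a gamma CI to the ratio (monotone decreasing transform).

    Open-ended gamma bounds map to the natural ratio limits (0 below, 1 above,
    since gamma >= 0).
    """
    g_lo, g_hi = gamma_ci
    r_hi = predict_ratio(max(g_lo, 0.0), T1, T2) if g_lo is not None else 1.0
    r_lo = predict_ratio(g_hi, T1, T2) if g_hi is not None else 0.0
    return r_lo, r_hi


@dataclass
class BootstrapResult:
    """Bootstrap estimates with quantile CIs (bounds are order statistics)."""

    estimates: pd.DataFrame
    ci95: dict[str, tuple[float, float]]
    ci99: dict[str, tuple[float, float]]
    n_boot: int
    seed: int
    n_failed: int

    def ecdf(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        x = np.sort(self.estimates[name].to_numpy())
        return x, np.arange(1, len(x) + 1) / len(x)


def _quantile_ci(x: np.ndarray, level: float) -> tuple[float, float]:
    a = (1.0 - level) / 2.0
    return (
        float(np.quantile(x, a, method="lower")),
        float(np.quantile(x, 1.0 - a, method="higher")),
    )


def _resample_cells(cells: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Two-level resample: plates with replacement, then cells within each
    pooled condition x time point of every selected plate."""
    plates = np.sort(cells["plate_id"].unique())
    drawn = rng.choice(plates, size=len(plates), replace=True)
    group_cache: dict = {}
    pieces = []
    new_ids = []
    for b, plate in enumerate(drawn):
        if plate not in group_cache:
            sub = cells[cells["plate_id"] == plate]
            group_cache[plate] = (
                sub,
                sub.groupby(["compound", "concentration_um", "time_h"], sort=True).indices,
            )
        sub, groups = group_cache[plate]
        take = []
        for key in sorted(groups):
            idx = groups[key]
            take.append(idx[rng.integers(0, len(idx), len(idx))])
        take = np.concatenate(take)
        pieces.append(sub.iloc[take])
        new_ids.append(np.full(len(take), f"bs{b}", dtype=object))
    out = pd.concat(pieces, ignore_index=True)
    out["plate_id"] = np.concatenate(new_ids)
    return out


def bootstrap_ci(
    cells: pd.DataFrame,
    problem: FitProblem,
    n_boot: int = 200,
    seed: int = 0,
    mle: FitResult | None = None,
    sigma_floor_frac: float = 0.05,
    multistart: bool = False,
) -> BootstrapResult:
    """Hierarchical (inter-/intra-plate) bootstrap CIs for the fitted parameters.

    Each bootstrap sample is preprocessed exactly like the original data and
    re-fitted warm-started at the original MLE (a full multistart per sample
    is available behind ``multistart=True`` for robustness studies).  Samples
    whose refit fails are logged and redrawn, capped at ``2 * n_boot`` draws.
    """
    if len(problem.compounds) != 1:
        raise ValueError("bootstrap operates on single-compound problems")
    comp = problem.compounds[0]
    if mle is None:
        mle = fit_multistart(problem)
    rng = np.random.default_rng(seed)
    rows: list[dict[str, float]] = []
    n_failed = 0
    attempts = 0
    while len(rows) < n_boot and attempts < 2 * n_boot:
        attempts += 1
        sample = _resample_cells(cells, rng)
        try:
            summary = summarize(sample)
            prob_b = problem_from_summary(
                summary, comp.name, comp.variant, mle.params[comp.name],
                free_names=problem.free_names, sigma_floor_frac=sigma_floor_frac,
                bounds=problem.bounds, n_starts=problem.n_starts, seed=problem.seed,
                rtol=problem.rtol, atol=problem.atol,
            )
            fr = fit_multistart(prob_b) if multistart else refit(prob_b, mle.theta_hat)
            if not np.isfinite(fr.cost):
                raise RuntimeError("non-finite refit cost")
        except Exception as exc:
            n_failed += 1
            logger.warning("bootstrap sample failed (%s); redrawing", exc)
            continue
        rows.append(dict(zip(fr.theta_names, map(float, fr.theta_hat))))
    if len(rows) < n_boot:
        raise RuntimeError(
            f"only {len(rows)}/{n_boot} bootstrap samples succeeded within the redraw cap"
        )
    est = pd.DataFrame(rows)
    ci95 = {c: _quantile_ci(est[c].to_numpy(), 0.95) for c in est.columns}
    ci99 = {c: _quantile_ci(est[c].to_numpy(), 0.99) for c in est.columns}
    return BootstrapResult(est, ci95, ci99, n_boot, seed, n_failed)


def compare_measured_ratios(
    predicted_ratio: float,
    intervals: Mapping[str, tuple[float, float]],
    measured: Sequence[float] = (),
) -> dict:
    """Check externally measured compound ratios against model CIs.

    ``intervals`` maps labels (e.g. 'pl_95', 'boot_95') to (low, high) CIs of
    the predicted ratio.  Reports each measured replicate ratio, their mean,
    and whether the mean falls inside each interval; with some intervals
    containing the mean and others not, the overall flag is 'mixed'.
    """
    measured = [float(m) for m in measured]
    if any(m <= 0 for m in measured):
        raise ValueError("measured ratios must be > 0")
    report: dict = {
        "predicted_ratio": float(predicted_ratio),
        "measured": measured,
        "measured_mean": float(np.mean(measured)) if measured else None,
        "inside": {},
        "flag": "prediction_only",
    }
    if measured:
        mean = report["measured_mean"]
        inside = {
            label: bool(lo <= mean <= hi) for label, (lo, hi) in intervals.items()
        }
        report["inside"] = inside
        if not intervals:
            report["flag"] = "no_intervals"
        elif all(inside.values()):
            report["flag"] = "consistent"
        elif any(inside.values()):
            report["flag"] = "mixed"
        else:
            report["flag"] = "outside"
    return report
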