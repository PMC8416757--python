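"""Tests of profile likelihood, derived-quantity profiling, PK ratios and the
hierarchical bootstrap."""

import numpy as np
import pandas as pd
import pytest

from conftest import build_problem
from mitommp.calibrate import refit
from mitommp.model import ModelParameters, ModelVariant
from mitommp.synth import CompoundDesign, ExperimentDesign, generate_experiment
from mitommp.uncertainty import (
    DerivedQuantity,
    _curve_from,
    _walk_profile,
    bootstrap_ci,
    compare_measured_ratios,
    pl_threshold,
    predict_ratio,
    predict_ratios,
    profile_derived,
    profile_parameter,
    ratio_ci_from_gamma_ci,
)


class TestPlThreshold:
    def test_small_confidence_gives_small_threshold(self):
        assert pl_threshold(1e-6) < 1e-5

    def test_chi2_quantiles(self):
        assert pl_threshold(0.95) == pytest.approx(3.8415, abs=1e-3)
        assert pl_threshold(0.99) == pytest.approx(6.6349, abs=1e-3)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 2.0])
    def test_domain(self, bad):
        with pytest.raises(ValueError):
            pl_threshold(bad)


class TestProfileEngineLinearGaussian:
    """The walking/refinement engine against a closed-form least-squares CI."""

    def test_ci_matches_analytic_interval(self):
        rng = np.random.default_rng(8)
        t = np.arange(1.0, 24.0)
        sigma = 0.2
        theta_true = 1.3
        y = theta_true * t + rng.normal(0, sigma, len(t))
        sum_t2 = np.sum(t**2)
        theta_hat = np.sum(t * y) / sum_t2
        se_theta = sigma / np.sqrt(sum_t2)

        def cost(th):
            return 0.5 * np.sum((th * t - y) ** 2) / sigma**2

        def refit_at(v, warm):
            return cost(v), warm, False

        delta = pl_threshold(0.95)
        values, npl, sides = _walk_profile(
            refit_at, theta_hat, np.array([]), cost(theta_hat), delta,
            step=1.3, max_decades=6, max_points=80, lo=-np.inf, hi=np.inf,
        )
        curve = _curve_from("slope", values, npl, sides, delta, theta_hat, cost(theta_hat))
        assert curve.identifiable
        assert curve.ci_low == pytest.approx(theta_hat - 1.96 * se_theta, rel=0.01)
        assert curve.ci_high == pytest.approx(theta_hat + 1.96 * se_theta, rel=0.01)


@pytest.fixture(scope="module")
def decay_problem_and_fit(uncoupler_truth):
    variant = ModelVariant("pk_decay", "uncoupler")
    problem = build_problem(
        uncoupler_truth, variant, ["V_A", "K_A", "c1", "c0", "gamma", "D0"],
        noise_sd=0.01, sigma=0.01, seed=11, n_starts=3,
    )
    x0 = np.array([uncoupler_truth.get(n) for n in problem.local_names(0)])
    fit = refit(problem, x0)
    return problem, fit


class TestProfileParameter:
    def test_npl_minimum_is_twice_best_cost(self, decay_problem_and_fit):
        problem, fit = decay_problem_and_fit
        curve = profile_parameter(problem, "gamma", fit=fit)
        assert curve.npl_min == pytest.approx(2.0 * fit.cost, rel=1e-6)
        assert np.all(curve.npl >= curve.npl_min - 1e-6)

    def test_gamma_profile_is_identifiable_around_the_mle(self, decay_problem_and_fit):
        problem, fit = decay_problem_and_fit
        curve = profile_parameter(problem, "gamma", fit=fit)
        assert curve.identifiable
        assert curve.ci_low < curve.mle_value < curve.ci_high
        # the data are informative: the CI is a narrow band around the MLE
        assert (curve.ci_high - curve.ci_low) / curve.mle_value < 0.5

    def test_unknown_name_rejected(self, decay_problem_and_fit):
        problem, fit = decay_problem_and_fit
        with pytest.raises(KeyError):
            profile_parameter(problem, "K_U", fit=fit)


class TestProfileDerived:
    def test_identity_quantity_matches_parameter_profile(self, decay_problem_and_fit):
        problem, fit = decay_problem_and_fit
        base = profile_parameter(problem, "gamma", fit=fit)
        ident = DerivedQuantity(
            "gamma_identity",
            func=lambda p: p.gamma,
            invert=("gamma", lambda v, p: v),
        )
        derived = profile_derived(problem, ident, fit=fit)
        assert derived.ci_low == pytest.approx(base.ci_low, rel=1e-6)
        assert derived.ci_high == pytest.approx(base.ci_high, rel=1e-6)

    def test_monotone_transform_equivariance(self, decay_problem_and_fit):
        # the 24h/2h ratio is exp(-22*gamma): its profile CI must be the
        # transform of the gamma profile CI (in reversed order)
        problem, fit = decay_problem_and_fit
        gamma_curve = profile_parameter(problem, "gamma", fit=fit)
        ratio = DerivedQuantity(
            "ratio_24_2",
            func=lambda p: float(np.exp(-22.0 * p.gamma)),
            invert=("gamma", lambda v, p: -np.log(v) / 22.0),
        )
        rcurve = profile_derived(problem, ratio, fit=fit)
        assert rcurve.identifiable
        assert rcurve.ci_low == pytest.approx(np.exp(-22.0 * gamma_curve.ci_high), rel=0.02)
        assert rcurve.ci_high == pytest.approx(np.exp(-22.0 * gamma_curve.ci_low), rel=0.02)

    def test_penalty_route_agrees_with_substitution(self, decay_problem_and_fit):
        problem, fit = decay_problem_and_fit
        with_invert = profile_derived(
            problem,
            DerivedQuantity("g", lambda p: p.gamma, invert=("gamma", lambda v, p: v)),
            fit=fit,
        )
        penalty = profile_derived(
            problem, DerivedQuantity("g", lambda p: p.gamma), fit=fit
        )
        assert penalty.ci_low == pytest.approx(with_invert.ci_low, rel=0.05)
        assert penalty.ci_high == pytest.approx(with_invert.ci_high, rel=0.05)

    def test_constant_quantity_is_degenerate(self, decay_problem_and_fit):
        problem, fit = decay_problem_and_fit
        curve = profile_derived(problem, DerivedQuantity("const", lambda p: 42.0), fit=fit)
        assert curve.degenerate
        assert not curve.identifiable


class TestPredictRatio:
    def test_equal_times(self):
        assert predict_ratio(0.3, 5.0, 5.0) == 1.0

    def test_no_decay(self):
        assert predict_ratio(0.0, 2.0, 24.0) == 1.0

    def test_hand_computed(self):
        assert predict_ratio(0.1, 2.0, 24.0) == pytest.approx(np.exp(-2.2))

    def test_domain(self):
        with pytest.raises(ValueError):
            predict_ratio(0.1, 8.0, 2.0)
        with pytest.raises(ValueError):
            predict_ratio(-0.1, 2.0, 8.0)

    def test_default_pairs(self):
        out = predict_ratios(0.1)
        assert set(out) == {"R_8h_vs_2h", "R_24h_vs_2h", "R_24h_vs_8h"}
        assert out["R_24h_vs_2h"] == pytest.approx(out["R_8h_vs_2h"] * out["R_24h_vs_8h"])

    def test_gamma_ci_propagation(self):
        lo, hi = ratio_ci_from_gamma_ci((0.05, 0.2), 2.0, 24.0)
        assert lo == pytest.approx(np.exp(-0.2 * 22))
        assert hi == pytest.approx(np.exp(-0.05 * 22))
        lo_open, hi_open = ratio_ci_from_gamma_ci((None, None), 2.0, 24.0)
        assert (lo_open, hi_open) == (0.0, 1.0)


def _uncoupler_cells(sigma_log, seed=13, gamma=0.15):
    params = ModelParameters(D0=(1.0, 6.0), gamma=gamma, c1=0.9, c0=0.1)
    comp = CompoundDesign(
        name="fccp_like",
        variant=ModelVariant("pk_decay", "uncoupler"),
        params=params,
        concentrations=(1.0, 6.0),
    )
    design = ExperimentDesign(
        compounds=[comp], n_plates=2, n_tech=2, n_dmso_wells=1,
        cells_per_well=30, cells_dispersion=None, sigma_log=sigma_log,
        plate_scale_jitter=0.02,
    )
    cells, truth = generate_experiment(design, seed=seed)
    return cells, params, comp.variant


def _problem_for(cells, params, variant):
    from mitommp.calibrate import problem_from_summary
    from mitommp.preprocess import summarize

    return problem_from_summary(
        summarize(cells), "fccp_like", variant, params,
        free_names=["gamma", "c1", "c0"], n_starts=2, seed=1,
    )


class TestBootstrap:
    def test_zero_variance_single_plate_gives_zero_width_ci(self):
        cells, params, variant = _uncoupler_cells(sigma_log=0.0)
        cells = cells[cells["plate_id"] == "plate0"]
        problem = _problem_for(cells, params, variant)
        x0 = np.array([params.get(n) for n in problem.local_names(0)])
        mle = refit(problem, x0)
        boot = bootstrap_ci(cells, problem, n_boot=5, seed=2, mle=mle)
        for name, (lo, hi) in boot.ci95.items():
            assert hi - lo == pytest.approx(0.0, abs=1e-12), name

    def test_ci_nesting_and_content(self):
        cells, params, variant = _uncoupler_cells(sigma_log=0.3)
        problem = _problem_for(cells, params, variant)
        x0 = np.array([params.get(n) for n in problem.local_names(0)])
        mle = refit(problem, x0)
        boot = bootstrap_ci(cells, problem, n_boot=15, seed=3, mle=mle)
        assert len(boot.estimates) == 15
        for name in boot.ci95:
            l95, h95 = boot.ci95[name]
            l99, h99 = boot.ci99[name]
            assert l99 <= l95 <= h95 <= h99
        x, f = boot.ecdf("gamma")
        assert len(x) == 15 and f[-1] == 1.0

    def test_wider_cell_noise_weakly_widens_gamma_ci(self):
        widths = {}
        for sig in (0.1, 0.6):
            cells, params, variant = _uncoupler_cells(sigma_log=sig, seed=13)
            problem = _problem_for(cells, params, variant)
            x0 = np.array([params.get(n) for n in problem.local_names(0)])
            mle = refit(problem, x0)
            boot = bootstrap_ci(cells, problem, n_boot=12, seed=4, mle=mle)
            lo, hi = boot.ci95["gamma"]
            widths[sig] = hi - lo
        assert widths[0.6] >= widths[0.1]

    def test_order_preserving_plate_relabeling_is_neutral(self):
        cells, params, variant = _uncoupler_cells(sigma_log=0.3)
        problem = _problem_for(cells, params, variant)
        x0 = np.array([params.get(n) for n in problem.local_names(0)])
        mle = refit(problem, x0)
        a = bootstrap_ci(cells, problem, n_boot=6, seed=5, mle=mle)
        relabeled = cells.assign(
            plate_id=cells["plate_id"].map({"plate0": "rep_A", "plate1": "rep_B"})
        )
        b = bootstrap_ci(relabeled, problem, n_boot=6, seed=5, mle=mle)
        pd.testing.assert_frame_equal(a.estimates, b.estimates)


class TestCompareMeasuredRatios:
    def test_consistent(self):
        rep = compare_measured_ratios(0.5, {"pl_95": (0.3, 0.7)}, [0.45, 0.55])
        assert rep["flag"] == "consistent"
        assert rep["inside"]["pl_95"]

    def test_mixed_mirrors_narrow_pl_wide_bootstrap(self):
        rep = compare_measured_ratios(
            0.5, {"pl_95": (0.45, 0.55), "boot_95": (0.1, 0.9)}, [0.2, 0.3]
        )
        assert rep["flag"] == "mixed"
        assert not rep["inside"]["pl_95"]
        assert rep["inside"]["boot_95"]

    def test_outside(self):
        rep = compare_measured_ratios(0.5, {"pl_95": (0.4, 0.6)}, [0.05])
        assert rep["flag"] == "outside"

    def test_prediction_only_without_measurements(self):
        rep = compare_measured_ratios(0.5, {"pl_95": (0.4, 0.6)}, [])
        assert rep["flag"] == "prediction_only"
        assert rep["measured_mean"] is None

    def test_non_positive_measurement_rejected(self):
        with pytest.raises(ValueError):
            compare_measured_ratios(0.5, {}, [0.2, -0.1])
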