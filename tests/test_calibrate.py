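"""Tests of the likelihood, multi-start estimation, joint fitting and the
KS comparison of fit quality between inhibitor classes."""

from itertools import combinations

import numpy as np
import pytest

from conftest import build_problem
from mitommp.calibrate import (
    FitProblem,
    compare_classes,
    fit_joint,
    fit_multistart,
    refit,
    total_cost,
    weighted_ssr,
)
from mitommp.model import ModelParameters, ModelVariant


class TestWeightedSsr:
    def test_perfect_match_is_zero(self):
        y = np.linspace(0.5, 1.0, 23)
        assert weighted_ssr(y, y, np.full(23, 0.1)) == 0.0

    def test_unit_standardized_residuals(self):
        y = np.zeros(23)
        assert weighted_ssr(y + 0.1, y, np.full(23, 0.1)) == pytest.approx(23.0)

    def test_hand_computed(self):
        ym = np.array([1.1, 0.8])
        yd = np.array([1.0, 1.0])
        s = np.array([0.1, 0.1])
        assert weighted_ssr(ym, yd, s) == pytest.approx(5.0)

    def test_validation(self):
        with pytest.raises(ValueError):
            weighted_ssr([1.0], [1.0, 2.0], [0.1, 0.1])
        with pytest.raises(ValueError):
            weighted_ssr([1.0], [1.0], [0.0])


class TestTotalCost:
    def test_zero_at_truth_on_noiseless_data(self, small_etc_problem):
        truth, problem = small_etc_problem
        theta = np.array([truth.get(n) for n in problem.local_names(0)])
        assert total_cost(theta, problem) < 1e-10

    def test_equals_half_sum_of_condition_ssr(self, small_etc_problem):
        truth, problem = small_etc_problem
        names = problem.local_names(0)
        theta = np.array([truth.get(n) for n in names])
        # perturb one kinetic parameter so the residuals are non-trivial
        theta[names.index("V_A")] *= 1.15
        from mitommp.simulate import simulate

        perturbed = truth.with_values(["V_A"], [theta[names.index("V_A")]])
        manual = 0.0
        for cond in problem.compounds[0].conditions:
            y = simulate(problem.compounds[0].variant, perturbed, cond.dose_index, cond.times).y
            manual += weighted_ssr(y, cond.y, cond.sigma)
        assert total_cost(theta, problem) == pytest.approx(manual / 2.0, rel=1e-6)


class TestFitMultistart:
    def test_warm_start_at_truth_stays_at_truth(self, small_etc_problem):
        truth, problem = small_etc_problem
        names = problem.local_names(0)
        x0 = np.array([truth.get(n) for n in names])
        fr = refit(problem, x0)
        assert fr.cost < 1e-10
        rel = np.abs(fr.theta_hat - x0) / np.maximum(np.abs(x0), 1e-12)
        assert np.linalg.norm(rel) < 1e-4

    def test_small_multistart_recovers_truth(self):
        truth = ModelParameters(K_E=0.05, K_Ei=0.2, D0=(0.1, 1.0), c1=0.9, c0=0.1)
        problem = build_problem(
            truth, ModelVariant("basic", "etc_inhibitor"), ["V_A", "K_A", "c1"],
            n_starts=12, seed=21,
        )
        fr = fit_multistart(problem)
        assert fr.cost < 1e-8
        for name in ("V_A", "K_A", "c1"):
            assert fr.params["cmpd"].get(name) == pytest.approx(truth.get(name), rel=1e-3)

    def test_result_invariants(self, small_etc_problem):
        _, problem = small_etc_problem
        fr = fit_multistart(problem)
        finite = [c for c, _ in fr.start_trace if np.isfinite(c)]
        assert fr.cost == pytest.approx(min(finite), rel=1e-9)
        assert fr.cost == pytest.approx(fr.per_condition_R2["R2"].sum() / 2.0, rel=1e-6, abs=1e-9)
        assert len(fr.start_trace) == problem.n_starts


class TestFitJoint:
    def test_single_compound_reduces_to_multistart(self, small_etc_problem):
        _, problem = small_etc_problem
        a = fit_multistart(problem)
        b = fit_joint([problem])
        assert b.cost == pytest.approx(a.cost, rel=1e-12)
        np.testing.assert_allclose(a.theta_hat, b.theta_hat, rtol=1e-12)

    def test_joint_fit_shares_kinetics_and_nests_separate_fits(self):
        variant = ModelVariant("basic", "etc_inhibitor")
        shared = dict(V_A=1.4, K_A=0.8, r=1.0, K_E=0.05, K_Ei=0.2)
        t1 = ModelParameters(D0=(0.02, 0.2, 2.0), c1=1.0, c0=0.0, **shared)
        t2 = ModelParameters(D0=(0.01, 0.12, 1.2), c1=0.7, c0=0.3, **shared)
        free = ["V_A", "K_A", "r", "c1", "c0", "D0"]
        probs = [
            build_problem(t1, variant, free, noise_sd=5e-4, sigma=5e-4, seed=4,
                          name="cmpdA", n_starts=4, max_nfev=400),
            build_problem(t2, variant, free, noise_sd=5e-4, sigma=5e-4, seed=5,
                          name="cmpdB", n_starts=4, max_nfev=400),
        ]
        joint = fit_joint(probs, shared=("V_A", "K_A", "r"))
        # shared kinetic parameters recovered near truth
        for name, true_val in (("V_A", 1.4), ("K_A", 0.8), ("r", 1.0)):
            gi = joint.theta_names.index(name)
            assert joint.theta_hat[gi] == pytest.approx(true_val, rel=0.02)
        # nested-model inequality against separate fits
        separate = sum(fit_multistart(p).cost for p in probs)
        assert joint.cost >= separate - 1e-6


class TestCompareClasses:
    def test_identical_samples(self):
        out = compare_classes({"I": [1.0, 2.0, 3.0], "II": [1.0, 2.0, 3.0]})
        row = out.iloc[0]
        assert row["D"] == 0.0
        assert row["p_value"] == pytest.approx(1.0)

    def test_disjoint_samples_match_permutation_oracle(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        out = compare_classes({"I": a, "II": b})
        assert out.iloc[0]["D"] == pytest.approx(1.0)
        assert out.iloc[0]["p_value"] == pytest.approx(_permutation_p(a, b), abs=1e-12)

    def test_random_small_samples_match_permutation_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            a = list(rng.normal(0, 1, 4))
            b = list(rng.normal(0.5, 1, 5))
            out = compare_classes({"x": a, "y": b})
            assert out.iloc[0]["p_value"] == pytest.approx(_permutation_p(a, b), abs=1e-9)

    def test_scale_invariance(self):
        a, b = [1.0, 2.0, 5.0], [1.5, 3.0, 4.0]
        d1 = compare_classes({"I": a, "II": b}).iloc[0]["D"]
        d2 = compare_classes({"I": [2 * x for x in a], "II": [2 * x for x in b]}).iloc[0]["D"]
        assert d1 == d2

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            compare_classes({"I": [1.0], "II": []})

    def test_three_classes_give_three_pairs(self):
        out = compare_classes({"I": [1.0, 2.0], "II": [2.0, 3.0], "III": [0.5, 1.5]})
        assert len(out) == 3


def _ks_stat(a, b):
    pooled = np.sort(np.concatenate([a, b]))
    fa = np.searchsorted(np.sort(a), pooled, side="right") / len(a)
    fb = np.searchsorted(np.sort(b), pooled, side="right") / len(b)
    return np.max(np.abs(fa - fb))


def _permutation_p(a, b):
    """Exhaustive two-sample KS p-value over all label assignments."""
    pooled = np.array(list(a) + list(b))
    n_a = len(a)
    d_obs = _ks_stat(np.array(a), np.array(b))
    count = total = 0
    for idx in combinations(range(len(pooled)), n_a):
        mask = np.zeros(len(pooled), bool)
        mask[list(idx)] = True
        d = _ks_stat(pooled[mask], pooled[~mask])
        count += d >= d_obs - 1e-12
        total += 1
    return count / total
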