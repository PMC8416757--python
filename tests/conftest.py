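"""Shared fixtures: compact synthetic calibration problems with known truth."""

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from mitommp.calibrate import CompoundData, FitCondition, FitProblem
from mitommp.model import ModelParameters, ModelVariant
from mitommp.simulate import simulate


def build_problem(
    truth: ModelParameters,
    variant: ModelVariant,
    free_names,
    times=None,
    noise_sd: float = 0.0,
    sigma: float | None = None,
    seed: int = 0,
    name: str = "cmpd",
    nominal: ModelParameters | None = None,
    **problem_kw,
):
    """Simulate every dose of ``truth`` and wrap the series as a FitProblem.

    ``sigma`` is the reported SE used for weighting (defaults to 5% of the
    mean signal, the preprocessing floor); ``noise_sd`` adds seeded Gaussian
    noise to the observations.
    """
    times = np.arange(1.0, 24.0) if times is None else np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)
    conditions = []
    for j in range(len(truth.D0)):
        y = simulate(variant, truth, j, times).y
        sig = np.full_like(y, sigma if sigma is not None else 0.05 * np.mean(np.abs(y)))
        if noise_sd > 0:
            y = y + rng.normal(0.0, noise_sd, size=len(y))
        conditions.append(FitCondition(j, times, y, sig))
    base = truth if nominal is None else nominal
    comp = CompoundData(name, variant, base, conditions)
    return FitProblem(compounds=[comp], free_names=list(free_names), **problem_kw)


@pytest.fixture
def small_etc_problem():
    """Three-dose noiseless ETC-inhibitor problem, nominal = truth."""
    truth = ModelParameters(K_E=0.05, K_Ei=0.2, D0=(0.02, 0.2, 2.0),
                            V_A=1.2, K_A=1.0, c1=0.9, c0=0.1)
    variant = ModelVariant("basic", "etc_inhibitor")
    return truth, build_problem(truth, variant, ["V_A", "K_A", "D0", "c1", "c0", "r"],
                                n_starts=5, seed=3)


@pytest.fixture(scope="session")
def uncoupler_truth():
    return ModelParameters(D0=(0.5, 2.0, 8.0), gamma=0.15, c1=0.9, c0=0.1)
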