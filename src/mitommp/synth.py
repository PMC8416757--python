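"""Synthetic single-cell Rho123 imaging datasets with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes: per-well log-normal single-cell intensity distributions, plate-level
multiplicative dye drift (quenching plus a transient uptake bump) shared by
treated and DMSO wells on the same plate, per-plate/compound scale jitter of
the observation map (the compound-specific baseline scatter of normalized
intensities), 3-4 biological replicate plates with technical replicate wells,
and hourly sampling over 23 time points.  Treated-well signals follow the ODE
model trajectories through the linear observation map.

Per-cell intensities are drawn log-normally with *median* equal to the well
signal, so the well geometric mean is an unbiased estimate of the signal on
the log scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .model import ModelParameters, ModelVariant
from .simulate import DEFAULT_TIMES, simulate

__all__ = ["CompoundDesign", "ExperimentDesign", "generate_experiment", "make_paper_like_panels"]


@dataclass
class CompoundDesign:
    """One compound: its true parameters, variant and applied concentrations."""

    name: str
    variant: ModelVariant
    params: ModelParameters
    concentrations: tuple[float, ...]

    def __post_init__(self) -> None:
        self.concentrations = tuple(float(c) for c in self.concentrations)
        if any(b <= a for a, b in zip(self.concentrations, self.concentrations[1:])):
            raise ValueError("applied concentrations must be strictly ascending")
        if len(self.concentrations) != len(self.params.D0):
            raise ValueError("concentrations and true effective doses D0 must align")

    @property
    def baseline_signal(self) -> float:
        return self.params.c1 * self.params.psi_o + self.params.c0


@dataclass
class ExperimentDesign:
    """Design of a synthetic imaging experiment."""

    compounds: list[CompoundDesign]
    n_plates: int = 4
    n_tech: int = 2
    n_dmso_wells: int = 2
    cells_per_well: int = 300
    cells_dispersion: float | None = 20.0  # negative-binomial size; None = fixed count
    times: np.ndarray = field(default_factory=lambda: DEFAULT_TIMES.copy())
    sigma_log: float = 0.5  # log-scale SD of single-cell intensities
    plate_scale_jitter: float = 0.10  # per plate x compound jitter of the observation map
    quench_range: tuple[float, float] = (0.01, 0.04)  # 1/h, plate dye quenching
    drift_base_range: tuple[float, float] = (0.9, 1.1)
    uptake_amp_range: tuple[float, float] = (0.0, 0.05)
    uptake_tau_range: tuple[float, float] = (2.0, 6.0)
    drift_fns: Sequence[Callable[[np.ndarray], np.ndarray]] | None = None  # per-plate override

    def __post_init__(self) -> None:
        if not self.compounds:
            raise ValueError("design needs at least one compound")
        if min(self.n_plates, self.n_tech, self.n_dmso_wells, self.cells_per_well) < 1:
            raise ValueError("all counts must be >= 1")
        if self.sigma_log < 0 or self.plate_scale_jitter < 0:
            raise ValueError("noise levels must be >= 0")


def _draw_drift(design: ExperimentDesign, rng: np.random.Generator, plate: int,
                times: np.ndarray) -> np.ndarray:
    if design.drift_fns is not None:
        d = np.asarray(design.drift_fns[plate](times), dtype=float)
    else:
        base = rng.uniform(*design.drift_base_range)
        q = rng.uniform(*design.quench_range)
        amp = rng.uniform(*design.uptake_amp_range)
        tau = rng.uniform(*design.uptake_tau_range)
        d = base * np.exp(-q * times) * (1.0 + amp * times * np.exp(-times / tau))
    if np.any(d <= 0):
        raise ValueError("plate drift must be strictly positive")
    return d


def _cell_counts(design: ExperimentDesign, rng: np.random.Generator, n: int) -> np.ndarray:
    if design.cells_dispersion is None:
        return np.full(n, design.cells_per_well, dtype=np.int64)
    r = design.cells_dispersion
    m = design.cells_per_well
    counts = rng.negative_binomial(r, r / (r + m), size=n)
    return np.maximum(counts, 1)


def generate_experiment(design: ExperimentDesign, seed: int) -> tuple[pd.DataFrame, dict]:
    """Generate a single-cell table plus the ground-truth record.

    Identical seeds yield byte-identical tables.  The truth record stores the
    true parameters, the noise-free normalized trajectories per condition, the
    per-plate drift curves and the per-plate/compound scale jitters.
    """
    rng = np.random.default_rng(seed)
    times = np.asarray(design.times, dtype=float)
    n_t = len(times)

    # noise-free normalized trajectories per compound x dose
    y_true: dict[tuple[str, float], np.ndarray] = {}
    for comp in design.compounds:
        for j, conc in enumerate(comp.concentrations):
            traj = simulate(comp.variant, comp.params, j, times)
            y_true[(comp.name, conc)] = traj.y

    baseline = float(np.mean([c.baseline_signal for c in design.compounds]))

    cols: dict[str, list] = {k: [] for k in (
        "plate_id", "well_id", "compound", "concentration_um", "time_h",
        "cell_id", "intensity", "is_control",
    )}
    drift_rec: dict[str, np.ndarray] = {}
    jitter_rec: dict[tuple[str, str], float] = {}

    def emit(plate_id, well_id, compound, conc, signal_t, is_control):
        counts = _cell_counts(design, rng, n_t)
        total = int(counts.sum())
        noise = rng.standard_normal(total) * design.sigma_log if design.sigma_log > 0 else np.zeros(total)
        cols["plate_id"].append(np.full(total, plate_id, dtype=object))
        cols["well_id"].append(np.full(total, well_id, dtype=object))
        cols["compound"].append(np.full(total, compound, dtype=object))
        cols["concentration_um"].append(np.full(total, conc))
        cols["time_h"].append(np.repeat(times, counts))
        cols["cell_id"].append(np.arange(total, dtype=np.int64))
        cols["intensity"].append(np.repeat(signal_t, counts) * np.exp(noise))
        cols["is_control"].append(np.full(total, is_control, dtype=bool))

    for p in range(design.n_plates):
        plate_id = f"plate{p}"
        drift = _draw_drift(design, rng, p, times)
        drift_rec[plate_id] = drift
        for comp in design.compounds:
            j_scale = design.plate_scale_jitter
            scale = 1.0 + rng.uniform(-j_scale, j_scale) if j_scale > 0 else 1.0
            jitter_rec[(plate_id, comp.name)] = scale
            for conc in comp.concentrations:
                signal = drift * scale * y_true[(comp.name, conc)]
                for w in range(design.n_tech):
                    emit(plate_id, f"{plate_id}:{comp.name}:{conc:g}:w{w}",
                         comp.name, conc, signal, False)
        for w in range(design.n_dmso_wells):
            emit(plate_id, f"{plate_id}:DMSO:w{w}", "DMSO", 0.0, drift * baseline, True)

    cells = pd.DataFrame({k: np.concatenate(v) for k, v in cols.items()})
    truth = {
        "seed": seed,
        "params": {c.name: c.params for c in design.compounds},
        "variants": {c.name: c.variant for c in design.compounds},
        "concentrations": {c.name: c.concentrations for c in design.compounds},
        "y_true": y_true,
        "times": times,
        "drift": drift_rec,
        "plate_compound_scale": jitter_rec,
        "baseline_signal": baseline,
    }
    return cells, truth


def _geom_space(lo: float, hi: float, n: int) -> tuple[float, ...]:
    return tuple(float(v) for v in np.geomspace(lo, hi, n))


def make_paper_like_panels(seed: int = 0) -> dict[str, dict]:
    """Three canned study designs mirroring the classical inhibitor panels.

    ``etc``: rotenone-style ETC inhibition, basic variant, 10 concentrations,
    4 plates.  ``uncoupler``: FCCP-style uncoupling with pharmacokinetic decay,
    4 plates.  ``atp_synthase``: oligomycin-style hyperpolarisation with
    concentration-dependent decay (fast at the 4 lowest doses), 8
    concentrations, 3 plates.  Returns per panel the design, a generated
    single-cell table and the ground-truth record.
    """
    common = dict(V_A=1.2, K_A=1.0, C_f=1.0, r=1.0, c1=0.9, c0=0.1)

    # slow oxygen turnover (small K_E) keeps the MMP decrease effectively
    # monotone over the 23 h window, as observed for ETC inhibitors
    etc_conc = _geom_space(0.002, 2.0, 10)
    etc = CompoundDesign(
        name="rotenone_like",
        variant=ModelVariant("basic", "etc_inhibitor"),
        params=ModelParameters(K_E=0.02, K_Ei=0.2, D0=etc_conc, **common),
        concentrations=etc_conc,
    )

    unc_conc = _geom_space(0.02, 10.0, 8)
    unc = CompoundDesign(
        name="fccp_like",
        variant=ModelVariant("pk_decay", "uncoupler"),
        params=ModelParameters(gamma=0.1, D0=unc_conc, **common),
        concentrations=unc_conc,
    )

    oli_conc = tuple(0.0125 * 2.0**k for k in range(8))  # 0.0125 .. 1.6 uM
    oli = CompoundDesign(
        name="oligomycin_like",
        variant=ModelVariant("conc_dep_decay", "atp_synthase_inhibitor", n_low=4),
        params=ModelParameters(K_Ai=0.05, gamma_L=0.6, gamma_H=0.04, D0=oli_conc, **common),
        concentrations=oli_conc,
    )

    panels = {}
    for offset, (key, comp, n_plates) in enumerate(
        (("etc", etc, 4), ("uncoupler", unc, 4), ("atp_synthase", oli, 3))
    ):
        design = ExperimentDesign(
            compounds=[comp],
            n_plates=n_plates,
            cells_per_well=120,
            cells_dispersion=None,
            sigma_log=0.4,
        )
        cells, truth = generate_experiment(design, seed=seed + 101 * (offset + 1))
        panels[key] = {"design": design, "cells": cells, "truth": truth}
    return panels
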