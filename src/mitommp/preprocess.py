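"""From single-cell Rho123 intensity tables to normalized condition trajectories.

Single-cell integrated intensities within a well are approximately log-normal,
so the per-well summary is the geometric mean.  Plate-specific dye artefacts
(quenching, uptake drift) multiply treated and vehicle wells alike, so
dividing each treated geometric mean by the same-plate, same-time-point DMSO
geometric mean cancels them exactly.  Normalized per-plate trajectories are
then averaged across biological replicates (plates), reporting the arithmetic
mean and the standard error of the mean.

Expected single-cell table columns::

    plate_id, well_id, compound, concentration_um, time_h, cell_id,
    intensity, is_control
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ConditionSeries",
    "well_geometric_mean",
    "normalize_to_control",
    "aggregate_replicates",
    "summarize",
    "calibration_sigma",
]

logger = logging.getLogger(__name__)

CELL_COLUMNS = [
    "plate_id",
    "well_id",
    "compound",
    "concentration_um",
    "time_h",
    "cell_id",
    "intensity",
    "is_control",
]


@dataclass
class ConditionSeries:
    """DMSO-normalized mean +/- SE trajectory for one compound x concentration."""

    compound: str
    concentration_um: float
    times: np.ndarray
    mean_norm_y: np.ndarray
    se_norm_y: np.ndarray
    n_replicates: int

    def __post_init__(self) -> None:
        n = len(self.times)
        if not (len(self.mean_norm_y) == len(self.se_norm_y) == n):
            raise ValueError("times, mean and SE series must share length")


def well_geometric_mean(intensities) -> float:
    """exp(mean(log)) of a collection of strictly positive intensities."""
    x = np.asarray(intensities, dtype=float)
    if x.size == 0:
        raise ValueError("empty intensity collection")
    if np.any(x <= 0) or not np.all(np.isfinite(x)):
        raise ValueError("geometric mean requires strictly positive, finite intensities")
    return float(np.exp(np.mean(np.log(x))))


def normalize_to_control(treated, control) -> np.ndarray:
    """Elementwise treated/control ratio on an aligned per-plate time grid."""
    treated = np.asarray(treated, dtype=float)
    control = np.asarray(control, dtype=float)
    if treated.shape != control.shape:
        raise ValueError("treated and control series must be aligned on the same grid")
    if np.any(~np.isfinite(control)) or np.any(control <= 0):
        raise ValueError("control series must be strictly positive at every time point")
    return treated / control


def aggregate_replicates(replicates) -> tuple[np.ndarray, np.ndarray, int]:
    """Mean and SE across replicate series.

    ``replicates`` is an (N, n_t) array-like of normalized per-plate series.
    Returns (mean, se, N); with a single replicate the SE is NaN (flagged
    unavailable, to be floored downstream).
    """
    arr = np.asarray(replicates, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 1:
        raise ValueError("need at least one replicate series of equal length")
    n = arr.shape[0]
    mean = arr.mean(axis=0)
    if n >= 2:
        se = arr.std(axis=0, ddof=1) / np.sqrt(n)
    else:
        se = np.full(arr.shape[1], np.nan)
    return mean, se, n


def summarize(cells: pd.DataFrame) -> pd.DataFrame:
    """Full preprocessing chain: cells -> condition-summary table.

    Technical-replicate wells of the same condition on a plate are pooled
    before the geometric mean; cells with non-positive or missing intensity
    are dropped (count logged).  Output columns: compound, concentration_um,
    time_h, mean_norm, se_norm, n_rep.
    """
    missing = [c for c in CELL_COLUMNS if c not in cells.columns]
    if missing:
        raise ValueError(f"single-cell table lacks columns {missing}")
    bad = ~(cells["intensity"] > 0) | ~np.isfinite(cells["intensity"])
    if bad.any():
        logger.warning("dropping %d cells with non-positive or missing intensity", int(bad.sum()))
        cells = cells.loc[~bad]

    logs = cells.assign(log_i=np.log(cells["intensity"].to_numpy(dtype=float)))

    ctrl = (
        logs[logs["is_control"]]
        .groupby(["plate_id", "time_h"], sort=True)["log_i"]
        .mean()
        .rename("log_ctrl")
    )
    if ctrl.empty:
        raise ValueError("no control (DMSO) wells present")

    treated = (
        logs[~logs["is_control"]]
        .groupby(["plate_id", "compound", "concentration_um", "time_h"], sort=True)["log_i"]
        .mean()
        .rename("log_treated")
        .reset_index()
    )
    merged = treated.merge(ctrl.reset_index(), on=["plate_id", "time_h"], how="left")
    if merged["log_ctrl"].isna().any():
        missing_pt = merged.loc[merged["log_ctrl"].isna(), ["plate_id", "time_h"]]
        raise ValueError(
            "missing DMSO control for plate/time combinations: "
            f"{missing_pt.drop_duplicates().to_dict('records')[:5]}"
        )
    merged["norm"] = np.exp(merged["log_treated"] - merged["log_ctrl"])

    out = (
        merged.groupby(["compound", "concentration_um", "time_h"], sort=True)["norm"]
        .agg(mean_norm="mean", sd="std", n_rep="count")
        .reset_index()
    )
    out["se_norm"] = out["sd"] / np.sqrt(out["n_rep"])
    out.loc[out["n_rep"] < 2, "se_norm"] = np.nan
    return out.drop(columns="sd")


def calibration_sigma(summary: pd.DataFrame, floor_frac: float = 0.05) -> pd.Series:
    """Weights for the calibration residuals, with a floor on degenerate SEs.

    Where the SE is zero or unavailable (single replicate), it is replaced by
    ``floor_frac`` times the condition's mean signal, keeping the weighted
    residuals finite.
    """
    if floor_frac <= 0:
        raise ValueError("floor_frac must be > 0")
    sigma = summary["se_norm"].to_numpy(dtype=float).copy()
    cond_mean = (
        summary.groupby(["compound", "concentration_um"])["mean_norm"].transform("mean").abs()
    )
    floor = floor_frac * cond_mean.to_numpy(dtype=float)
    degenerate = ~np.isfinite(sigma) | (sigma <= 0)
    sigma[degenerate] = floor[degenerate]
    return pd.Series(sigma, index=summary.index, name="sigma")


def condition_series(summary: pd.DataFrame, compound: str, concentration_um: float) -> ConditionSeries:
    """Extract one condition's trajectory from a summary table."""
    sel = summary[
        (summary["compound"] == compound)
        & np.isclose(summary["concentration_um"], concentration_um)
    ].sort_values("time_h")
    if sel.empty:
        raise KeyError(f"no rows for {compound} at {concentration_um} uM")
    return ConditionSeries(
        compound=compound,
        concentration_um=float(concentration_um),
        times=sel["time_h"].to_numpy(dtype=float),
        mean_norm_y=sel["mean_norm"].to_numpy(dtype=float),
        se_norm_y=sel["se_norm"].to_numpy(dtype=float),
        n_replicates=int(sel["n_rep"].min()),
    )
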