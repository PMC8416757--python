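"""Orchestration: generate -> preprocess -> fit -> profile/bootstrap -> ratios.

Each stage reads its inputs from the output directory (or from the previous
stage in memory), writes tabular artifacts as CSV and structured results as
JSON, and records a manifest with the configuration, seeds, package version
and SHA-256 checksums of every artifact.  Given identical configuration and
seed the run is deterministic, so manifests are reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibrate import FitProblem, fit_multistart, problem_from_summary
from .model import ModelParameters, ModelVariant, TARGET_CLASSES, VARIANT_NAMES
from .preprocess import summarize
from .simulate import simulate
from .synth import make_paper_like_panels
from .uncertainty import (
    DEFAULT_RATIO_PAIRS,
    bootstrap_ci,
    compare_measured_ratios,
    predict_ratio,
    profile_parameter,
    ratio_ci_from_gamma_ci,
)

__all__ = ["ConfigError", "validate_config", "run_pipeline", "DEFAULT_CONFIG"]

logger = logging.getLogger(__name__)

STAGES = ("generate", "preprocess", "fit", "profile", "bootstrap",
          "predict_ratios", "compare_ratios")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "mitommp_out",
    "stages": ["generate", "preprocess", "fit"],
    "generate": {"panel": "uncoupler", "cells_csv": None},
    "fit": {
        "variant": "pk_decay",
        "target_class": "uncoupler",
        "free": ["V_A", "K_A", "D0", "c1", "c0", "r", "gamma"],
        "n_starts": 20,
        "sigma_floor_frac": 0.05,
    },
    "profile": {"parameters": ["gamma"], "confidence": 0.95},
    "bootstrap": {"n_boot": 50},
    "ratios": {"pairs": [list(p) for p in DEFAULT_RATIO_PAIRS]},
    "compare": {"measured_csv": None},
}


class ConfigError(ValueError):
    """Pipeline configuration violates the schema."""


def validate_config(config: dict) -> dict:
    """Merge with defaults and validate; raises ConfigError naming the field."""
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    for key in ("generate", "fit", "profile", "bootstrap", "ratios", "compare"):
        cfg[key] = {**DEFAULT_CONFIG[key], **(cfg.get(key) or {})}
    for st in cfg["stages"]:
        if st not in STAGES:
            raise ConfigError(f"stages: unknown stage {st!r}; expected one of {STAGES}")
    if not isinstance(cfg["seed"], (int, np.integer)):
        raise ConfigError("seed: must be an integer")
    fit = cfg["fit"]
    if fit["variant"] not in VARIANT_NAMES:
        raise ConfigError(f"fit.variant: unknown variant {fit['variant']!r}; "
                          f"expected one of {VARIANT_NAMES}")
    if fit["target_class"] not in TARGET_CLASSES:
        raise ConfigError(f"fit.target_class: unknown class {fit['target_class']!r}")
    if not isinstance(fit["n_starts"], (int, np.integer)) or fit["n_starts"] < 1:
        raise ConfigError("fit.n_starts: must be a positive integer")
    gen = cfg["generate"]
    if gen["cells_csv"] is None and gen["panel"] not in ("etc", "uncoupler", "atp_synthase"):
        raise ConfigError(f"generate.panel: unknown panel {gen['panel']!r}")
    if cfg["bootstrap"]["n_boot"] < 1:
        raise ConfigError("bootstrap.n_boot: must be >= 1")
    if not 0 < cfg["profile"]["confidence"] < 1:
        raise ConfigError("profile.confidence: must lie in (0, 1)")
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonable))


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, ModelParameters):
        return x.to_dict()
    raise TypeError(f"not JSON serializable: {type(x)}")


def run_pipeline(config: dict | str | Path) -> dict:
    """Execute the enabled stages in order and return the run manifest."""
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = validate_config(config)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    artifacts: dict[str, str] = {}
    manifest = {"config": cfg, "seed": seed, "version": __version__, "artifacts": artifacts}

    cells = None
    summary = None
    problem: FitProblem | None = None
    fit_result = None
    gamma_pl_ci = None
    boot = None
    compound = None

    def record(name: str, path: Path) -> None:
        artifacts[name] = _sha256(path)

    for stage in [s for s in STAGES if s in cfg["stages"]]:
        logger.info("pipeline stage: %s", stage)
        if stage == "generate":
            gen = cfg["generate"]
            if gen["cells_csv"]:
                cells = pd.read_csv(gen["cells_csv"])
            else:
                panels = make_paper_like_panels(seed)
                cells = panels[gen["panel"]]["cells"]
            path = outdir / "cells.csv"
            cells.to_csv(path, index=False)
            record("cells.csv", path)

        elif stage == "preprocess":
            if cells is None:
                cells = pd.read_csv(outdir / "cells.csv")
            summary = summarize(cells)
            path = outdir / "summary.csv"
            summary.to_csv(path, index=False)
            record("summary.csv", path)

        elif stage == "fit":
            if summary is None:
                summary = pd.read_csv(outdir / "summary.csv")
            fit_cfg = cfg["fit"]
            variant = ModelVariant(fit_cfg["variant"], fit_cfg["target_class"])
            compounds = sorted(summary["compound"].unique())
            compound = compounds[0]
            problem = problem_from_summary(
                summary, compound, variant, ModelParameters(),
                free_names=fit_cfg["free"],
                sigma_floor_frac=fit_cfg["sigma_floor_frac"],
                n_starts=int(fit_cfg["n_starts"]), seed=seed,
            )
            fit_result = fit_multistart(problem)
            _write_json(outdir / f"fit_{compound}.json", fit_result.as_dict())
            record(f"fit_{compound}.json", outdir / f"fit_{compound}.json")
            frames = []
            best = fit_result.params[compound]
            for cond in problem.compounds[0].conditions:
                frames.append(
                    simulate(variant, best, cond.dose_index, cond.times).to_frame(compound)
                )
            path = outdir / f"bestfit_{compound}.csv"
            pd.concat(frames, ignore_index=True).to_csv(path, index=False)
            record(f"bestfit_{compound}.csv", path)

        elif stage == "profile":
            if problem is None or fit_result is None:
                raise ConfigError("profile stage requires the fit stage in the same run")
            for name in cfg["profile"]["parameters"]:
                curve = profile_parameter(
                    problem, name, fit=fit_result,
                    confidence=cfg["profile"]["confidence"],
                )
                path = outdir / f"profile_{name}.csv"
                curve.to_frame().to_csv(path, index=False)
                record(f"profile_{name}.csv", path)
                _write_json(outdir / f"profile_{name}.json", {
                    "name": name, "mle": curve.mle_value, "delta": curve.delta,
                    "ci_low": curve.ci_low, "ci_high": curve.ci_high,
                    "identifiable": curve.identifiable,
                })
                record(f"profile_{name}.json", outdir / f"profile_{name}.json")
                if name == "gamma":
                    gamma_pl_ci = (curve.ci_low, curve.ci_high)

        elif stage == "bootstrap":
            if problem is None or fit_result is None:
                raise ConfigError("bootstrap stage requires the fit stage in the same run")
            if cells is None:
                cells = pd.read_csv(outdir / "cells.csv")
            boot = bootstrap_ci(cells, problem, n_boot=int(cfg["bootstrap"]["n_boot"]),
                                seed=seed, mle=fit_result)
            path = outdir / "bootstrap_estimates.csv"
            boot.estimates.to_csv(path, index=False)
            record("bootstrap_estimates.csv", path)
            _write_json(outdir / "bootstrap_ci.json",
                        {"ci95": boot.ci95, "ci99": boot.ci99,
                         "n_boot": boot.n_boot, "n_failed": boot.n_failed})
            record("bootstrap_ci.json", outdir / "bootstrap_ci.json")

        elif stage == "predict_ratios":
            if fit_result is None:
                raise ConfigError("predict_ratios requires the fit stage in the same run")
            gamma_hat = fit_result.params[compound].gamma
            out = {}
            for t1, t2 in cfg["ratios"]["pairs"]:
                entry = {"ratio": predict_ratio(gamma_hat, t1, t2)}
                if gamma_pl_ci is not None:
                    entry["pl_ci95"] = list(ratio_ci_from_gamma_ci(gamma_pl_ci, t1, t2))
                if boot is not None and "gamma" in boot.ci95:
                    entry["boot_ci95"] = list(
                        ratio_ci_from_gamma_ci(boot.ci95["gamma"], t1, t2)
                    )
                out[f"R_{t2:g}h_vs_{t1:g}h"] = entry
            _write_json(outdir / "ratios.json", out)
            record("ratios.json", outdir / "ratios.json")

        elif stage == "compare_ratios":
            measured_csv = cfg["compare"]["measured_csv"]
            ratios_path = outdir / "ratios.json"
            if not ratios_path.exists():
                raise ConfigError("compare_ratios requires predict_ratios artifacts")
            ratios = json.loads(ratios_path.read_text())
            reports = {}
            measured = pd.read_csv(measured_csv) if measured_csv else pd.DataFrame(
                columns=["compound", "T1_h", "T2_h", "replicate_ratio"]
            )
            for label, entry in ratios.items():
                t_part = label.split("R_")[1]  # e.g. "24h_vs_2h"
                t2 = float(t_part.split("h_vs_")[0])
                t1 = float(t_part.split("h_vs_")[1].rstrip("h"))
                sel = measured[
                    np.isclose(measured["T1_h"], t1) & np.isclose(measured["T2_h"], t2)
                ] if len(measured) else measured
                intervals = {
                    k: tuple(v) for k, v in entry.items() if k.endswith(("ci95", "ci99"))
                }
                reports[label] = compare_measured_ratios(
                    entry["ratio"], intervals, sel["replicate_ratio"].tolist() if len(sel) else []
                )
            _write_json(outdir / "ratio_comparison.json", reports)
            record("ratio_comparison.json", outdir / "ratio_comparison.json")

    _write_json(outdir / "manifest.json", manifest)
    return manifest
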