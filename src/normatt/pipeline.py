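"""End-to-end orchestration: generate -> fit -> validate -> stats -> report.

A run writes into one directory with ``data/``, ``fits/``, ``stats/``,
``figures/`` and a ``manifest.json`` recording the config snapshot, the
master seed, package version, content hashes of every output file, and stage
timings.  All randomness flows from the single master seed, so rerunning
with the same config and seed reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .nma import ConditionPredictor, ConfigurationError, ModelParams, PopulationGrid, StimulusGeometry, build_grid
from . import fitting, suppression, synthetic
from .psychophysics import StaircaseConfig, simulate_behavioral_experiment

__all__ = ["default_config", "load_config", "run_pipeline", "STAGES"]

STAGES = ("simulate", "fit", "null", "cv", "stats", "report")


def default_config() -> dict:
    """Built-in configuration mirroring the study conditions."""
    return {
        "grid": {"n_space": 121, "space_extent": 60.0, "n_direction": 72},
        "geometry": dataclasses.asdict(StimulusGeometry()),
        "params": dataclasses.asdict(ModelParams()),
        "generator": {"n_participants": 10, "scale_sd": 0.2, "noise_sd": 0.10,
                      "threshold_jitter_sd": 0.2},
        "behavior": {"trials_per_track": 100},
        "fit": {"n_starts": 20, "constrained": False},
        "null": {"n_shuffles": 1000, "n_starts": 5, "constrained": True},
        "cv": {"k": 5, "n_starts": 5},
    }


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML config, overlaying it on the defaults."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigurationError("config file must contain a mapping")
        cfg = _merge(cfg, user)
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _predictor(cfg: dict) -> ConditionPredictor:
    grid = build_grid(**cfg["grid"])
    geometry = StimulusGeometry(**cfg["geometry"])
    return ConditionPredictor(grid=grid, geometry=geometry)


def _params(cfg: dict) -> ModelParams:
    return ModelParams(**cfg["params"])


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _ttest_block(d: dict) -> dict:
    return {k: dataclasses.asdict(v) for k, v in d.items()}


class PipelineRun:
    """Stateful single-run orchestrator; see :func:`run_pipeline`."""

    def __init__(self, config: dict, seed: int, outdir: str | Path):
        self.config = config
        self.seed = int(seed)
        self.outdir = Path(outdir)
        self.predictor = _predictor(config)
        self.params = _params(config)
        self.timings: dict[str, float] = {}
        for sub in ("data", "fits", "stats", "figures"):
            (self.outdir / sub).mkdir(parents=True, exist_ok=True)

    # -- paths ---------------------------------------------------------
    @property
    def betas_csv(self) -> Path:
        return self.outdir / "data" / "betas.csv"

    @property
    def thresholds_csv(self) -> Path:
        return self.outdir / "data" / "thresholds.csv"

    def _require(self, path: Path, stage: str) -> Path:
        if not path.exists():
            raise FileNotFoundError(
                f"stage '{stage}' requires missing input {path}; "
                "run the 'simulate' stage (or provide the file) first")
        return path

    # -- stages --------------------------------------------------------
    def simulate(self) -> list[Path]:
        gcfg = synthetic.GeneratorConfig(params=self.params, seed=self.seed,
                                         **self.config["generator"])
        betas = synthetic.gen_fmri_betas(gcfg, self.predictor)
        betas.to_csv(self.betas_csv, index=False)
        stair = StaircaseConfig(trials_per_track=self.config["behavior"]["trials_per_track"])
        thresholds = simulate_behavioral_experiment(
            self.params, n_participants=gcfg.n_participants, seed=self.seed + 1,
            predictor=self.predictor, config=stair,
            threshold_jitter_sd=gcfg.threshold_jitter_sd)
        thresholds.to_csv(self.thresholds_csv, index=False)
        return [self.betas_csv, self.thresholds_csv]

    def fit(self) -> list[Path]:
        betas = pd.read_csv(self._require(self.betas_csv, "fit"))
        vec = fitting.normalize_betas(betas)
        fcfg = self.config["fit"]
        res = fitting.fit(vec, self.predictor, n_starts=fcfg["n_starts"],
                          seed=self.seed, constrained=fcfg["constrained"])
        out = self.outdir / "fits" / "fit.json"
        _write_json(out, {
            "free_params": res.free,
            "mse": res.mse,
            "data_normalized": {k: float(v) for k, v in vec.items()},
            "predicted_normalized": res.predictions.normalized,
            "predicted_threshold_ms": res.predictions.threshold_ms,
            "ordering_recovered": res.ordering_recovered(),
            "n_starts": res.n_starts,
            "seed": res.seed,
            "converged": res.converged,
        })
        return [out]

    def null(self) -> list[Path]:
        betas = pd.read_csv(self._require(self.betas_csv, "null"))
        ncfg = self.config["null"]
        null = fitting.shuffle_null(betas, n_shuffles=ncfg["n_shuffles"],
                                    constrained=ncfg["constrained"],
                                    seed=self.seed, predictor=self.predictor,
                                    n_starts=ncfg["n_starts"])
        hist, edges = np.histogram(null.mses, bins=20)
        out = self.outdir / "fits" / "null.json"
        _write_json(out, {
            "observed_mse": null.observed_mse,
            "null_mean_mse": float(null.mses.mean()),
            "p_value": null.p_value,
            "constrained": null.constrained,
            "n_shuffles": null.n_shuffles,
            "seed": null.seed,
            "histogram": {"counts": hist.tolist(), "edges": edges.tolist()},
        })
        return [out]

    def cv(self) -> list[Path]:
        betas = pd.read_csv(self._require(self.betas_csv, "cv"))
        ccfg = self.config["cv"]
        res = fitting.cross_validate(betas, k=ccfg["k"], seed=self.seed,
                                     predictor=self.predictor,
                                     n_starts=ccfg["n_starts"])
        out = self.outdir / "fits" / "cv.json"
        _write_json(out, {
            "fold_mses": res.fold_mses.tolist(),
            "mean_mse": res.mean_mse,
            "sem_mse": res.sem_mse,
            "fold_assignments": res.fold_assignments,
            "seed": res.seed,
        })
        return [out]

    def stats(self, si_csv: str | Path | None = None) -> list[Path]:
        """Stats stage; ``si_csv`` allows a stats-only run on a provided SI
        table (columns participant, attention, direction, si, modality)."""
        written = []
        tables = []
        if si_csv is not None:
            tables.append(("provided", pd.read_csv(si_csv)))
        else:
            if self.thresholds_csv.exists():
                thresholds = pd.read_csv(self.thresholds_csv)
                tables.append(("behavioral", suppression.si_table_from_thresholds(thresholds)))
            if self.betas_csv.exists():
                betas = pd.read_csv(self.betas_csv)
                tables.append(("fmri", suppression.si_table_from_betas(betas)))
            if not tables:
                raise FileNotFoundError(
                    "stats stage found neither data/thresholds.csv nor "
                    "data/betas.csv; run 'simulate' or pass an SI table")
        for name, si in tables:
            si_path = self.outdir / "stats" / f"si_{name}.csv"
            si.to_csv(si_path, index=False)
            report = suppression.stats_report(si)
            rep_path = self.outdir / "stats" / f"stats_{name}.json"
            _write_json(rep_path, report.to_dict())
            written += [si_path, rep_path]
        return written

    def report(self) -> list[Path]:
        from . import plots
        fit_path = self._require(self.outdir / "fits" / "fit.json", "report")
        payload = json.loads(fit_path.read_text())
        out = self.outdir / "figures" / "model_fit.png"
        plots.model_vs_data_panels(
            data_normalized=payload["data_normalized"],
            model_normalized=payload["predicted_normalized"],
            predicted_threshold_ms=payload["predicted_threshold_ms"],
            path=out)
        return [out]

    # -- driver --------------------------------------------------------
    def run(self, stages=STAGES, si_csv=None) -> dict:
        unknown = set(stages) - set(STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stages: {sorted(unknown)}")
        files: list[Path] = []
        for stage in STAGES:
            if stage not in stages:
                continue
            t0 = time.perf_counter()
            if stage == "stats":
                files += self.stats(si_csv)
            else:
                files += getattr(self, stage)()
            self.timings[stage] = time.perf_counter() - t0
        manifest = {
            "config": self.config,
            "seed": self.seed,
            "version": __version__,
            "stages": [s for s in STAGES if s in stages],
            "files": {str(p.relative_to(self.outdir)): _sha256(p) for p in files},
            "timings_s": {k: round(v, 3) for k, v in self.timings.items()},
        }
        _write_json(self.outdir / "manifest.json", manifest)
        return manifest


def run_pipeline(
    config: dict | str | Path | None = None,
    stages=STAGES,
    seed: int = 0,
    outdir: str | Path = "normatt_run",
    si_csv: str | Path | None = None,
) -> dict:
    """Execute the requested stages and return the run manifest.

    ``config`` may be a mapping, a YAML path, or ``None`` for the defaults.
    """
    if config is None or isinstance(config, (str, Path)):
        config = load_config(config)
    return PipelineRun(config, seed, outdir).run(stages, si_csv=si_csv)
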