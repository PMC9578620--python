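"""End-to-end experiment orchestration with a reproducibility manifest.

One YAML config drives the whole pipeline: simulate a labeled synthetic
cohort, profile and classify its irregularity, split it, train every
model on every (T_s, P_t) grid cell, evaluate accuracy, and run the
mm-gating feasibility grid.  Every numbered stage derives its own seed
from the master seed through a counter scheme
(``SeedSequence([master_seed, stage_index])``), so no stage consumes a
shared random stream implicitly and any stage can be reproduced alone.

All tabular outputs are written with fixed float formatting and sorted
keys; the manifest lists each artifact with its SHA-256 content hash, so
two runs of the same config produce byte-identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .errors import InvalidConfigurationError, RespigateError
from .gating import feasibility_study
from .irregularity import classify_cohort, profile_signal
from .metrics import anova_across_models, records_to_rows, run_sweep
from .models import PredictorSpec
from .preprocessing import split_cohort
from .signal import write_signal_csv
from .synthetic import (
    COHORT_DURATION_RANGE_S,
    GeneratorConfig,
    default_group_configs,
    generate_cohort,
)
from .training import TrainingProtocol, save_checkpoint

_STAGE_SEEDS = {"simulate": 0, "split": 1, "train": 2, "feasibility": 3}


def stage_seed(master_seed: int, stage: str) -> int:
    """Per-stage seed from the master seed (documented counter scheme)."""
    ss = np.random.SeedSequence([int(master_seed), _STAGE_SEEDS[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class ExperimentConfig:
    """Everything needed to rerun an experiment from scratch."""

    seed: int = 0
    output_dir: str = "experiment_out"
    # cohort generation
    n_per_group: int = 2
    duration_range_s: tuple[float, float] = COHORT_DURATION_RANGE_S
    period_jitter_sd: float = 0.6
    amplitude_jitter_sd: float = 0.30
    base: dict[str, Any] = field(default_factory=dict)  # GeneratorConfig overrides
    # taxonomy
    group_size: int | None = None  # default: n_per_group
    # split
    n_test: int | None = None  # default: cohort/9 (test fraction of the study)
    train_fraction: float = 0.7
    stratify_by_group: bool = True
    # windowing grid (ms)
    ts_grid: tuple[float, ...] = (1000.0,)
    pt_grid: tuple[float, ...] = (500.0,)
    # models and training
    model_kinds: tuple[str, ...] = ("lstm", "bilstm", "transformer")
    model_overrides: dict[str, Any] = field(default_factory=dict)
    epochs: int = 100
    batch_size: int = 300
    learning_rate: float = 1e-4
    weight_decay: float = 2e-4
    max_train_windows: int | None = None
    max_val_windows: int | None = None
    # postprocessing filter
    sg_window: int | None = 5
    sg_polyorder: int = 2
    # feasibility
    feasibility_latencies_ms: tuple[float, ...] = ()
    motion_mm: float = 10.0
    feasibility_patterns: tuple[str, ...] = ("regular", "type1", "type2")
    n_cases_per_pattern: int = 10

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @staticmethod
    def from_dict(d: dict[str, Any]) -> "ExperimentConfig":
        d = dict(d)
        for f in dataclasses.fields(ExperimentConfig):
            if f.name in d and isinstance(d[f.name], list):
                d[f.name] = tuple(d[f.name])
        unknown = set(d) - {f.name for f in dataclasses.fields(ExperimentConfig)}
        if unknown:
            raise InvalidConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return ExperimentConfig(**d)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @staticmethod
    def load(path: str | Path) -> "ExperimentConfig":
        return ExperimentConfig.from_dict(yaml.safe_load(Path(path).read_text()))


class _Log:
    def __init__(self, path: Path, verbose: bool = False):
        self.path = path
        self.verbose = verbose
        self.lines: list[str] = []
        self.t0 = time.monotonic()

    def info(self, stage: str, message: str) -> None:
        line = f"[{time.monotonic() - self.t0:9.2f}s] {stage:<12} INFO  {message}"
        self.lines.append(line)
        if self.verbose:
            print(line)

    def flush(self) -> None:
        self.path.write_text("\n".join(self.lines) + "\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.8g")


def run_experiment(config: ExperimentConfig, verbose: bool = False) -> Path:
    """Execute the full pipeline; returns the artifact directory.

    Any stage failure aborts with the stage name and cause in the log.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _Log(out / "run.log", verbose=verbose)
    config.save(out / "config.yaml")
    stage = "setup"
    try:
        # -- simulate -----------------------------------------------------
        stage = "simulate"
        sim_seed = stage_seed(config.seed, "simulate")
        base = GeneratorConfig(**{
            **dataclasses.asdict(default_group_configs()["regular"]),
            **config.base,
        })
        group_configs = default_group_configs(
            base=base,
            period_jitter_sd=config.period_jitter_sd,
            amplitude_jitter_sd=config.amplitude_jitter_sd,
        )
        cohort = generate_cohort(
            config.n_per_group, group_configs, seed=sim_seed,
            duration_range_s=config.duration_range_s,
        )
        sig_dir = out / "signals"
        sig_dir.mkdir(exist_ok=True)
        for sig in cohort:
            write_signal_csv(sig, sig_dir / f"{sig.id}.csv")
        log.info(stage, f"generated {len(cohort)} signals (seed {sim_seed})")

        # -- classify -----------------------------------------------------
        stage = "classify"
        profiles = [profile_signal(s) for s in cohort]
        group_size = config.group_size or config.n_per_group
        profiles = classify_cohort(profiles, group_size)
        _write_csv(
            pd.DataFrame(
                {
                    "signal_id": [p.signal_id for p in profiles],
                    "amp_irr": [p.amplitude_irregularity for p in profiles],
                    "phase_irr": [p.phase_irregularity for p in profiles],
                    "combined_irr": [p.combined_irregularity for p in profiles],
                    "group": [p.group for p in profiles],
                }
            ),
            out / "irregularity.csv",
        )
        log.info(stage, f"classified cohort into 4 groups of {group_size}")

        # -- split + train + evaluate -------------------------------------
        stage = "train"
        split_seed = stage_seed(config.seed, "split")
        n_test = config.n_test or max(1, round(len(cohort) / 9))
        split = split_cohort(cohort, n_test, config.train_fraction, split_seed,
                             stratify_by_group=config.stratify_by_group)
        protocol = TrainingProtocol(
            learning_rate=config.learning_rate,
            weight_decay=config.weight_decay,
            batch_size=config.batch_size,
            epochs=config.epochs,
            shuffle_seed=stage_seed(config.seed, "train"),
        )
        specs = [
            PredictorSpec(kind=kind, **config.model_overrides.get(kind, {}))
            for kind in config.model_kinds
        ]
        sweep = run_sweep(
            cohort, specs, config.ts_grid, config.pt_grid, protocol,
            seed=stage_seed(config.seed, "train"), split=split,
            max_train_windows=config.max_train_windows,
            max_val_windows=config.max_val_windows,
            sg_window=config.sg_window, sg_polyorder=config.sg_polyorder,
        )
        ckpt_dir = out / "checkpoints"
        ckpt_dir.mkdir(exist_ok=True)
        for (kind, ts, pt), cond in sorted(sweep.conditions.items()):
            save_checkpoint(
                ckpt_dir / f"{kind}_ts{ts:.0f}_pt{pt:.0f}.ckpt",
                cond.model, cond.state, protocol,
                extra={"ts_ms": ts, "pt_ms": pt},
            )
        _write_csv(pd.DataFrame(records_to_rows(sweep.records)), out / "metrics.csv")
        anova = {}
        for ts in config.ts_grid:
            for pt in config.pt_grid:
                if len(specs) >= 2:
                    for metric in ("rmse", "cc"):
                        r = anova_across_models(sweep, ts, pt, metric)
                        anova[f"ts{ts:.0f}_pt{pt:.0f}_{metric}"] = {
                            "f": r.f_statistic, "p": r.p_value,
                            "group_sizes": list(r.group_sizes),
                        }
        (out / "anova.json").write_text(json.dumps(anova, indent=2, sort_keys=True))
        log.info(stage, f"trained {len(sweep.conditions)} grid cells")

        # -- feasibility --------------------------------------------------
        if config.feasibility_latencies_ms:
            stage = "feasibility"
            missing = set(map(float, config.feasibility_latencies_ms)) - set(
                map(float, config.pt_grid)
            )
            if missing:
                raise InvalidConfigurationError(
                    f"feasibility latencies {sorted(missing)} not in the P_t grid"
                )
            ts0 = float(config.ts_grid[0])
            by_id = {s.id: s for s in cohort}
            signals_by_pattern = {}
            for pattern in config.feasibility_patterns:
                members = [
                    by_id[i] for i in split.test_signals
                    if by_id[i].group == pattern
                ]
                if not members:  # fall back to cohort members of the pattern
                    members = [s for s in cohort if s.group == pattern]
                signals_by_pattern[pattern] = members[: config.n_cases_per_pattern]
            models_by_latency = {
                spec.kind: {
                    float(lat): sweep.condition(spec.kind, ts0, lat).model
                    for lat in config.feasibility_latencies_ms
                }
                for spec in specs
            }
            cells = feasibility_study(
                signals_by_pattern, models_by_latency, ts_ms=ts0,
                latencies_ms=config.feasibility_latencies_ms,
                peak_to_peak_mm=config.motion_mm,
                sg_window=config.sg_window,
            )
            _write_csv(pd.DataFrame([vars(c) for c in cells]), out / "feasibility.csv")
            log.info(stage, f"feasibility grid: {len(cells)} cells")

        # -- manifest -----------------------------------------------------
        stage = "manifest"
        artifacts = sorted(
            p for p in out.rglob("*")
            if p.is_file() and p.name not in ("run.log", "manifest.json")
        )
        manifest = {
            str(p.relative_to(out)): _sha256(p) for p in artifacts
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
        log.info(stage, f"{len(manifest)} artifacts hashed")
    except RespigateError as exc:
        log.info(stage, f"FAILED: {exc}")
        log.flush()
        raise
    log.flush()
    return out
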