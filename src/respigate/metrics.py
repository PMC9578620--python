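"""Forecast accuracy metrics and the (T_s, P_t) sweep experiments.

Accuracy is measured by the root-mean-square error between actual and
predicted series and by Pearson's correlation coefficient; model
differences are tested with a one-way ANOVA over per-signal metric
values.  Metrics are computed per signal and then averaged across
signals (a pooled-over-pairs variant is available); predicted series are
Savitzky-Golay filtered as a postprocessing step before scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, InvalidInputError
from .models import PredictorSpec, _BaseModel, build_model
from .preprocessing import (
    DataSplit,
    build_datasets,
    make_windows,
    savitzky_golay,
    split_cohort,
    window_counts,
    zscore_normalize,
)
from .signal import RespirationSignal
from .training import TrainingProtocol, TrainState, train


def rmse(actual: np.ndarray, predicted: np.ndarray) -> float:
    """Root of the mean squared difference."""
    a = np.asarray(actual, dtype=np.float64)
    p = np.asarray(predicted, dtype=np.float64)
    if a.shape != p.shape or a.size == 0:
        raise InvalidInputError("rmse requires equal, nonzero-length inputs")
    return float(np.sqrt(np.mean((a - p) ** 2)))


def pearson_cc(actual: np.ndarray, predicted: np.ndarray) -> float:
    """Pearson correlation: covariance over the product of SDs."""
    a = np.asarray(actual, dtype=np.float64)
    p = np.asarray(predicted, dtype=np.float64)
    if a.shape != p.shape or a.size < 2:
        raise InvalidInputError("pearson_cc requires equal lengths >= 2")
    a = a - a.mean()
    p = p - p.mean()
    denom = np.sqrt((a * a).sum() * (p * p).sum())
    if denom == 0.0:
        raise DegenerateInputError("zero variance input to pearson_cc")
    return float((a * p).sum() / denom)


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    p_value: float
    group_sizes: tuple[int, ...]


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Classical one-way ANOVA over per-model value lists."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise InvalidInputError("need >= 2 groups with >= 2 values each")
    f, p = stats.f_oneway(*[np.asarray(g, dtype=np.float64) for g in groups])
    return AnovaResult(float(f), float(p), tuple(len(g) for g in groups))


@dataclass
class MetricsRecord:
    """One row of the accuracy tables."""

    model_kind: str
    role: str  # "validation" or "test"
    ts_ms: float
    pt_ms: float
    group: str  # regularity group or "all"
    rmse: float
    cc: float
    n_pairs: int
    n_signals: int


def predict_series(
    model: _BaseModel,
    signal: RespirationSignal,
    ts_ms: float,
    pt_ms: float,
    start: int = 0,
    stop: int | None = None,
    sg_window: int | None = 5,
    sg_polyorder: int = 2,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Latency-compensated forecast series over one (z-scored) signal.

    Returns ``(target_indices, actual, predicted)`` where entry *j* is the
    model's forecast made from the window ending ``pt_ms`` before sample
    ``target_indices[j]``.  The predicted series is S-G smoothed unless
    ``sg_window`` is None.
    """
    ds = make_windows(signal, ts_ms, pt_ms, start=start, stop=stop)
    predicted = model.predict(ds.inputs)
    if sg_window is not None and predicted.size >= sg_window:
        predicted = savitzky_golay(predicted, sg_window, sg_polyorder)
    L, H = window_counts(ts_ms, pt_ms, signal.sampling_rate_hz)
    stop = signal.n_samples if stop is None else min(stop, signal.n_samples)
    indices = np.arange(start + L + H - 1, start + L + H - 1 + ds.n_pairs)
    return indices, ds.targets, predicted


@dataclass
class SignalScore:
    signal_id: str
    group: str
    rmse: float
    cc: float
    n_pairs: int


def score_signals(
    model: _BaseModel,
    signals: Sequence[RespirationSignal],
    ts_ms: float,
    pt_ms: float,
    boundaries: Mapping[str, int] | None = None,
    sg_window: int | None = 5,
    sg_polyorder: int = 2,
    normalize: bool = True,
    max_eval_s: float | None = None,
) -> list[SignalScore]:
    """Per-signal RMSE/CC; with ``boundaries`` given, scoring is restricted
    to each signal's validation segment (samples at or past the boundary).
    ``max_eval_s`` caps the scored segment length (seconds)."""
    scores = []
    for sig in signals:
        s = zscore_normalize(sig) if normalize else sig
        start = 0 if boundaries is None else boundaries[sig.id]
        stop = None
        if max_eval_s is not None:
            stop = start + int(round(max_eval_s * sig.sampling_rate_hz))
        _, actual, predicted = predict_series(
            model, s, ts_ms, pt_ms, start=start, stop=stop,
            sg_window=sg_window, sg_polyorder=sg_polyorder,
        )
        scores.append(
            SignalScore(sig.id, sig.group or "all", rmse(actual, predicted),
                        pearson_cc(actual, predicted), actual.size)
        )
    return scores


def _aggregate(
    scores: Sequence[SignalScore], model_kind: str, role: str,
    ts_ms: float, pt_ms: float, group: str,
) -> MetricsRecord:
    return MetricsRecord(
        model_kind=model_kind, role=role, ts_ms=ts_ms, pt_ms=pt_ms, group=group,
        rmse=float(np.mean([s.rmse for s in scores])),
        cc=float(np.mean([s.cc for s in scores])),
        n_pairs=int(sum(s.n_pairs for s in scores)),
        n_signals=len(scores),
    )


@dataclass
class ConditionResult:
    """Trained model plus its accuracy records for one (model, T_s, P_t)."""

    spec: PredictorSpec
    ts_ms: float
    pt_ms: float
    model: _BaseModel
    state: TrainState
    records: list[MetricsRecord]
    test_scores: list[SignalScore]


@dataclass
class SweepResult:
    records: list[MetricsRecord]
    conditions: dict[tuple[str, float, float], ConditionResult]

    def condition(self, kind: str, ts_ms: float, pt_ms: float) -> ConditionResult:
        return self.conditions[(kind, float(ts_ms), float(pt_ms))]


def train_condition(
    signals: Sequence[RespirationSignal],
    split: DataSplit,
    spec: PredictorSpec,
    ts_ms: float,
    pt_ms: float,
    protocol: TrainingProtocol,
    seed: int = 0,
    max_train_windows: int | None = None,
    max_val_windows: int | None = None,
    sg_window: int | None = 5,
    sg_polyorder: int = 2,
    max_eval_s: float | None = None,
    score_validation: bool = True,
) -> ConditionResult:
    """Train one model for one (T_s, P_t) cell and score it.

    ``max_*_windows`` subsample the sliding-window datasets (seeded) and
    ``max_eval_s`` caps the scored segment per signal, keeping desk-scale
    runs tractable; scoring always slides stride-1 within its segment.
    """
    by_id = {s.id: s for s in signals}
    train_ds, val_ds, _ = build_datasets(signals, split, ts_ms, pt_ms)
    if max_train_windows is not None:
        train_ds = train_ds.subsample(max_train_windows, seed=seed)
    if max_val_windows is not None:
        val_ds = val_ds.subsample(max_val_windows, seed=seed + 1)
    model = build_model(dc_replace(spec, seed=spec.seed + seed))
    state = train(model, train_ds, val_ds, protocol)

    records = []
    if score_validation:
        val_scores = score_signals(
            model, [by_id[i] for i in split.train_signals], ts_ms, pt_ms,
            boundaries=split.boundaries, sg_window=sg_window,
            sg_polyorder=sg_polyorder, max_eval_s=max_eval_s,
        )
        records.append(
            _aggregate(val_scores, spec.kind, "validation", ts_ms, pt_ms, "all")
        )
    test_signals = [by_id[i] for i in split.test_signals]
    test_scores = score_signals(
        model, test_signals, ts_ms, pt_ms,
        sg_window=sg_window, sg_polyorder=sg_polyorder, max_eval_s=max_eval_s,
    )
    records.append(_aggregate(test_scores, spec.kind, "test", ts_ms, pt_ms, "all"))
    for group in sorted({s.group for s in test_scores}):
        members = [s for s in test_scores if s.group == group]
        if group != "all" and members:
            records.append(_aggregate(members, spec.kind, "test", ts_ms, pt_ms, group))
    return ConditionResult(spec, float(ts_ms), float(pt_ms), model, state,
                           records, test_scores)


def run_sweep(
    cohort: Sequence[RespirationSignal],
    model_specs: Sequence[PredictorSpec],
    ts_grid: Sequence[float],
    pt_grid: Sequence[float],
    protocol: TrainingProtocol = TrainingProtocol(),
    seed: int = 0,
    n_test: int | None = None,
    train_fraction: float = 0.7,
    stratify_by_group: bool = True,
    max_train_windows: int | None = None,
    max_val_windows: int | None = None,
    sg_window: int | None = 5,
    sg_polyorder: int = 2,
    split: DataSplit | None = None,
) -> SweepResult:
    """Retrain from scratch for every (model, T_s, P_t) grid cell.

    Cells are independent and fully seeded, so the sweep is reproducible
    and any cell can be recomputed in isolation.  Emits validation and
    test records plus per-regularity-group test records.
    """
    if not ts_grid or not pt_grid or not model_specs:
        raise InvalidInputError("model, T_s and P_t 'grids' must be nonempty")
    if split is None:
        if n_test is None:
            n_test = max(1, round(len(cohort) / 9))  # 540 -> 60 proportion
        split = split_cohort(cohort, n_test, train_fraction, seed,
                             stratify_by_group=stratify_by_group)
    records: list[MetricsRecord] = []
    conditions: dict[tuple[str, float, float], ConditionResult] = {}
    cell = 0
    for spec in model_specs:
        for ts_ms in ts_grid:
            for pt_ms in pt_grid:
                result = train_condition(
                    cohort, split, spec, ts_ms, pt_ms, protocol,
                    seed=seed + 1000 * cell,
                    max_train_windows=max_train_windows,
                    max_val_windows=max_val_windows,
                    sg_window=sg_window, sg_polyorder=sg_polyorder,
                )
                records.extend(result.records)
                conditions[(spec.kind, float(ts_ms), float(pt_ms))] = result
                cell += 1
    return SweepResult(records=records, conditions=conditions)


def anova_across_models(
    sweep: SweepResult, ts_ms: float, pt_ms: float, metric: str = "rmse",
) -> AnovaResult:
    """Omnibus F test of per-signal test metrics across the model kinds."""
    groups = []
    for (kind, ts, pt), cond in sorted(sweep.conditions.items()):
        if (ts, pt) == (float(ts_ms), float(pt_ms)):
            groups.append([getattr(s, metric) for s in cond.test_scores])
    return one_way_anova(groups)


def records_to_rows(records: Sequence[MetricsRecord]) -> list[dict]:
    return [vars(r).copy() for r in records]
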