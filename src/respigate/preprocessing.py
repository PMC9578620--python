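"""Signal normalization, sliding-window dataset construction and splitting.

The forecasting task is sequence-to-one: an input window of ``T_s``
milliseconds of signal is mapped to the single amplitude ``P_t``
milliseconds after the window's last sample, where ``P_t`` matches the
beam-control latency being compensated.  Windows slide with a stride of
one sample.  Splits are temporal within each signal (first 70% of samples
for training, the rest for validation) so no future sample can leak into
training, and whole signals are reserved for the test role.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.signal import savgol_filter

from ._io import load_arrays, save_arrays
from .errors import (
    DegenerateSignalError,
    EmptyDatasetError,
    InvalidParameterError,
    InvalidSplitError,
)
from .signal import RespirationSignal


def zscore_array(x: np.ndarray) -> np.ndarray:
    """Z-score with population (divisor-N) standard deviation."""
    x = np.asarray(x, dtype=np.float64)
    if x.size < 2:
        raise InvalidParameterError("need at least 2 samples to z-score")
    sd = float(np.std(x))
    if sd == 0.0:
        raise DegenerateSignalError("constant signal cannot be z-scored")
    return (x - float(np.mean(x))) / sd


def zscore_normalize(signal: RespirationSignal) -> RespirationSignal:
    """Per-signal Z-score normalization (baseline matching across patients).

    Mean and population SD are computed over this signal only; the output
    has mean 0 and SD 1.
    """
    return signal.with_samples(zscore_array(signal.samples), zscored=True)


def savitzky_golay(
    series: np.ndarray, window_samples: int = 5, polyorder: int = 2
) -> np.ndarray:
    """Savitzky-Golay smoothing: centre value of a least-squares polynomial
    fit over each sliding window, with mirror padding at the edges.

    Applied to *predicted* series as a postprocessing step; raw signals are
    fed to the networks unfiltered.
    """
    series = np.asarray(series, dtype=np.float64)
    if window_samples % 2 == 0 or window_samples <= polyorder:
        raise InvalidParameterError(
            f"window must be odd and > polyorder, got {window_samples}/{polyorder}"
        )
    if series.size < window_samples:
        raise InvalidParameterError("series shorter than the filter window")
    return savgol_filter(series, window_samples, polyorder, mode="mirror")


def window_counts(
    ts_ms: float, pt_ms: float, sampling_rate_hz: float
) -> tuple[int, int]:
    """(input length L, horizon H) in samples; both must sit on the grid."""
    dt_ms = 1000.0 / sampling_rate_hz
    out = []
    for name, ms in (("ts_ms", ts_ms), ("pt_ms", pt_ms)):
        k = ms / dt_ms
        if ms <= 0 or abs(k - round(k)) > 1e-9:
            raise InvalidParameterError(
                f"{name}={ms} is not a positive multiple of the {dt_ms:.0f} ms sampling interval"
            )
        out.append(int(round(k)))
    return out[0], out[1]


@dataclass
class WindowedDataset:
    """(input window, target point) pairs for one (T_s, P_t) condition."""

    inputs: np.ndarray  # (n_pairs, L)
    targets: np.ndarray  # (n_pairs,)
    ts_ms: float
    pt_ms: float
    sampling_rate_hz: float
    source_ids: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))

    @property
    def n_pairs(self) -> int:
        return int(self.targets.size)

    def subsample(self, n: int, seed: int = 0) -> "WindowedDataset":
        """Seeded random subset of at most ``n`` pairs (order preserved)."""
        if n >= self.n_pairs:
            return self
        idx = np.sort(np.random.default_rng(seed).choice(self.n_pairs, n, replace=False))
        return WindowedDataset(
            self.inputs[idx], self.targets[idx], self.ts_ms, self.pt_ms,
            self.sampling_rate_hz, self.source_ids[idx],
        )

    @staticmethod
    def concatenate(parts: Sequence["WindowedDataset"]) -> "WindowedDataset":
        if not parts:
            raise EmptyDatasetError("nothing to concatenate")
        first = parts[0]
        for p in parts[1:]:
            if (p.ts_ms, p.pt_ms, p.sampling_rate_hz) != (
                first.ts_ms, first.pt_ms, first.sampling_rate_hz,
            ):
                raise InvalidParameterError("mismatched window conditions")
        return WindowedDataset(
            np.concatenate([p.inputs for p in parts]),
            np.concatenate([p.targets for p in parts]),
            first.ts_ms, first.pt_ms, first.sampling_rate_hz,
            np.concatenate([p.source_ids for p in parts]),
        )

    def save(self, path: str | Path) -> Path:
        return save_arrays(
            path,
            {"inputs": self.inputs, "targets": self.targets,
             "source_ids": self.source_ids.astype(str)},
            {"ts_ms": self.ts_ms, "pt_ms": self.pt_ms,
             "sampling_rate_hz": self.sampling_rate_hz},
        )

    @staticmethod
    def load(path: str | Path) -> "WindowedDataset":
        arrays, attrs = load_arrays(path)
        return WindowedDataset(
            arrays["inputs"], arrays["targets"],
            float(attrs["ts_ms"]), float(attrs["pt_ms"]),
            float(attrs["sampling_rate_hz"]),
            arrays["source_ids"].astype(object),
        )


def make_windows(
    signal: RespirationSignal,
    ts_ms: float,
    pt_ms: float,
    start: int = 0,
    stop: int | None = None,
) -> WindowedDataset:
    """Sliding (window, target) pairs with stride one sample.

    Restricted to samples ``[start, stop)``; the pair count over N usable
    samples is ``N - L - H + 1`` for input length L and horizon H.
    """
    L, H = window_counts(ts_ms, pt_ms, signal.sampling_rate_hz)
    stop = signal.n_samples if stop is None else min(stop, signal.n_samples)
    x = signal.samples[start:stop]
    n = x.size
    n_pairs = n - L - H + 1
    if n_pairs < 1:
        raise EmptyDatasetError(
            f"signal segment of {n} samples too short for L={L}, H={H}"
        )
    windows = np.lib.stride_tricks.sliding_window_view(x, L)[:n_pairs]
    targets = x[L + H - 1:]
    return WindowedDataset(
        inputs=np.ascontiguousarray(windows, dtype=np.float64),
        targets=np.ascontiguousarray(targets, dtype=np.float64),
        ts_ms=ts_ms,
        pt_ms=pt_ms,
        sampling_rate_hz=signal.sampling_rate_hz,
        source_ids=np.array([signal.id] * n_pairs, dtype=object),
    )


@dataclass
class DataSplit:
    """Cohort split: whole signals for test, temporal 7:3 within the rest.

    Every non-test signal contributes its first ``train_fraction`` of
    samples to training windows and the remainder to validation windows;
    ``boundaries`` maps signal id to the first validation sample index.
    """

    train_signals: tuple[str, ...]
    test_signals: tuple[str, ...]
    boundaries: dict[str, int]
    train_fraction: float

    @property
    def validation_signals(self) -> tuple[str, ...]:
        # validation windows come from the tail segments of the training signals
        return self.train_signals


def split_cohort(
    signals: Sequence[RespirationSignal],
    n_test: int,
    train_fraction: float = 0.7,
    seed: int = 0,
    stratify_by_group: bool = False,
) -> DataSplit:
    """Reserve ``n_test`` whole signals for test (seeded draw) and split the
    remaining signals temporally at ``train_fraction`` of their length.

    With ``stratify_by_group`` the test draw is spread over the signals'
    regularity-group labels proportionally (largest-remainder rounding), so
    every group present in the cohort is represented in the test role.
    """
    if not 0 < train_fraction < 1:
        raise InvalidSplitError("train_fraction must lie in (0, 1)")
    if n_test >= len(signals) or n_test < 0:
        raise InvalidSplitError(
            f"cannot reserve {n_test} test signals out of {len(signals)}"
        )
    rng = np.random.default_rng(seed)
    ids = [s.id for s in signals]
    if len(set(ids)) != len(ids):
        raise InvalidSplitError("signal ids must be unique")

    if stratify_by_group and n_test > 0:
        by_group: dict[str, list[str]] = {}
        for s in signals:
            by_group.setdefault(s.group or "all", []).append(s.id)
        groups = sorted(by_group)
        quotas = {g: n_test * len(by_group[g]) / len(signals) for g in groups}
        counts = {g: int(quotas[g]) for g in groups}
        remainders = sorted(groups, key=lambda g: quotas[g] - counts[g], reverse=True)
        for g in remainders:
            if sum(counts.values()) == n_test:
                break
            if counts[g] < len(by_group[g]):
                counts[g] += 1
        test_ids: list[str] = []
        for g in groups:
            test_ids.extend(rng.choice(sorted(by_group[g]), counts[g], replace=False))
        test_ids = sorted(test_ids)
    else:
        test_ids = sorted(rng.choice(sorted(ids), n_test, replace=False))

    test_set = set(test_ids)
    train_ids = tuple(i for i in ids if i not in test_set)
    boundaries = {
        s.id: int(np.floor(s.n_samples * train_fraction))
        for s in signals
        if s.id not in test_set
    }
    return DataSplit(
        train_signals=train_ids,
        test_signals=tuple(test_ids),
        boundaries=boundaries,
        train_fraction=train_fraction,
    )


def build_datasets(
    signals: Sequence[RespirationSignal],
    split: DataSplit,
    ts_ms: float,
    pt_ms: float,
    normalize: bool = True,
    sg_filter_targets: bool = False,
    sg_window: int = 5,
    sg_polyorder: int = 2,
) -> tuple[WindowedDataset, WindowedDataset, WindowedDataset]:
    """(train, validation, test) windowed datasets for one condition.

    Signals are z-scored per signal first (unless ``normalize=False``);
    no training or validation window straddles the 7:3 boundary.  With
    ``sg_filter_targets`` the supervision targets are drawn from an S-G
    smoothed copy of each signal while the inputs stay raw (off by
    default; the smoothing normally applies to predictions only).
    """

    def windows(sig: RespirationSignal, **kw) -> WindowedDataset:
        ds = make_windows(sig, ts_ms, pt_ms, **kw)
        if sg_filter_targets:
            smooth = sig.with_samples(
                savitzky_golay(sig.samples, sg_window, sg_polyorder)
            )
            ds.targets = make_windows(smooth, ts_ms, pt_ms, **kw).targets
        return ds

    by_id = {s.id: s for s in signals}
    train_parts, val_parts, test_parts = [], [], []
    for sid in split.train_signals:
        sig = zscore_normalize(by_id[sid]) if normalize else by_id[sid]
        b = split.boundaries[sid]
        train_parts.append(windows(sig, stop=b))
        val_parts.append(windows(sig, start=b))
    for sid in split.test_signals:
        sig = zscore_normalize(by_id[sid]) if normalize else by_id[sid]
        test_parts.append(windows(sig))
    return (
        WindowedDataset.concatenate(train_parts),
        WindowedDataset.concatenate(val_parts),
        WindowedDataset.concatenate(test_parts),
    )
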