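"""Millimetre gating-error analysis at the 30%/70% respiratory phases.

Phase-gated delivery switches the beam at fixed respiratory phases; a
prediction error therefore matters through the amplitude discrepancy at
the gate times.  Each breathing cycle (peak to peak, 0% = peak inhale) is
divided into 10 linear phases; the 30% and 70% phase times of the
*predicted* signal are located, the surrogate is scaled so its global
peak-to-valley range equals the assumed tumor excursion (10 mm by
default), and the absolute amplitude difference between actual and
predicted signal at each gate time is the gating error.  Average and
maximum errors over cycles are reported per latency.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import (
    DegenerateSignalError,
    InsufficientCyclesError,
    InvalidConfigurationError,
)
from .irregularity import detect_extrema
from .metrics import predict_series
from .preprocessing import zscore_normalize
from .signal import RespirationSignal

DEFAULT_GATE_PHASES = (30.0, 70.0)
DEFAULT_MOTION_MM = 10.0


def scale_to_motion(samples: np.ndarray, peak_to_peak_mm: float = DEFAULT_MOTION_MM):
    """Affine map taking the series' global peak-to-peak range to
    ``peak_to_peak_mm``, centred so the maximum sits at +range/2.

    Returns ``(scaled, (gain, offset))`` so the same map can be applied to
    a second series on the same scale.
    """
    x = np.asarray(samples, dtype=np.float64)
    span = float(x.max() - x.min())
    if span == 0.0:
        raise DegenerateSignalError("constant signal cannot be scaled to motion")
    gain = peak_to_peak_mm / span
    offset = peak_to_peak_mm / 2.0 - gain * float(x.max())
    return gain * x + offset, (gain, offset)


@dataclass
class PhaseDecomposition:
    """Peak-to-peak cycles with a linear phase map and per-cycle gates."""

    cycle_starts_s: np.ndarray  # peak times, length n_cycles + 1
    gate_phases_pct: tuple[float, ...]
    gate_times_s: np.ndarray  # (n_cycles, n_gates)

    @property
    def n_cycles(self) -> int:
        return int(self.cycle_starts_s.size - 1)


def phase_decompose(
    signal: RespirationSignal,
    gate_phases_pct: Sequence[float] = DEFAULT_GATE_PHASES,
    min_separation_s: float = 1.5,
    min_prominence: float | None = None,
) -> PhaseDecomposition:
    """Divide each full cycle into linear phases anchored at inhale peaks.

    Phase is 0% at each cycle-start peak and grows linearly to 100% at the
    next peak; the gate time for phase p in cycle [t_k, t_{k+1}] is
    ``t_k + (p/100) (t_{k+1} - t_k)``.
    """
    peaks, _ = detect_extrema(signal, min_separation_s, min_prominence)
    if peaks.size < 2:
        raise InsufficientCyclesError("need >= 2 peaks for a phase decomposition")
    t_peaks = signal.times[peaks]
    phases = np.asarray(gate_phases_pct, dtype=np.float64)
    if np.any((phases <= 0) | (phases >= 100)):
        raise InvalidConfigurationError("gate phases must lie strictly in (0, 100)%")
    starts = t_peaks[:-1][:, None]
    periods = np.diff(t_peaks)[:, None]
    gate_times = starts + (phases[None, :] / 100.0) * periods
    return PhaseDecomposition(
        cycle_starts_s=t_peaks,
        gate_phases_pct=tuple(float(p) for p in phases),
        gate_times_s=gate_times,
    )


@dataclass
class GatingErrorReport:
    """Per-cycle mm errors at the gate phases for one signal and latency."""

    signal_id: str
    pattern: str
    latency_ms: float
    gate_phases_pct: tuple[float, ...]
    errors_mm: np.ndarray  # (n_cycles, n_gates)
    mean_error_mm: float
    max_error_mm: float

    @property
    def n_cycles(self) -> int:
        return int(self.errors_mm.shape[0])


def gating_error(
    actual_mm: np.ndarray,
    predicted_mm: np.ndarray,
    times_s: np.ndarray,
    latency_ms: float,
    sampling_rate_hz: float,
    signal_id: str = "signal",
    pattern: str = "all",
    gate_phases_pct: Sequence[float] = DEFAULT_GATE_PHASES,
    gates_from_actual: bool = False,
) -> GatingErrorReport:
    """Amplitude error (mm) between actual and predicted series at the
    gate times of the predicted signal.

    Both series must share the time axis ``times_s`` and be scaled to mm.
    Amplitudes at non-sample gate times are linearly interpolated.  With
    ``gates_from_actual`` the gates are located on the actual signal
    instead (the alternative reading of the error definition).
    """
    actual_mm = np.asarray(actual_mm, dtype=np.float64)
    predicted_mm = np.asarray(predicted_mm, dtype=np.float64)
    times_s = np.asarray(times_s, dtype=np.float64)
    if not (actual_mm.shape == predicted_mm.shape == times_s.shape):
        raise InvalidConfigurationError("series and time axis must share shape")
    gate_source = actual_mm if gates_from_actual else predicted_mm
    decomp = phase_decompose(
        RespirationSignal(
            samples=gate_source, sampling_rate_hz=sampling_rate_hz, id=signal_id
        ),
        gate_phases_pct=gate_phases_pct,
    )
    gates = decomp.gate_times_s + times_s[0]  # decomposition clock starts at 0
    a = np.interp(gates, times_s, actual_mm)
    p = np.interp(gates, times_s, predicted_mm)
    errors = np.abs(a - p)
    return GatingErrorReport(
        signal_id=signal_id,
        pattern=pattern,
        latency_ms=float(latency_ms),
        gate_phases_pct=tuple(float(g) for g in gate_phases_pct),
        errors_mm=errors,
        mean_error_mm=float(errors.mean()),
        max_error_mm=float(errors.max()),
    )


def signal_gating_error(
    model,
    signal: RespirationSignal,
    ts_ms: float,
    latency_ms: float,
    peak_to_peak_mm: float = DEFAULT_MOTION_MM,
    gate_phases_pct: Sequence[float] = DEFAULT_GATE_PHASES,
    sg_window: int | None = 5,
    gates_from_actual: bool = False,
    max_eval_s: float | None = None,
) -> GatingErrorReport:
    """Gating error of one trained model on one signal.

    The model must have been trained with ``P_t = latency_ms``.  The
    signal is z-scored, forecast latency-compensated over its length
    (optionally capped at ``max_eval_s`` seconds), and both series are
    scaled to mm with the affine map fitted on the actual signal (so
    systematic amplitude errors survive).
    """
    z = zscore_normalize(signal)
    stop = None
    if max_eval_s is not None:
        stop = int(round(max_eval_s * signal.sampling_rate_hz))
    idx, actual, predicted = predict_series(
        model, z, ts_ms, latency_ms, stop=stop, sg_window=sg_window
    )
    actual_mm, (gain, offset) = scale_to_motion(actual, peak_to_peak_mm)
    predicted_mm = gain * predicted + offset
    times = idx / signal.sampling_rate_hz
    return gating_error(
        actual_mm, predicted_mm, times, latency_ms, signal.sampling_rate_hz,
        signal_id=signal.id, pattern=signal.group or "all",
        gate_phases_pct=gate_phases_pct, gates_from_actual=gates_from_actual,
    )


@dataclass
class FeasibilityCell:
    """Aggregate over the representative cases of one pattern/latency/model."""

    pattern: str
    model_kind: str
    latency_ms: float
    mean_error_mm: float  # mean of per-signal mean errors
    max_error_mm: float  # overall maximum
    n_signals: int
    n_cycles: int


def feasibility_study(
    signals_by_pattern: Mapping[str, Sequence[RespirationSignal]],
    models_by_latency: Mapping[str, Mapping[float, object]],
    ts_ms: float = 1000.0,
    latencies_ms: Sequence[float] = (300.0, 500.0, 700.0),
    peak_to_peak_mm: float = DEFAULT_MOTION_MM,
    gate_phases_pct: Sequence[float] = DEFAULT_GATE_PHASES,
    sg_window: int | None = 5,
    max_eval_s: float | None = None,
) -> list[FeasibilityCell]:
    """Gating-error grid over pattern x latency x model.

    ``models_by_latency[kind][latency]`` must hold a model trained at
    ``P_t = latency``; a missing entry is a configuration error.
    """
    cells: list[FeasibilityCell] = []
    for kind, per_latency in models_by_latency.items():
        for latency in latencies_ms:
            if float(latency) not in {float(k) for k in per_latency}:
                raise InvalidConfigurationError(
                    f"no {kind} model trained at latency {latency} ms"
                )
            model = per_latency[float(latency)]
            for pattern, signals in signals_by_pattern.items():
                reports = [
                    signal_gating_error(
                        model, sig, ts_ms, latency, peak_to_peak_mm,
                        gate_phases_pct, sg_window=sg_window,
                        max_eval_s=max_eval_s,
                    )
                    for sig in signals
                ]
                cells.append(
                    FeasibilityCell(
                        pattern=pattern,
                        model_kind=kind,
                        latency_ms=float(latency),
                        mean_error_mm=float(np.mean([r.mean_error_mm for r in reports])),
                        max_error_mm=float(max(r.max_error_mm for r in reports)),
                        n_signals=len(reports),
                        n_cycles=int(sum(r.n_cycles for r in reports)),
                    )
                )
    return cells
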