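"""The respiration surrogate trace container and its CSV round-trip.

A surrogate trace is a 1-D distance measurement of the patient's chest
surface sampled uniformly (20 Hz for the Anzai AZ-733VI class of gating
devices).  The amplitude is unitless: phase-gating hardware reports a
normalized quantity, and the millimetre interpretation is deferred to the
gating-feasibility stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .errors import FormatError, InvalidConfigurationError

DEFAULT_SAMPLING_RATE_HZ = 20.0

#: relative tolerance on inter-sample gaps when reading external CSV traces
_GAP_TOLERANCE = 0.10


@dataclass
class RespirationSignal:
    """A uniformly sampled respiration surrogate trace.

    Parameters
    ----------
    samples
        Amplitude values on a unitless, normalized scale.
    sampling_rate_hz
        Samples per second (20 Hz for the study device).
    id
        Opaque identifier, unique within a cohort.
    metadata
        Generator parameters or the source-file path, plus an optional
        regularity-group label under the key ``"group"``.
    """

    samples: np.ndarray
    sampling_rate_hz: float
    id: str = "signal"
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise InvalidConfigurationError("samples must be one-dimensional")
        if not self.sampling_rate_hz > 0:
            raise InvalidConfigurationError("sampling_rate_hz must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise InvalidConfigurationError("samples must be finite")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        """Total length in seconds (n_samples / rate)."""
        return self.n_samples / self.sampling_rate_hz

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.n_samples) / self.sampling_rate_hz

    @property
    def group(self) -> str | None:
        """Regularity-group label if one has been assigned."""
        return self.metadata.get("group")

    def with_samples(self, samples: np.ndarray, **meta: Any) -> "RespirationSignal":
        """Copy of this signal with new samples and merged metadata."""
        md = dict(self.metadata)
        md.update(meta)
        return RespirationSignal(
            samples=np.asarray(samples, dtype=np.float64),
            sampling_rate_hz=self.sampling_rate_hz,
            id=self.id,
            metadata=md,
        )


def write_signal_csv(signal: RespirationSignal, path: str | Path) -> Path:
    """Write a trace as CSV with header ``time_s,amplitude`` (6 decimals)."""
    path = Path(path)
    df = pd.DataFrame({"time_s": signal.times, "amplitude": signal.samples})
    df.to_csv(path, index=False, float_format="%.6f")
    sidecar = signal.metadata.get("generator_config")
    if sidecar is not None:
        path.with_suffix(".json").write_text(
            json.dumps(sidecar, indent=2, sort_keys=True) + "\n"
        )
    return path


def read_signal_csv(
    path: str | Path,
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ,
) -> RespirationSignal:
    """Read a ``time_s,amplitude`` CSV trace.

    The time column must be uniform at the expected rate: any gap deviating
    by more than 10% from the nominal sampling interval raises
    :class:`~respigate.errors.FormatError` (out-of-spec rates are rejected,
    not resampled).
    """
    path = Path(path)
    df = pd.read_csv(path)
    if not {"time_s", "amplitude"}.issubset(df.columns):
        raise FormatError(f"{path}: expected columns time_s,amplitude")
    t = df["time_s"].to_numpy(dtype=np.float64)
    amp = df["amplitude"].to_numpy(dtype=np.float64)
    if t.size >= 2:
        dt_nominal = 1.0 / sampling_rate_hz
        gaps = np.diff(t)
        if np.any(np.abs(gaps - dt_nominal) > _GAP_TOLERANCE * dt_nominal):
            raise FormatError(
                f"{path}: non-uniform timestamps (expected {dt_nominal * 1e3:.0f} ms grid)"
            )
    return RespirationSignal(
        samples=amp,
        sampling_rate_hz=sampling_rate_hz,
        id=path.stem,
        metadata={"source": str(path)},
    )
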