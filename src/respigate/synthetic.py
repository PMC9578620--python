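"""Synthetic respiration surrogate generator.

Real cohorts of free-breathing surrogate traces are quasi-periodic with
breath-to-breath variation in both period and depth, slow baseline drift
and measurement noise.  The generator reproduces that structure with a
Lujan-style ``cos^2n`` waveform built cycle by cycle: cycle *i* has its own
period ``tau_i`` and peak-to-valley depth ``b_i`` drawn around the
configured means, so period and amplitude irregularity are independent
knobs.  Cycles are valley-anchored (they start and end at the flat exhale
dwell, with the sharp inhale peak mid-cycle), which keeps the concatenated
trace continuous under period jitter and makes every cycle carry exactly
one interior peak of height ``b_i`` above its valleys.

Four regularity classes mirror a gated-radiotherapy study cohort:
``regular`` (small jitter everywhere), ``type1`` (irregular period),
``type2`` (irregular amplitude) and ``type3`` (both).
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .errors import InvalidConfigurationError
from .signal import DEFAULT_SAMPLING_RATE_HZ, RespirationSignal

#: regularity-group labels, in canonical order
GROUPS: tuple[str, ...] = ("regular", "type1", "type2", "type3")

#: recording-length range of the study cohort, seconds
COHORT_DURATION_RANGE_S: tuple[float, float] = (84.35, 272.50)


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the cycle-by-cycle breathing-trace generator.

    All amplitudes are unitless (normalized scale); times are seconds.
    """

    base_period_s: float = 4.0
    base_amplitude: float = 1.0
    exponent_n: int = 2
    period_jitter_sd: float = 0.0
    amplitude_jitter_sd: float = 0.0
    drift_rate: float = 0.0
    noise_sd: float = 0.0
    duration_s: float = 145.26
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ
    seed: int = 0

    def validate(self) -> None:
        nonneg = {
            "period_jitter_sd": self.period_jitter_sd,
            "amplitude_jitter_sd": self.amplitude_jitter_sd,
            "noise_sd": self.noise_sd,
        }
        positive = {
            "base_period_s": self.base_period_s,
            "base_amplitude": self.base_amplitude,
            "duration_s": self.duration_s,
            "sampling_rate_hz": self.sampling_rate_hz,
        }
        for name, value in {**nonneg, **positive, "drift_rate": self.drift_rate}.items():
            if not math.isfinite(value):
                raise InvalidConfigurationError(f"{name} must be finite, got {value!r}")
        for name, value in nonneg.items():
            if value < 0:
                raise InvalidConfigurationError(f"{name} must be >= 0, got {value}")
        for name, value in positive.items():
            if value <= 0:
                raise InvalidConfigurationError(f"{name} must be > 0, got {value}")
        if self.exponent_n < 1:
            raise InvalidConfigurationError(
                f"exponent_n must be >= 1, got {self.exponent_n}"
            )


def _cos2n_mean(n: int) -> float:
    # time-average of cos^(2n) over a full period: C(2n, n) / 4^n
    return math.comb(2 * n, n) / 4.0**n


def generate_signal(config: GeneratorConfig, signal_id: str = "synthetic") -> RespirationSignal:
    """Generate one surrogate trace from a :class:`GeneratorConfig`.

    Cycle *i* has period ``tau_i = base_period_s + eps_tau`` and
    peak-to-valley depth ``b_i = base_amplitude + eps_b`` with zero-mean
    normal jitter, truncated at ``0.5 * base_period_s`` and
    ``0.2 * base_amplitude`` so no cycle degenerates.  Within a cycle the
    waveform is the mean-removed ``b_i * cos^2n`` pulse; linear drift and
    white sample noise are added on top.  Identical ``(config, seed)``
    pairs give bit-identical arrays.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_total = int(round(config.duration_s * config.sampling_rate_hz))
    dt = 1.0 / config.sampling_rate_hz
    t = np.arange(n_total) * dt
    samples = np.empty(n_total, dtype=np.float64)

    m_n = _cos2n_mean(config.exponent_n)
    t_start = 0.0
    k = 0  # next sample index to fill
    while k < n_total:
        tau = config.base_period_s + rng.normal(0.0, 1.0) * config.period_jitter_sd
        tau = max(tau, 0.5 * config.base_period_s)
        b = config.base_amplitude + rng.normal(0.0, 1.0) * config.amplitude_jitter_sd
        b = max(b, 0.2 * config.base_amplitude)
        t_end = t_start + tau
        k_end = min(n_total, int(math.ceil(t_end / dt - 1e-12)))
        local = t[k:k_end] - t_start
        # valley-anchored cos^2n pulse: sin^2n(pi t/tau) = cos^2n(pi(t - tau/2)/tau)
        samples[k:k_end] = b * (
            np.sin(np.pi * local / tau) ** (2 * config.exponent_n) - m_n
        )
        k = k_end
        t_start = t_end

    samples += config.drift_rate * t
    if config.noise_sd > 0:
        samples += rng.normal(0.0, config.noise_sd, size=n_total)

    return RespirationSignal(
        samples=samples,
        sampling_rate_hz=config.sampling_rate_hz,
        id=signal_id,
        metadata={"generator_config": asdict(config)},
    )


def default_group_configs(
    base: GeneratorConfig | None = None,
    period_jitter_sd: float = 0.6,
    amplitude_jitter_sd: float = 0.30,
) -> dict[str, GeneratorConfig]:
    """Per-group generator templates with well-separated jitter knobs.

    ``regular`` keeps a small residual jitter (perfectly metronomic
    breathing does not occur in guided free-breathing either); the three
    irregular types switch on the period and/or amplitude knob.
    """
    if base is None:
        base = GeneratorConfig(
            period_jitter_sd=0.08,
            amplitude_jitter_sd=0.03,
            drift_rate=0.002,
            noise_sd=0.01,
        )
    return {
        "regular": base,
        "type1": replace(base, period_jitter_sd=period_jitter_sd),
        "type2": replace(base, amplitude_jitter_sd=amplitude_jitter_sd),
        "type3": replace(
            base,
            period_jitter_sd=period_jitter_sd,
            amplitude_jitter_sd=amplitude_jitter_sd,
        ),
    }


def generate_cohort(
    n_per_group: int,
    group_configs: Mapping[str, GeneratorConfig] | None = None,
    seed: int = 0,
    duration_range_s: tuple[float, float] = COHORT_DURATION_RANGE_S,
    groups: Sequence[str] = GROUPS,
) -> list[RespirationSignal]:
    """Generate ``len(groups) * n_per_group`` labeled signals.

    Recording lengths are drawn uniformly from ``duration_range_s``
    (defaulting to the 84.35-272.50 s range of clinical gating records);
    each signal gets an independent child seed so the cohort is
    reproducible as a whole.
    """
    if n_per_group < 1:
        raise InvalidConfigurationError("n_per_group must be >= 1")
    configs = dict(group_configs) if group_configs is not None else default_group_configs()
    missing = [g for g in groups if g not in configs]
    if missing:
        raise InvalidConfigurationError(f"missing generator config for groups {missing}")

    rng = np.random.default_rng(seed)
    child_seeds = np.random.SeedSequence(seed).generate_state(len(groups) * n_per_group)
    signals: list[RespirationSignal] = []
    i = 0
    for group in groups:
        for j in range(n_per_group):
            duration = rng.uniform(*duration_range_s)
            cfg = replace(
                configs[group],
                duration_s=float(duration),
                seed=int(child_seeds[i] % (2**31)),
            )
            sig = generate_signal(cfg, signal_id=f"{group}-{j:03d}")
            sig.metadata["group"] = group
            signals.append(sig)
            i += 1
    return signals
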