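import numpy as np
import pytest

from respigate.signal import RespirationSignal
from respigate.synthetic import GeneratorConfig, generate_signal


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def regular_signal():
    """A clean quasi-regular trace: 4-s breaths, 60 s at 20 Hz."""
    cfg = GeneratorConfig(
        base_period_s=4.0, duration_s=60.0, exponent_n=2,
        period_jitter_sd=0.05, amplitude_jitter_sd=0.02, noise_sd=0.005,
        seed=42,
    )
    return generate_signal(cfg, signal_id="regular-fixture")


@pytest.fixture
def sine_signal():
    """Pure sinusoid, period 4 s, 20 s at 20 Hz."""
    t = np.arange(400) / 20.0
    return RespirationSignal(
        samples=np.sin(2 * np.pi * t / 4.0), sampling_rate_hz=20.0, id="sine"
    )


def tiny_cohort(n=6, duration_s=(30.0, 40.0), seed=9):
    """Small mixed cohort for fast orchestration tests."""
    from respigate.synthetic import default_group_configs, generate_cohort

    configs = default_group_configs()
    half = n // 2
    out = generate_cohort(half, configs, seed=seed,
                          duration_range_s=duration_s, groups=("regular",))
    out += generate_cohort(n - half, configs, seed=seed + 1,
                           duration_range_s=duration_s, groups=("type2",))
    return out
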