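"""Phase decomposition and millimetre gating-error translation."""

import numpy as np
import pytest

from respigate.errors import DegenerateSignalError, InvalidConfigurationError
from respigate.gating import (
    feasibility_study,
    gating_error,
    phase_decompose,
    scale_to_motion,
    signal_gating_error,
)
from respigate.irregularity import detect_extrema
from respigate.signal import RespirationSignal
from respigate.synthetic import GeneratorConfig, generate_signal


class TestScaleToMotion:
    def test_symmetric_unit_signal_maps_to_plus_minus_five(self):
        x = np.array([-1.0, 0.0, 1.0])
        scaled, _ = scale_to_motion(x, 10.0)
        np.testing.assert_allclose(scaled, [-5.0, 0.0, 5.0], atol=1e-12)

    def test_idempotent_on_already_scaled_signal(self, rng):
        x = rng.normal(size=200)
        once, _ = scale_to_motion(x, 10.0)
        twice, _ = scale_to_motion(once, 10.0)
        np.testing.assert_allclose(once, twice, atol=1e-9)

    def test_peak_to_peak_range_is_exact(self, rng):
        x = rng.normal(size=500) * 3.7 + 12.0
        scaled, _ = scale_to_motion(x, 10.0)
        assert scaled.max() - scaled.min() == pytest.approx(10.0, abs=1e-9)
        assert scaled.max() == pytest.approx(5.0, abs=1e-9)

    def test_constant_signal_rejected(self):
        with pytest.raises(DegenerateSignalError):
            scale_to_motion(np.full(10, 2.0), 10.0)


class TestPhaseDecompose:
    def test_pure_periodic_gate_times(self):
        # peaks every 4 s; 30%/70% gates at 1.2 s and 2.8 s into each cycle
        t = np.arange(400) / 20.0
        sig = RespirationSignal(np.cos(2 * np.pi * t / 4.0), 20.0, id="cos")
        d = phase_decompose(sig)
        offsets = d.gate_times_s - d.cycle_starts_s[:-1][:, None]
        np.testing.assert_allclose(offsets[:, 0], 1.2, atol=1e-9)
        np.testing.assert_allclose(offsets[:, 1], 2.8, atol=1e-9)

    def test_gate_pair_count_equals_complete_cycles(self, regular_signal):
        d = phase_decompose(regular_signal)
        peaks, _ = detect_extrema(regular_signal)
        assert d.gate_times_s.shape == (len(peaks) - 1, 2)

    def test_jittered_cycles_use_their_own_periods(self):
        cfg = GeneratorConfig(period_jitter_sd=0.5, duration_s=80.0, seed=21)
        sig = generate_signal(cfg)
        d = phase_decompose(sig)
        peaks, _ = detect_extrema(sig)
        t_peaks = sig.times[peaks]
        for k in range(d.n_cycles):  # independent per-cycle computation
            period = t_peaks[k + 1] - t_peaks[k]
            assert d.gate_times_s[k, 0] == pytest.approx(
                t_peaks[k] + 0.3 * period, abs=1e-12)
            assert d.gate_times_s[k, 1] == pytest.approx(
                t_peaks[k] + 0.7 * period, abs=1e-12)

    def test_gate_phases_validated(self, regular_signal):
        with pytest.raises(InvalidConfigurationError):
            phase_decompose(regular_signal, gate_phases_pct=(0.0, 70.0))


class TestGatingError:
    def _sinusoid_mm(self, delta_t=0.0, n=1200, rate=20.0, period=4.0):
        t = np.arange(n) / rate
        return t, 5.0 * np.sin(2 * np.pi * (t - delta_t) / period)

    def test_perfect_prediction_gives_zero_error(self):
        t, z = self._sinusoid_mm()
        for latency in (300.0, 500.0, 700.0):
            rep = gating_error(z, z.copy(), t, latency, 20.0)
            assert rep.mean_error_mm == 0.0
            assert rep.max_error_mm == 0.0

    def test_shifted_sinusoid_matches_closed_form(self):
        period, dt = 4.0, 0.3
        t, actual = self._sinusoid_mm()
        _, shifted = self._sinusoid_mm(delta_t=dt)
        rep = gating_error(actual, shifted, t, 300.0, 20.0)
        # closed form |z(t_g) - z(t_g - dt)| at the predicted signal's gates
        d = phase_decompose(RespirationSignal(shifted, 20.0, id="s"))
        z = lambda tt: 5.0 * np.sin(2 * np.pi * tt / period)
        expected = np.abs(z(d.gate_times_s) - z(d.gate_times_s - dt))
        # linear interpolation at 20 Hz bounds the residual discretization
        np.testing.assert_allclose(rep.errors_mm, expected, atol=1.5e-2)
        # and against an interpolating oracle the match is exact
        oracle = np.abs(np.interp(d.gate_times_s, t, actual)
                        - np.interp(d.gate_times_s, t, shifted))
        np.testing.assert_allclose(rep.errors_mm, oracle, atol=1e-9)

    def test_translation_invariance(self, rng):
        t, actual = self._sinusoid_mm()
        predicted = actual + rng.normal(0, 0.5, actual.size)
        a = gating_error(actual, predicted, t, 500.0, 20.0)
        b = gating_error(actual + 3.3, predicted + 3.3, t, 500.0, 20.0)
        np.testing.assert_allclose(a.errors_mm, b.errors_mm, atol=1e-9)

    def test_mean_not_above_max(self, rng):
        t, actual = self._sinusoid_mm()
        rep = gating_error(actual, actual + rng.normal(0, 1, actual.size),
                           t, 500.0, 20.0)
        assert 0.0 <= rep.mean_error_mm <= rep.max_error_mm


class _PerfectPredictor:
    """Looks up the exact future value for every known window (test oracle)."""

    def __init__(self, signals, ts_ms, pt_ms):
        from respigate.preprocessing import make_windows, zscore_normalize

        self.table = {}
        for sig in signals:
            ds = make_windows(zscore_normalize(sig), ts_ms, pt_ms)
            for row, target in zip(ds.inputs, ds.targets):
                self.table[row.tobytes()] = target

    def predict(self, x, batch_size=0):
        return np.array([self.table[np.asarray(row, float).tobytes()] for row in x])


class TestFeasibilityStudy:
    def test_perfect_oracle_gives_zero_mm(self, regular_signal):
        oracle = _PerfectPredictor([regular_signal], 1000.0, 500.0)
        rep = signal_gating_error(oracle, regular_signal, 1000.0, 500.0,
                                  sg_window=None)
        assert rep.mean_error_mm == pytest.approx(0.0, abs=1e-12)
        assert rep.max_error_mm == pytest.approx(0.0, abs=1e-12)

    def test_grid_size_and_missing_model_error(self, regular_signal):
        oracle = _PerfectPredictor([regular_signal], 1000.0, 500.0)
        cells = feasibility_study(
            {"regular": [regular_signal]},
            {"oracle": {500.0: oracle}},
            latencies_ms=(500.0,), sg_window=None,
        )
        assert len(cells) == 1  # patterns x latencies x models
        assert cells[0].mean_error_mm == pytest.approx(0.0, abs=1e-12)
        with pytest.raises(InvalidConfigurationError):
            feasibility_study({"regular": [regular_signal]},
                              {"oracle": {500.0: oracle}},
                              latencies_ms=(300.0,))
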