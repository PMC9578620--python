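"""Normalization, S-G filtering, windowing and split mechanics."""

import numpy as np
import pytest

from respigate.errors import (
    DegenerateSignalError,
    EmptyDatasetError,
    FormatError,
    InvalidParameterError,
    InvalidSplitError,
)
from respigate.preprocessing import (
    WindowedDataset,
    build_datasets,
    make_windows,
    savitzky_golay,
    split_cohort,
    window_counts,
    zscore_array,
    zscore_normalize,
)
from respigate.signal import RespirationSignal, read_signal_csv, write_signal_csv


def _sig(samples, rate=20.0, sid="s"):
    return RespirationSignal(samples=np.asarray(samples, float),
                             sampling_rate_hz=rate, id=sid)


class TestZScore:
    def test_three_point_example(self):
        np.testing.assert_allclose(
            zscore_array([1.0, 2.0, 3.0]), [-1.224745, 0.0, 1.224745], atol=1e-6
        )

    def test_idempotent_on_standardized_signal(self, regular_signal):
        once = zscore_normalize(regular_signal)
        twice = zscore_normalize(once)
        np.testing.assert_allclose(once.samples, twice.samples, atol=1e-9)
        assert abs(once.samples.mean()) < 1e-9
        assert abs(once.samples.std() - 1.0) < 1e-9

    def test_constant_signal_rejected(self):
        with pytest.raises(DegenerateSignalError):
            zscore_array([5.0, 5.0, 5.0])


def _sg_oracle(x, window, polyorder):
    """Sliding least-squares polynomial fit with mirror padding."""
    half = window // 2
    padded = np.concatenate([x[1:half + 1][::-1], x, x[-half - 1:-1][::-1]])
    out = np.empty_like(x)
    t = np.arange(window) - half
    for i in range(x.size):
        coeffs = np.polyfit(t, padded[i:i + window], polyorder)
        out[i] = np.polyval(coeffs, 0.0)
    return out


class TestSavitzkyGolay:
    def test_exact_on_cubic_polynomial(self):
        # exact reproduction wherever the fit window lies inside the series
        # (the mirror-padded edges see a non-polynomial extension)
        t = np.linspace(-1, 1, 60)
        x = 2 * t**3 - t**2 + 0.5 * t - 3
        np.testing.assert_allclose(savitzky_golay(x, 5, 3)[2:-2], x[2:-2], atol=1e-9)

    def test_constant_series_unchanged(self):
        x = np.full(30, 2.5)
        np.testing.assert_allclose(savitzky_golay(x, 7, 2), x, atol=1e-12)

    def test_matches_sliding_polyfit_oracle(self, rng):
        x = rng.normal(size=80)
        np.testing.assert_allclose(
            savitzky_golay(x, 7, 2), _sg_oracle(x, 7, 2), atol=1e-9
        )

    @pytest.mark.parametrize("window,order", [(4, 2), (5, 5), (5, 6)])
    def test_invalid_parameters_rejected(self, window, order):
        with pytest.raises(InvalidParameterError):
            savitzky_golay(np.arange(30.0), window, order)


class TestMakeWindows:
    def test_pair_count_example(self, rng):
        ds = make_windows(_sig(rng.normal(size=50)), 1000, 500)
        assert ds.n_pairs == 21  # N - L - H + 1 = 50 - 20 - 10 + 1
        assert ds.inputs.shape == (21, 20)

    def test_single_pair_boundary_case(self, rng):
        x = rng.normal(size=30)
        ds = make_windows(_sig(x), 1000, 500)
        assert ds.n_pairs == 1
        assert ds.targets[0] == x[29]
        np.testing.assert_array_equal(ds.inputs[0], x[:20])

    def test_too_short_raises(self, rng):
        with pytest.raises(EmptyDatasetError):
            make_windows(_sig(rng.normal(size=29)), 1000, 500)

    def test_count_formula_on_random_conditions(self, rng):
        for _ in range(200):
            L = int(rng.integers(2, 40))
            H = int(rng.integers(1, 20))
            N = int(rng.integers(L + H, L + H + 200))
            ds = make_windows(_sig(rng.normal(size=N)), L * 50, H * 50)
            assert ds.n_pairs == N - L - H + 1

    def test_off_grid_durations_rejected(self, rng):
        with pytest.raises(InvalidParameterError):
            make_windows(_sig(rng.normal(size=100)), 1025, 500)
        with pytest.raises(InvalidParameterError):
            window_counts(1000, -500, 20.0)


class TestSplit:
    def _cohort(self, rng, n=540):
        return [
            _sig(rng.normal(size=int(rng.integers(400, 900))), sid=f"sig{i:03d}")
            for i in range(n)
        ]

    def test_study_proportions(self, rng):
        cohort = self._cohort(rng)
        split = split_cohort(cohort, n_test=60, seed=0)
        assert len(split.test_signals) == 60
        assert len(split.train_signals) == 480
        assert not set(split.test_signals) & set(split.train_signals)

    def test_temporal_boundary_and_ratio(self, rng):
        cohort = [_sig(rng.normal(size=1000), sid="a"), _sig(rng.normal(size=1000), sid="b")]
        split = split_cohort(cohort, n_test=1, train_fraction=0.7, seed=3)
        sid = split.train_signals[0]
        assert split.boundaries[sid] == 700

    def test_no_leakage_into_validation_windows(self, rng):
        cohort = [_sig(rng.normal(size=800), sid=f"s{i}") for i in range(4)]
        split = split_cohort(cohort, n_test=1, seed=1)
        _, val, _ = build_datasets(cohort, split, 1000, 500, normalize=False)
        by_id = {s.id: s for s in cohort}
        # every validation target must come from at or past the boundary
        for sid in split.train_signals:
            b = split.boundaries[sid]
            mask = val.source_ids == sid
            tail = by_id[sid].samples[b:]
            ds = make_windows(_sig(tail), 1000, 500)
            np.testing.assert_array_equal(val.targets[mask], ds.targets)

    def test_target_smoothing_flag_changes_targets_only(self, rng):
        cohort = [_sig(np.cumsum(rng.normal(size=900)), sid=f"s{i}")
                  for i in range(3)]
        split = split_cohort(cohort, n_test=1, seed=2)
        raw_tr, _, _ = build_datasets(cohort, split, 1000, 500)
        sm_tr, _, _ = build_datasets(cohort, split, 1000, 500,
                                     sg_filter_targets=True)
        np.testing.assert_array_equal(raw_tr.inputs, sm_tr.inputs)
        assert not np.allclose(raw_tr.targets, sm_tr.targets)

    def test_same_seed_same_membership(self, rng):
        cohort = self._cohort(rng, n=50)
        a = split_cohort(cohort, 10, seed=5).test_signals
        b = split_cohort(cohort, 10, seed=5).test_signals
        assert a == b

    def test_impossible_split_rejected(self, rng):
        cohort = self._cohort(rng, n=5)
        with pytest.raises(InvalidSplitError):
            split_cohort(cohort, n_test=5)
        with pytest.raises(InvalidSplitError):
            split_cohort(cohort, n_test=2, train_fraction=1.5)


class TestExternalInterfaces:
    def test_csv_round_trip(self, tmp_path, regular_signal):
        path = write_signal_csv(regular_signal, tmp_path / "trace.csv")
        back = read_signal_csv(path)
        np.testing.assert_allclose(back.samples, regular_signal.samples, atol=1e-6)
        assert back.sampling_rate_hz == regular_signal.sampling_rate_hz

    def test_non_uniform_timestamps_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("time_s,amplitude\n0.00,1.0\n0.05,1.1\n0.20,1.2\n")
        with pytest.raises(FormatError):
            read_signal_csv(path)

    def test_windowed_dataset_persistence(self, tmp_path, rng):
        ds = make_windows(_sig(rng.normal(size=120)), 1000, 500)
        ds.save(tmp_path / "ds.npz")
        back = WindowedDataset.load(tmp_path / "ds.npz")
        np.testing.assert_array_equal(back.inputs, ds.inputs)
        np.testing.assert_array_equal(back.targets, ds.targets)
        assert (back.ts_ms, back.pt_ms) == (ds.ts_ms, ds.pt_ms)
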