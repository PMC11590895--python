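"""Time/frequency window features and the two selection filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from calfsense.core import ALL_CHANNELS
from calfsense.errors import ShapeError
from calfsense.features import (
    STATISTICS,
    dominant_frequency,
    drop_correlated,
    extract_features,
    feature_columns,
    gradient_series,
    iqr,
    select_by_importance,
    zero_crossings,
)
from calfsense.windowing import Window


def naive_dft_dominant(x, fs):
    """Direct evaluation of the DFT sum (O(N^2)) on the centered series."""
    x = np.asarray(x, float)
    x = x - x.mean()
    n = len(x)
    best_k, best_p = 0, 0.0
    for k in range(1, n // 2 + 1):
        Xk = sum(x[m] * np.exp(-2j * np.pi * k * m / n) for m in range(n))
        p = abs(Xk) ** 2
        if p > best_p:
            best_k, best_p = k, p
    if best_p <= 0:
        return 0.0, 0.0
    return best_k * fs / n, best_p


class TestDominantFrequency:
    def test_pure_sinusoid_bin_aligned(self):
        fs, n = 25.0, 250
        t = np.arange(n) / fs
        freq, power = dominant_frequency(np.sin(2 * np.pi * 2.0 * t), fs)
        assert freq == pytest.approx(2.0)
        assert power > 0

    def test_constant_series_convention(self):
        assert dominant_frequency(np.full(100, 3.7), fs=25.0) == (0.0, 0.0)

    def test_strongest_component_wins(self):
        fs, n = 25.0, 250
        t = np.arange(n) / fs
        x = np.sin(2 * np.pi * 1.0 * t) + 3.0 * np.sin(2 * np.pi * 5.0 * t)
        assert dominant_frequency(x, fs)[0] == pytest.approx(5.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_naive_dft(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 256))
        x = rng.normal(0, 1, n)
        freq, power = dominant_frequency(x, fs=25.0)
        freq_o, power_o = naive_dft_dominant(x, fs=25.0)
        assert freq == pytest.approx(freq_o)
        assert power == pytest.approx(power_o, rel=1e-9)

    def test_off_bin_frequency_within_one_bin(self):
        fs, n = 25.0, 250
        t = np.arange(n) / fs
        freq, _ = dominant_frequency(np.sin(2 * np.pi * 1.53 * t), fs)
        assert abs(freq - 1.53) <= fs / n


class TestScalarFeatures:
    def test_iqr_examples(self):
        assert iqr(np.full(10, 2.0)) == 0.0
        assert iqr(np.arange(1, 101)) == pytest.approx(49.5)

    @settings(deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-100, 100), min_size=2, max_size=50),
        st.floats(-50, 50),
        st.floats(0.1, 10),
    )
    def test_iqr_affine_covariance(self, xs, shift, scale):
        x = np.array(xs)
        assert iqr(x + shift) == pytest.approx(iqr(x), abs=1e-8)
        assert iqr(scale * x) == pytest.approx(scale * iqr(x), rel=1e-9, abs=1e-8)

    def test_zero_crossings_examples(self):
        assert zero_crossings(np.array([1.0, -1.0, 1.0, -1.0])) == 3
        assert zero_crossings(np.arange(10.0)) == 1  # centered ramp
        assert zero_crossings(np.full(10, 5.0)) == 0

    def test_zero_crossings_zero_inherits_previous_sign(self):
        # zero-mean [1, 0, -1]: the exact zero takes the preceding + sign,
        # so the single true crossing is still counted
        assert zero_crossings(np.array([1.0, 0.0, -1.0])) == 1
        # a touch of zero without a crossing is not counted
        assert zero_crossings(np.array([1.0, 0.0, 1.0, -1.0, -1.0])) == 1

    @settings(deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(-10, 10), min_size=3, max_size=40),
        st.sampled_from([0.5, 1.0, 2.0, 8.0]),
    )
    def test_zero_crossings_scale_invariance(self, xs, a):
        x = np.array(xs, float)
        assert zero_crossings(a * x) == zero_crossings(x)

    def test_zero_crossings_shift_invariance(self):
        x = np.array([3.0, -1.0, 2.0, -5.0, 4.0, 0.0, -2.0])
        for b in (-7.0, -0.5, 4.0):
            assert zero_crossings(x + b) == zero_crossings(x)

    def test_gradient_series(self):
        x = 2.0 * np.arange(10)
        np.testing.assert_allclose(gradient_series(x, dt=0.04), np.full(9, 50.0))
        np.testing.assert_allclose(gradient_series(np.full(5, 1.0), 0.04), 0.0)
        assert len(gradient_series(np.arange(7.0), 1.0)) == 6
        with pytest.raises(ValueError):
            gradient_series(x, dt=0.0)


def _window_from(signals, calf_id="c1", start=0):
    return Window(calf_id, start, start + signals.shape[0], start / 25.0, signals)


class TestExtractFeatures:
    def test_full_grid_dimensions(self):
        rng = np.random.default_rng(0)
        windows = [_window_from(rng.normal(0, 1, (250, 8))) for _ in range(10)]
        table = extract_features(windows, "model1", fs=25.0)
        assert len(table) == 10
        assert len(feature_columns(table)) == len(ALL_CHANNELS) * len(STATISTICS) == 96

    def test_gyro_oscillation_recovered(self):
        fs, n = 25.0, 250
        t = np.arange(n) / fs
        sig = np.zeros((n, 8))
        sig[:, 4] = 30.0 * np.sin(2 * np.pi * 1.5 * t)  # gy
        table = extract_features([_window_from(sig)], "model1", fs)
        assert table["gy_dom_freq"][0] == pytest.approx(1.5, abs=fs / n)

    def test_deterministic_rows(self):
        rng = np.random.default_rng(1)
        sig = rng.normal(0, 1, (250, 8))
        table = extract_features([_window_from(sig), _window_from(sig)], "model2", 25.0)
        feats = feature_columns(table)
        pd.testing.assert_series_equal(
            table.loc[0, feats], table.loc[1, feats], check_names=False
        )

    def test_non_uniform_lengths_rejected(self):
        rng = np.random.default_rng(2)
        windows = [
            _window_from(rng.normal(0, 1, (250, 8))),
            _window_from(rng.normal(0, 1, (100, 8))),
        ]
        with pytest.raises(ShapeError):
            extract_features(windows, "model1", 25.0)

    def test_batch_features_match_scalar_ops(self):
        """Grid cells agree with the standalone single-series operations."""
        rng = np.random.default_rng(3)
        sig = rng.normal(0, 1, (250, 8))
        table = extract_features([_window_from(sig)], "model1", 25.0)
        gx = sig[:, 3]
        assert table["gx_iqr"][0] == pytest.approx(iqr(gx))
        assert table["gx_zero_crossings"][0] == zero_crossings(gx)
        freq, power = dominant_frequency(gx, 25.0)
        assert table["gx_dom_freq"][0] == pytest.approx(freq)
        assert table["gx_dom_power"][0] == pytest.approx(power)
        grad = gradient_series(gx, 1 / 25.0)
        assert table["gx_grad_max_abs"][0] == pytest.approx(np.abs(grad).max())
        assert table["gx_grad_sd"][0] == pytest.approx(grad.std())


def _feature_table(cols: dict, labels=None) -> pd.DataFrame:
    df = pd.DataFrame(cols)
    df.insert(0, "calf_id", "c1")
    df.insert(1, "start_s", np.arange(len(df), dtype=float))
    df.insert(2, "action_label", labels if labels is not None else "others")
    df.insert(3, "state_label", "lying")
    return df


class TestSelection:
    def test_duplicate_feature_dropped(self):
        rng = np.random.default_rng(0)
        f = rng.normal(0, 1, 100)
        table = _feature_table({"f1": f, "f2": 2 * f, "f3": rng.normal(0, 1, 100)})
        out, report = drop_correlated(table, threshold=0.9)
        assert feature_columns(out) == ["f1", "f3"]
        assert report.dropped_correlated == [("f1", "f2", pytest.approx(1.0))]

    def test_independent_noise_survives(self):
        rng = np.random.default_rng(1)
        table = _feature_table({f"f{i}": rng.normal(0, 1, 500) for i in range(10)})
        out, report = drop_correlated(table, threshold=0.9)
        assert len(feature_columns(out)) == 10
        assert report.dropped_correlated == []

    def test_constant_column_dropped(self):
        rng = np.random.default_rng(2)
        table = _feature_table({"f1": np.full(50, 3.0), "f2": rng.normal(0, 1, 50)})
        out, _ = drop_correlated(table)
        assert feature_columns(out) == ["f2"]

    def test_selection_partitions_features(self):
        rng = np.random.default_rng(3)
        f = rng.normal(0, 1, 200)
        table = _feature_table(
            {"a": f, "b": f + rng.normal(0, 0.01, 200), "c": rng.normal(0, 1, 200)}
        )
        out, report = drop_correlated(table, threshold=0.9)
        dropped = [d for _, d, _ in report.dropped_correlated]
        assert sorted(report.surviving + dropped) == ["a", "b", "c"]

    def test_informative_feature_survives_importance(self):
        rng = np.random.default_rng(4)
        f1 = rng.normal(0, 1, 400)
        labels = np.where(f1 > np.median(f1), "rumination", "others")
        table = _feature_table({"f1": f1, "f2": rng.normal(0, 1, 400)}, labels)
        out, report = select_by_importance(table, table["action_label"], seed=0)
        assert "f1" in feature_columns(out)
        assert report.importances["f1"] > 0.9

    def test_top_k_all_keeps_everything(self):
        rng = np.random.default_rng(5)
        labels = np.where(rng.random(100) > 0.5, "feeding", "others")
        table = _feature_table(
            {"f1": rng.normal(0, 1, 100), "f2": rng.normal(0, 1, 100)}, labels
        )
        out, _ = select_by_importance(table, table["action_label"], top_k=2, seed=0)
        assert feature_columns(out) == ["f1", "f2"]
        with pytest.raises(ValueError):
            select_by_importance(table, table["action_label"], top_k=3)

    def test_single_class_rejected(self):
        table = _feature_table({"f1": np.arange(10.0)})
        with pytest.raises(ValueError):
            select_by_importance(table, table["action_label"])
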