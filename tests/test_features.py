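"""Window slicing and the six per-channel statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sp_stats

import pocketmotion as pm
from pocketmotion.features import (
    FEATURE_NAMES,
    SIGNAL_NAMES,
    STAT_NAMES,
    Window,
    iqr,
    kurtosis,
    skewness,
)
from pocketmotion.preprocess import SignalSet


def _signals(n, rate=25.0, seed=0):
    rng = np.random.default_rng(seed)
    return SignalSet(
        t=np.arange(n) / rate,
        rate_hz=rate,
        la3a=np.abs(rng.normal(size=n)),
        gyr3a=np.abs(rng.normal(size=n)),
        mag_x=rng.normal(size=n),
        mag_y=rng.normal(size=n),
        mag_z=rng.normal(size=n),
    )


class TestSlideWindows:
    def test_60s_at_25hz_gives_74_windows(self):
        sig = _signals(1500)
        ws = pm.slide_windows(sig)  # 1.6 s windows, 50 % overlap
        assert len(ws) == 74  # floor((1500 - 40)/20) + 1

    def test_stride_is_0_8_seconds(self):
        sig = _signals(200)
        ws = pm.slide_windows(sig)
        strides = np.diff([w.start_s for w in ws])
        np.testing.assert_allclose(strides, 0.8, atol=1e-12)

    def test_zero_overlap_tiles_disjointly(self):
        sig = _signals(205)
        ws = pm.slide_windows(sig, overlap=0.0)
        assert len(ws) == 205 // 40
        starts = [w.start_s for w in ws]
        np.testing.assert_allclose(np.diff(starts), 1.6, atol=1e-12)

    def test_short_signal_gives_no_windows(self):
        assert pm.slide_windows(_signals(30)) == []

    def test_labeled_windows_lie_inside_one_annotation(self):
        sig = _signals(1000)
        anns = [
            pm.ActivityAnnotation(0.0, 10.0, "walking"),
            pm.ActivityAnnotation(10.0, 40.0, "running"),
        ]
        ws = pm.slide_windows(sig, annotations=anns)
        for w in ws:
            covering = [
                a for a in anns
                if a.start_s <= w.start_s and w.start_s + 1.6 <= a.end_s
            ]
            assert len(covering) == 1 and covering[0].label == w.label
        # windows straddling the 10 s boundary are dropped, not mislabeled
        assert all(not (w.start_s < 10.0 < w.start_s + 1.6) for w in ws)

    def test_unannotated_signal_keeps_all_windows_unlabeled(self):
        ws = pm.slide_windows(_signals(200))
        assert all(w.label is None for w in ws)


# -- independent brute-force statistics (pure-Python evaluation) -----------


def _brute_skew(xs):
    n = len(xs)
    avg = sum(xs) / n
    std = math.sqrt(sum((v - avg) ** 2 for v in xs) / (n - 1))
    return n / ((n - 1) * (n - 2)) * sum(((v - avg) / std) ** 3 for v in xs)


def _brute_kurt(xs):
    n = len(xs)
    avg = sum(xs) / n
    std = math.sqrt(sum((v - avg) ** 2 for v in xs) / (n - 1))
    s2 = sum((v - avg) ** 2 for v in xs)
    s4 = sum((v - avg) ** 4 for v in xs)
    return (n * (n + 1) * s4 - 3 * s2 * s2 * (n - 1)) / (
        (n - 1) * (n - 2) * (n - 3) * std**4
    )


def _brute_iqr(xs):
    # type-7 (linear interpolation) percentiles
    def pct(p):
        s = sorted(xs)
        h = (len(s) - 1) * p
        lo = math.floor(h)
        return s[lo] + (h - lo) * (s[min(lo + 1, len(s) - 1)] - s[lo])

    return pct(0.75) - pct(0.25)


class TestStatistics:
    def test_symmetric_sample_has_zero_skew(self):
        assert skewness([1, 2, 3, 4, 5]) == pytest.approx(0.0, abs=1e-12)

    def test_skew_affine_invariance_and_sign_flip(self):
        x = np.array([0.1, 2.0, 2.1, 5.0, 9.0, 0.3])
        assert skewness(3 * x + 7) == pytest.approx(skewness(x), rel=1e-12)
        assert skewness(-x) == pytest.approx(-skewness(x), rel=1e-12)

    def test_skew_fixture_matches_brute_force(self):
        rng = np.random.default_rng(123)
        x = rng.normal(2.0, 1.5, size=40)
        assert skewness(x) == pytest.approx(_brute_skew(list(x)), rel=1e-9)

    def test_kurt_affine_invariance(self):
        x = np.array([1.0, 2, 3, 4, 5, 6, 7, 100])
        assert kurtosis(-2.5 * x + 1) == pytest.approx(kurtosis(x), rel=1e-12)

    def test_kurt_fixture_matches_brute_force(self):
        x = [1.0, 2, 3, 4, 5, 6, 7, 100]
        assert kurtosis(x) == pytest.approx(_brute_kurt(x), rel=1e-9)

    def test_kurt_matches_spreadsheet_estimator(self):
        """Algebraic equivalence with the standard bias-corrected formula."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            x = rng.normal(size=rng.integers(5, 60))
            expected = sp_stats.kurtosis(x, fisher=True, bias=False)
            assert kurtosis(x) == pytest.approx(expected, rel=1e-9, abs=1e-9)

    def test_skew_matches_bias_corrected_estimator(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            x = rng.normal(size=rng.integers(4, 60))
            expected = sp_stats.skew(x, bias=False)
            assert skewness(x) == pytest.approx(expected, rel=1e-9, abs=1e-9)

    def test_large_normal_sample_kurtosis_near_zero(self):
        x = np.random.default_rng(42).standard_normal(10_000)
        assert abs(kurtosis(x)) < 0.3

    def test_iqr_constant_window_is_zero(self):
        assert iqr([3.3] * 10) == 0.0

    def test_iqr_shift_invariant(self):
        x = np.array([4.0, 1.0, 7.0, 2.0, 9.0])
        assert iqr(x + 100.0) == pytest.approx(iqr(x), rel=1e-12)

    def test_iqr_fixture_matches_percentile_rule(self):
        x = list(range(1, 9))
        assert iqr(x) == pytest.approx(_brute_iqr(x), rel=1e-12)

    def test_degenerate_window_returns_zero(self):
        const = [5.0] * 12
        assert skewness(const) == 0.0
        assert kurtosis(const) == 0.0

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        data=st.lists(
            st.floats(-1e3, 1e3, allow_nan=False), min_size=5, max_size=60
        ),
        a=st.floats(0.1, 10),
        b=st.floats(-100, 100),
    )
    def test_property_shift_scale_behaviour(self, data, a, b):
        x = np.asarray(data)
        y = a * x + b
        assert iqr(y) == pytest.approx(a * iqr(x), rel=1e-6, abs=1e-6)
        if np.std(x, ddof=1) > 1e-6:
            assert skewness(y) == pytest.approx(skewness(x), rel=1e-6, abs=1e-6)
            assert kurtosis(y) == pytest.approx(kurtosis(x), rel=1e-6, abs=1e-6)


class TestExtractFeatures:
    def _window(self, seed=0, const=False):
        rng = np.random.default_rng(seed)
        chans = {
            s: (np.full(40, float(i)) if const else rng.normal(size=40))
            for i, s in enumerate(SIGNAL_NAMES)
        }
        return Window(start_s=0.0, n=40, channels=chans, label="walking")

    def test_vector_has_30_features_in_fixed_order(self):
        feats = pm.extract_features(self._window())
        names = [k for k in feats if k != "label"]
        assert names == list(FEATURE_NAMES)
        assert len(names) == len(SIGNAL_NAMES) * len(STAT_NAMES) == 30

    def test_constant_channels_zero_dispersion_stats(self):
        feats = pm.extract_features(self._window(const=True))
        for s in SIGNAL_NAMES:
            for stat in ("std", "skew", "kurt", "iqr"):
                assert feats[f"{s}_{stat}"] == 0.0
        assert feats["gyr3z_mean"] == 1.0  # channel index as constant

    def test_batch_table_shape_and_columns(self):
        sig = _signals(1500)
        ws = pm.slide_windows(sig)
        table = pm.extract_feature_table(ws)
        assert table.shape == (74, 31)
        assert list(table.columns[:-1]) == list(FEATURE_NAMES)

    def test_rotation_moves_mag_features_but_not_magnitude_features(
        self, walking_recording
    ):
        """The 12 la3a/gyr3z features are rotation-invariant; the 18
        magnetometer features generally are not."""
        from pocketmotion.synthetic import random_rotation

        base_sig = pm.derive_signals(walking_recording)
        base = pm.extract_feature_table(
            pm.slide_windows(base_sig, annotations=walking_recording.annotations)
        )
        R = random_rotation(np.random.default_rng(1))
        rotated = pm.Recording(
            traces={
                k: pm.SensorTrace(k, tr.rate_hz, tr.t, tr.xyz @ R.T)
                for k, tr in walking_recording.traces.items()
            },
            annotations=walking_recording.annotations,
        )
        rot = pm.extract_feature_table(
            pm.slide_windows(
                pm.derive_signals(rotated), annotations=rotated.annotations
            )
        )
        inv = [f for f in FEATURE_NAMES if f.startswith(("la3a", "gyr3z"))]
        var = [f for f in FEATURE_NAMES if f.startswith("mag")]
        assert len(inv) == 12 and len(var) == 18
        np.testing.assert_allclose(
            rot[inv].to_numpy(), base[inv].to_numpy(), rtol=1e-9, atol=1e-9
        )
        assert np.abs(rot[var].to_numpy() - base[var].to_numpy()).max() > 1.0
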