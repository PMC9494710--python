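"""Scalar feature operators, DFT magnitudes, windowing and tensor assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from semglite import (
    RawRecording,
    WindowSpec,
    build_feature_tensors,
    fft_magnitude,
    mav,
    rms,
    sliding_windows,
    ssc,
    wl,
    zc,
)


def naive_dft_magnitude(x):
    """O(N^2) DFT magnitude oracle."""
    n = len(x)
    k = np.arange(n)
    ww = np.exp(-2j * np.pi * np.outer(k, k) / n)
    return np.abs(ww @ np.asarray(x, dtype=np.float64))


def brute_ssc(v, eps):
    count = 0
    for k in range(1, len(v) - 1):
        d1, d2 = v[k] - v[k - 1], v[k] - v[k + 1]
        if d1 * d2 > 0 and abs(d1) > eps and abs(d2) > eps:
            count += 1
    return count


def brute_zc(v, eps):
    count = 0
    for k in range(1, len(v)):
        if np.sign(v[k]) != np.sign(v[k - 1]) and abs(v[k] - v[k - 1]) >= eps:
            count += 1
    return count


class TestScalarFeatures:
    @pytest.mark.parametrize(
        "fn,values,expected",
        [
            (mav, [1, -1, 1, -1], 1.0),
            (mav, [0, 0, 0], 0.0),
            (mav, [3, -4], 3.5),
            (rms, [5, 5, 5], 5.0),
            (rms, [-2, -2], 2.0),
            (rms, [3, -4], np.sqrt(12.5)),
            (rms, [0, 0], 0.0),
            (wl, [7, 7, 7], 0.0),
            (wl, [0, 1, 0, 1], 3.0),
            (wl, [0, 2, 5], 5.0),
        ],
    )
    def test_hand_computed_values(self, fn, values, expected):
        assert fn(np.array(values, dtype=float)) == pytest.approx(expected)

    def test_ssc_examples(self):
        assert ssc(np.arange(10.0)) == 0
        assert ssc(np.array([0.0, 1, 0, 1, 0]), epsilon=0.0) == 3
        assert ssc(np.full(5, 2.0)) == 0

    def test_zc_examples(self):
        assert zc(np.array([1.0, 2, 3])) == 0
        assert zc(np.array([1.0, -1, 1, -1]), epsilon=0.5) == 3
        assert zc(np.array([0.1, -0.1]), epsilon=1.0) == 0

    def test_short_windows_rejected(self):
        with pytest.raises(ValueError):
            wl(np.array([1.0]))
        with pytest.raises(ValueError):
            ssc(np.array([1.0, 2.0]))

    def test_against_brute_force_oracles(self, rng):
        for _ in range(200):
            v = rng.normal(size=rng.integers(3, 40))
            eps = float(rng.uniform(0, 0.5))
            assert mav(v) == pytest.approx(np.sum(np.abs(v)) / len(v))
            assert rms(v) == pytest.approx(np.sqrt(np.sum(v * v) / len(v)))
            assert wl(v) == pytest.approx(sum(abs(v[i + 1] - v[i]) for i in range(len(v) - 1)))
            assert ssc(v, eps) == brute_ssc(v, eps)
            assert zc(v, eps) == brute_zc(v, eps)

    @given(c=st.floats(-50, 50), seed=st.integers(0, 1000))
    @settings(max_examples=40, deadline=None)
    def test_positive_homogeneity(self, c, seed):
        v = np.random.default_rng(seed).normal(size=16)
        for fn in (mav, rms, wl):
            assert fn(c * v) == pytest.approx(abs(c) * fn(v), abs=1e-9)


class TestFFT:
    def test_zeros(self):
        assert np.all(fft_magnitude(np.zeros(100)) == 0)

    def test_dc(self):
        mags = fft_magnitude(np.full(100, 2.0))
        assert mags[0] == pytest.approx(200.0)
        assert np.abs(mags[1:]).max() < 1e-9

    def test_pure_cosine_bins(self):
        x = np.cos(2 * np.pi * 5 * np.arange(100) / 100)
        mags = fft_magnitude(x)
        assert mags[5] == pytest.approx(50.0)
        assert mags[95] == pytest.approx(50.0)
        others = np.delete(mags, [5, 95])
        assert np.abs(others).max() < 1e-9

    @pytest.mark.parametrize("n", [4, 16, 100])
    def test_matches_naive_dft(self, rng, n):
        for _ in range(10):
            x = rng.normal(size=n)
            np.testing.assert_allclose(
                fft_magnitude(x), naive_dft_magnitude(x), rtol=1e-9, atol=1e-9
            )


class TestSlidingWindows:
    @pytest.mark.parametrize(
        "n,window,step,expected",
        [(200, 200, 1, 1), (300, 100, 100, 3), (1000, 200, 200, 5)],
    )
    def test_window_count(self, n, window, step, expected):
        rec = RawRecording(np.zeros((n, 1)))
        spec = WindowSpec(window_len=window, step=step)
        wins = list(sliding_windows(rec, spec))
        assert len(wins) == expected

    def test_too_short_raises_with_lengths(self):
        rec = RawRecording(np.zeros((99, 1)))
        with pytest.raises(ValueError, match="99"):
            list(sliding_windows(rec, WindowSpec(window_len=100, step=1)))

    @given(
        n=st.integers(10, 400), window=st.integers(2, 100), step=st.integers(1, 100)
    )
    @settings(max_examples=60, deadline=None)
    def test_count_formula_matches_enumeration(self, n, window, step):
        if step > window or n < window:
            return
        spec = WindowSpec(window_len=window, step=step)
        starts = [s for s in range(0, n, step) if s + window <= n]
        # enumeration must agree with floor((n - window)/step) + 1
        assert spec.n_windows(n) == len(starts) == (n - window) // step + 1

    def test_half_open_coverage(self):
        rec = RawRecording(np.arange(12, dtype=float)[:, None])
        wins = list(sliding_windows(rec, WindowSpec(window_len=4, step=4)))
        np.testing.assert_array_equal(wins[0].values, [0, 1, 2, 3])
        np.testing.assert_array_equal(wins[2].values, [8, 9, 10, 11])


class TestFeatureTensors:
    def _rec(self, data):
        return RawRecording(data, gesture_label=1, trial_id="rep1-g01")

    def test_raw_exact_fit(self):
        rec = self._rec(np.random.default_rng(0).random((200, 6)))
        tensors = build_feature_tensors(rec, "RAW")
        assert len(tensors) == 1
        assert tensors[0].data.shape == (200, 6, 1)
        np.testing.assert_allclose(tensors[0].data[..., 0], rec.samples, rtol=1e-6)

    def test_fft_dc_places_energy_in_frame_dc_bins(self):
        rec = self._rec(np.full((200, 6), 0.5))
        (t,) = build_feature_tensors(rec, "FFT")
        col = t.data[:, 0, 0]
        assert col[0] == pytest.approx(50.0)  # frame 1, bin 0 = 100 * 0.5
        assert col[100] == pytest.approx(50.0)  # frame 2, bin 0
        assert np.abs(np.delete(col, [0, 100])).max() < 1e-4

    def test_fft_rms_preserves_frame_rms(self, rng):
        data = rng.normal(size=(200, 6))
        rec = self._rec(data)
        (t,) = build_feature_tensors(rec, "FFT_RMS")
        for ch in range(6):
            for frame in range(2):
                raw = data[frame * 100 : (frame + 1) * 100, ch]
                out = t.data[frame * 100 : (frame + 1) * 100, ch, 0]
                raw_rms = np.sqrt(np.mean(raw**2))
                out_rms = np.sqrt(np.mean(out.astype(np.float64) ** 2))
                assert out_rms == pytest.approx(raw_rms, rel=1e-4)

    def test_scalar_stream_layout(self, rng):
        data = rng.normal(size=(200, 6))
        rec = self._rec(data)
        (t,) = build_feature_tensors(rec, "RMS")
        col = t.data[:, 2, 0]
        # 101 sub-windows of length 100 at step 1, zero-padded to 200
        expected_first = np.sqrt(np.mean(data[:100, 2] ** 2))
        expected_last = np.sqrt(np.mean(data[100:200, 2] ** 2))
        assert col[0] == pytest.approx(expected_first, rel=1e-5)
        assert col[100] == pytest.approx(expected_last, rel=1e-5)
        assert np.all(col[101:] == 0)

    def test_unlabelled_recording_rejected(self):
        rec = RawRecording(np.zeros((200, 6)))
        with pytest.raises(ValueError, match="unlabelled"):
            build_feature_tensors(rec, "RAW")

    def test_unknown_kind_rejected(self):
        rec = self._rec(np.zeros((200, 6)))
        with pytest.raises(ValueError, match="feature kind"):
            build_feature_tensors(rec, "WAVELET")
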