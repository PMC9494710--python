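"""Filter responses, min-max scaling, and pipeline composition."""

import numpy as np
import pytest

from semglite import (
    FilterSettings,
    RawRecording,
    highpass,
    minmax_normalize,
    notch,
    preprocess_pipeline,
)
from semglite.preprocess import lowpass

from conftest import steady_rms


class TestHighpass:
    def test_removes_dc(self):
        rec = RawRecording(np.full((4000, 6), 3.7))
        out = highpass(rec)
        assert np.abs(out.samples[1000:3000]).max() < 1e-6

    def test_attenuates_subcutoff_tone(self, tone_recording):
        rec = tone_recording(5.0)
        out = highpass(rec)
        ratio = steady_rms(out.samples[:, 0], rec.fs) / steady_rms(rec.samples[:, 0], rec.fs)
        assert ratio < 0.10

    def test_passes_band_tone(self, tone_recording):
        rec = tone_recording(200.0)
        out = highpass(rec)
        ratio = steady_rms(out.samples[:, 0], rec.fs) / steady_rms(rec.samples[:, 0], rec.fs)
        assert ratio > 0.90

    def test_cutoff_at_nyquist_rejected(self):
        rec = RawRecording(np.zeros((100, 6)), fs=30.0)
        with pytest.raises(ValueError, match="highpass_cutoff_hz"):
            highpass(rec, FilterSettings(highpass_cutoff_hz=20.0))


class TestNotch:
    def test_kills_mains_tone(self, tone_recording):
        rec = tone_recording(50.0)
        out = notch(rec)
        ratio = steady_rms(out.samples[:, 0], rec.fs) / steady_rms(rec.samples[:, 0], rec.fs)
        assert ratio <= 0.10

    @pytest.mark.parametrize("freq", [30.0, 70.0, 100.0])
    def test_neighbouring_bands_pass(self, tone_recording, freq):
        rec = tone_recording(freq)
        out = notch(rec)
        ratio = steady_rms(out.samples[:, 0], rec.fs) / steady_rms(rec.samples[:, 0], rec.fs)
        assert ratio >= 0.90

    def test_zero_signal_stays_zero(self):
        rec = RawRecording(np.zeros((500, 6)))
        assert np.all(notch(rec).samples == 0)


class TestMinMax:
    def test_affine_mapping(self):
        rec = RawRecording(np.array([[2.0], [4.0], [6.0]]))
        out, mins, maxs = minmax_normalize(rec)
        np.testing.assert_allclose(out.samples[:, 0], [0.0, 0.5, 1.0])
        assert mins[0] == 2.0 and maxs[0] == 6.0

    def test_idempotent_on_unit_range(self):
        rec = RawRecording(np.array([[0.0], [0.25], [1.0]]))
        out, _, _ = minmax_normalize(rec)
        np.testing.assert_allclose(out.samples, rec.samples)

    def test_asymmetric_channel(self):
        rec = RawRecording(np.array([[-1.0], [0.0], [3.0]]))
        out, _, _ = minmax_normalize(rec)
        np.testing.assert_allclose(out.samples[:, 0], [0.0, 0.25, 1.0])

    def test_constant_channel_maps_to_half_with_warning(self):
        rec = RawRecording(np.column_stack([np.ones(10), np.arange(10.0)]))
        with pytest.warns(UserWarning, match="constant"):
            out, _, _ = minmax_normalize(rec)
        assert np.all(out.samples[:, 0] == 0.5)


class TestPipeline:
    def test_zero_signal_becomes_half(self):
        rec = RawRecording(np.zeros((1000, 6)))
        with pytest.warns(UserWarning):
            out = preprocess_pipeline(rec)
        assert np.all(out.samples == 0.5)

    def test_lowpass_disabled_by_default(self):
        settings = FilterSettings()
        assert settings.lowpass_cutoff_hz is None
        rec = RawRecording(np.zeros((100, 6)))
        with pytest.raises(ValueError, match="disabled"):
            lowpass(rec, settings)

    def test_lowpass_above_nyquist_rejected(self):
        rec = RawRecording(np.random.default_rng(0).normal(size=(500, 6)))
        with pytest.raises(ValueError, match="lowpass_cutoff_hz"):
            preprocess_pipeline(rec, FilterSettings(lowpass_cutoff_hz=2000.0))

    def test_deterministic(self, tiny_trials):
        rec = tiny_trials[0]
        a = preprocess_pipeline(rec)
        b = preprocess_pipeline(rec)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_output_in_unit_interval_and_shape_preserved(self, tiny_trials):
        rec = tiny_trials[1]
        out = preprocess_pipeline(rec)
        assert out.samples.shape == rec.samples.shape
        assert out.samples.min() >= 0.0 and out.samples.max() <= 1.0


class TestLinearity:
    def test_filters_are_linear_and_channel_independent(self, rng):
        x = rng.normal(size=(800, 6))
        rec = RawRecording(x)
        scaled = RawRecording(2.5 * x)
        for op in (highpass, notch):
            np.testing.assert_allclose(
                op(scaled).samples, 2.5 * op(rec).samples, atol=1e-9
            )
            # permuting channels commutes with filtering
            perm = [3, 0, 5, 1, 4, 2]
            np.testing.assert_allclose(
                op(RawRecording(x[:, perm])).samples, op(rec).samples[:, perm], atol=1e-12
            )
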