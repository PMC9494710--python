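"""Signal conditioning applied to raw sEMG before feature extraction.

The pipeline is: third-order Butterworth high-pass at 20 Hz (motion
artifacts), optional low-pass, a 50 Hz IIR notch (power-line hum), then
per-channel min-max scaling onto [0, 1].  All filtering is zero-phase
(forward-backward), appropriate for offline analysis and free of
channel-to-channel group delay.

The acquisition hardware low-pass sits at the sampling rate (2 kHz), i.e.
at or above Nyquist for the digital signal, so it is treated as an analog
anti-aliasing stage and the digital low-pass is disabled by default.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .recording import RawRecording

log = logging.getLogger(__name__)


@dataclass
class FilterSettings:
    """Filter and scaling configuration for the preprocessing pipeline.

    ``lowpass_cutoff_hz=None`` disables the low-pass stage.  ``notch_quality``
    is the dimensionless Q of the second-order IIR notch (bandwidth =
    notch_freq / Q).
    """

    highpass_cutoff_hz: float = 20.0
    highpass_order: int = 3
    lowpass_cutoff_hz: float | None = None
    lowpass_order: int = 3
    notch_freq_hz: float = 50.0
    notch_quality: float = 30.0
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.highpass_order < 1 or self.lowpass_order < 1:
            raise ValueError("filter orders must be >= 1")
        for name in ("highpass_cutoff_hz", "notch_freq_hz", "notch_quality"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def validate_against_fs(self, fs: float) -> None:
        """Raise if any enabled cutoff reaches the Nyquist frequency."""
        nyq = fs / 2.0
        for name, value in (
            ("highpass_cutoff_hz", self.highpass_cutoff_hz),
            ("lowpass_cutoff_hz", self.lowpass_cutoff_hz),
            ("notch_freq_hz", self.notch_freq_hz),
        ):
            if value is not None and value >= nyq:
                raise ValueError(
                    f"{name}={value} Hz is at or above Nyquist ({nyq} Hz) for fs={fs} Hz"
                )


def _filtfilt_sos(sos: np.ndarray, rec: RawRecording) -> RawRecording:
    # channels are filtered independently; axis=0 runs each column separately
    out = sps.sosfiltfilt(sos, rec.samples, axis=0)
    return rec.with_samples(out)


def highpass(rec: RawRecording, settings: FilterSettings | None = None) -> RawRecording:
    """Butterworth high-pass (default third order, 20 Hz), zero-phase."""
    settings = settings or FilterSettings()
    settings.validate_against_fs(rec.fs)
    sos = sps.butter(
        settings.highpass_order, settings.highpass_cutoff_hz, btype="highpass",
        fs=rec.fs, output="sos",
    )
    return _filtfilt_sos(sos, rec)


def lowpass(rec: RawRecording, settings: FilterSettings) -> RawRecording:
    """Butterworth low-pass; only callable when a cutoff is configured."""
    if settings.lowpass_cutoff_hz is None:
        raise ValueError("low-pass stage is disabled (lowpass_cutoff_hz is None)")
    settings.validate_against_fs(rec.fs)
    sos = sps.butter(
        settings.lowpass_order, settings.lowpass_cutoff_hz, btype="lowpass",
        fs=rec.fs, output="sos",
    )
    return _filtfilt_sos(sos, rec)


def notch(rec: RawRecording, settings: FilterSettings | None = None) -> RawRecording:
    """Second-order IIR notch at the power-line frequency (50 Hz, Q=30)."""
    settings = settings or FilterSettings()
    settings.validate_against_fs(rec.fs)
    b, a = sps.iirnotch(settings.notch_freq_hz, settings.notch_quality, fs=rec.fs)
    out = sps.filtfilt(b, a, rec.samples, axis=0)
    return rec.with_samples(out)


def minmax_normalize(rec: RawRecording) -> tuple[RawRecording, np.ndarray, np.ndarray]:
    """Map each channel affinely onto [0, 1].

    Returns the scaled recording together with the per-channel minima and
    maxima so the mapping can be inverted.  A constant channel (max == min)
    is mapped to all-0.5 and a warning is emitted.
    """
    mins = rec.samples.min(axis=0)
    maxs = rec.samples.max(axis=0)
    span = maxs - mins
    flat = span == 0
    if flat.any():
        names = [rec.channel_names[i] for i in np.flatnonzero(flat)]
        warnings.warn(f"constant channel(s) {names} mapped to 0.5", stacklevel=2)
    safe = np.where(flat, 1.0, span)
    out = (rec.samples - mins) / safe
    out[:, flat] = 0.5
    return rec.with_samples(out), mins, maxs


def preprocess_pipeline(
    rec: RawRecording, settings: FilterSettings | None = None
) -> RawRecording:
    """high-pass -> (low-pass if enabled) -> notch -> min-max scale.

    Deterministic and shape-preserving; the applied stage order is logged.
    """
    settings = settings or FilterSettings()
    settings.validate_against_fs(rec.fs)
    stages = ["highpass"]
    out = highpass(rec, settings)
    if settings.lowpass_cutoff_hz is not None:
        out = lowpass(out, settings)
        stages.append("lowpass")
    out = notch(out, settings)
    stages.append("notch")
    if settings.normalize:
        out, _, _ = minmax_normalize(out)
        stages.append("minmax")
    log.info("preprocess pipeline: %s", " -> ".join(stages))
    return out
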