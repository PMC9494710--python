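"""Sliding-window segmentation and feature representations of sEMG.

Two families of representations feed the classifiers, both shaped
``window_len x n_channels x 1`` (200 x 6 x 1 by default):

* time-domain scalars — MAV, WL, SSC, ZC, RMS — computed on 100-sample
  sub-windows slid one sample at a time across each 200-sample window,
  zero-padded back to window length;
* time-frequency — each 200-sample window is split per channel into two
  non-overlapping 100-sample frames, each replaced by its 100 two-sided DFT
  magnitudes (``FFT``); the fused ``FFT_RMS`` variant additionally rescales
  every spectral frame to carry the raw frame's time-domain RMS, so the
  representation keeps both spectral shape and contraction intensity.

Sample indices are 0-based; windows are half-open ``[start, start+len)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .recording import RawRecording

FEATURE_KINDS = ("RAW", "MAV", "WL", "SSC", "ZC", "RMS", "FFT", "FFT_RMS")
SCALAR_KINDS = ("MAV", "WL", "SSC", "ZC", "RMS")


@dataclass
class WindowSpec:
    """Window geometry and the ZC/SSC noise threshold.

    ``window_len``/``step`` describe the network-input windows;
    ``frame_len``/``frame_step`` the DFT frames inside each window (100/100,
    i.e. non-overlapping); ``scalar_step`` the stride of the 100-sample
    sub-windows used for scalar-feature streams.  ``zc_epsilon`` is the
    amplitude threshold that keeps noise-level wiggles out of the zero
    crossing and slope-sign-change counts, expressed in units of the
    normalized signal range.
    """

    window_len: int = 200
    step: int = 200
    frame_len: int = 100
    frame_step: int = 100
    scalar_step: int = 1
    zc_epsilon: float = 0.01

    def __post_init__(self) -> None:
        for name in ("window_len", "step", "frame_len", "frame_step", "scalar_step"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.step > self.window_len:
            raise ValueError("step must not exceed window_len")
        if self.zc_epsilon < 0:
            raise ValueError("zc_epsilon must be >= 0")

    def n_windows(self, n_samples: int) -> int:
        if n_samples < self.window_len:
            raise ValueError(
                f"recording of {n_samples} samples is shorter than "
                f"window_len={self.window_len}"
            )
        return (n_samples - self.window_len) // self.step + 1


@dataclass
class FeatureWindow:
    """One window of one channel: ``values`` has length ``window_len``."""

    values: np.ndarray
    channel_index: int = 0
    window_start: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if self.values.size == 0:
            raise ValueError("empty feature window")


@dataclass
class FeatureTensor:
    """One labelled network input of shape ``(window_len, n_channels, 1)``."""

    data: np.ndarray
    feature_kind: str
    label: int
    subject_id: str = "S0"
    trial_id: str = "T0"
    window_start: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim == 2:
            self.data = self.data[..., None]
        if self.data.ndim != 3 or self.data.shape[2] != 1:
            raise ValueError(f"tensor must be (window_len, n_channels, 1), got {self.data.shape}")
        if not np.isfinite(self.data).all():
            raise ValueError("tensor contains non-finite values")
        if self.feature_kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.feature_kind!r}")


def sliding_windows(rec: RawRecording, spec: WindowSpec) -> Iterator[FeatureWindow]:
    """Yield every window of every channel (channel-major order)."""
    n = spec.n_windows(rec.n_samples)
    for ch in range(rec.n_channels):
        col = rec.samples[:, ch]
        for w in range(n):
            start = w * spec.step
            yield FeatureWindow(col[start : start + spec.window_len], ch, start)


def _values(w) -> np.ndarray:
    return w.values if isinstance(w, FeatureWindow) else np.asarray(w, dtype=np.float64).ravel()


def mav(w) -> float:
    """Mean absolute value: average contraction level of the window."""
    return float(np.mean(np.abs(_values(w))))


def rms(w) -> float:
    """Root mean square: average-power proxy of the window."""
    return float(np.sqrt(np.mean(np.square(_values(w)))))


def wl(w) -> float:
    """Waveform length: cumulative absolute first difference."""
    v = _values(w)
    if v.size < 2:
        raise ValueError("waveform length needs at least 2 samples")
    return float(np.sum(np.abs(np.diff(v))))


def ssc(w, epsilon: float = 0.0) -> int:
    """Slope sign changes: local extrema whose flanks both exceed ``epsilon``."""
    v = _values(w)
    if v.size < 3:
        raise ValueError("slope sign change needs at least 3 samples")
    d_prev = v[1:-1] - v[:-2]
    d_next = v[1:-1] - v[2:]
    hit = (d_prev * d_next > 0) & (np.abs(d_prev) > epsilon) & (np.abs(d_next) > epsilon)
    return int(np.count_nonzero(hit))


def zc(w, epsilon: float = 0.0) -> int:
    """Zero crossings: sign changes whose amplitude jump is at least ``epsilon``."""
    v = _values(w)
    if v.size < 2:
        raise ValueError("zero crossing needs at least 2 samples")
    sign_change = np.sign(v[1:]) != np.sign(v[:-1])
    big_enough = np.abs(np.diff(v)) >= epsilon
    return int(np.count_nonzero(sign_change & big_enough))


def fft_magnitude(w) -> np.ndarray:
    """Two-sided N-point DFT magnitude, standard bin order, no normalization."""
    return np.abs(np.fft.fft(_values(w)))


_SCALAR_FN = {"MAV": mav, "RMS": rms, "WL": wl}


def _scalar_stream(col: np.ndarray, kind: str, spec: WindowSpec) -> np.ndarray:
    """Scalar feature on frame_len sub-windows slid at scalar_step, padded to window_len."""
    sub = sliding_window_view(col, spec.frame_len)[:: spec.scalar_step]
    if kind == "MAV":
        vals = np.mean(np.abs(sub), axis=1)
    elif kind == "RMS":
        vals = np.sqrt(np.mean(np.square(sub), axis=1))
    elif kind == "WL":
        vals = np.sum(np.abs(np.diff(sub, axis=1)), axis=1)
    elif kind == "SSC":
        d_prev = sub[:, 1:-1] - sub[:, :-2]
        d_next = sub[:, 1:-1] - sub[:, 2:]
        hit = (
            (d_prev * d_next > 0)
            & (np.abs(d_prev) > spec.zc_epsilon)
            & (np.abs(d_next) > spec.zc_epsilon)
        )
        vals = np.count_nonzero(hit, axis=1).astype(np.float64)
    elif kind == "ZC":
        change = np.sign(sub[:, 1:]) != np.sign(sub[:, :-1])
        big = np.abs(np.diff(sub, axis=1)) >= spec.zc_epsilon
        vals = np.count_nonzero(change & big, axis=1).astype(np.float64)
    else:  # pragma: no cover - guarded by caller
        raise ValueError(kind)
    out = np.zeros(len(col), dtype=np.float64)
    out[: len(vals)] = vals
    return out


def _fft_frames(win: np.ndarray, spec: WindowSpec, fuse_rms: bool) -> np.ndarray:
    """Per-channel frame-wise DFT magnitudes, optionally RMS-rescaled, concatenated."""
    n_frames = (spec.window_len - spec.frame_len) // spec.frame_step + 1
    if n_frames * spec.frame_len != spec.window_len:
        raise ValueError(
            f"frame_len={spec.frame_len} x {n_frames} frames does not tile "
            f"window_len={spec.window_len}"
        )
    out = np.empty_like(win)
    for f in range(n_frames):
        lo = f * spec.frame_step
        frame = win[lo : lo + spec.frame_len]
        mag = np.abs(np.fft.fft(frame, axis=0))
        if fuse_rms:
            raw_rms = np.sqrt(np.mean(np.square(frame), axis=0))
            mag_rms = np.sqrt(np.mean(np.square(mag), axis=0))
            scale = np.divide(raw_rms, mag_rms, out=np.zeros_like(raw_rms), where=mag_rms > 0)
            mag = mag * scale
        out[lo : lo + spec.frame_len] = mag
    return out


def build_feature_tensors(
    rec: RawRecording,
    feature_kind: str = "FFT_RMS",
    spec: WindowSpec | None = None,
) -> list[FeatureTensor]:
    """Cut a labelled recording into network-input tensors of one feature kind.

    The recording must carry a gesture label (``gesture_label >= 1``); every
    produced tensor inherits it together with subject/trial provenance and
    its window start offset.
    """
    spec = spec or WindowSpec()
    if feature_kind not in FEATURE_KINDS:
        raise ValueError(f"unknown feature kind {feature_kind!r}; choose from {FEATURE_KINDS}")
    if rec.gesture_label < 1:
        raise ValueError(
            f"recording {rec.trial_id} is unlabelled (gesture_label={rec.gesture_label}); "
            "label coverage is required for tensor construction"
        )
    n = spec.n_windows(rec.n_samples)
    tensors = []
    for wi in range(n):
        start = wi * spec.step
        win = rec.samples[start : start + spec.window_len]  # (window_len, n_channels)
        if feature_kind == "RAW":
            data = win
        elif feature_kind in ("FFT", "FFT_RMS"):
            data = _fft_frames(win, spec, fuse_rms=feature_kind == "FFT_RMS")
        else:
            data = np.column_stack(
                [_scalar_stream(win[:, ch], feature_kind, spec) for ch in range(win.shape[1])]
            )
        tensors.append(
            FeatureTensor(
                data[..., None],
                feature_kind=feature_kind,
                label=int(rec.gesture_label),
                subject_id=rec.subject_id,
                trial_id=rec.trial_id,
                window_start=start,
            )
        )
    return tensors
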