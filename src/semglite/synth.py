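"""Seeded synthetic 6-channel sEMG for a 16-gesture protocol.

Real surface EMG looks, to first order, like band-limited Gaussian noise
whose envelope follows muscle activation.  The generator emulates exactly
that: each gesture class has a per-channel activation weight matrix and a
carrier band inside the physiological 20-450 Hz range; a trial is
band-limited Gaussian noise per channel, scaled by the activation weight
and a raised-cosine on/off envelope (200 ms ramps), on top of a white
noise floor.  Rest segments carry the noise floor only.  Classes 7 and 8
deliberately share a carrier band and have nearly identical activation
patterns, mirroring gesture pairs driven by shared musculature that
dominate real confusion matrices.

It does not model motor-unit action potentials, electrode crosstalk,
fatigue or inter-subject variability — see the methods note for what that
implies about conclusions drawn from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .recording import LABEL_COLUMNS, RawRecording


def _default_activations(n_classes: int, n_channels: int) -> np.ndarray:
    """Distinct per-class channel weights: one primary and one secondary
    channel over a 0.1 floor; classes 7/8 are made nearly identical."""
    w = np.full((n_classes, n_channels), 0.1)
    for i in range(n_classes):
        p = i % n_channels
        s = (p + 1 + i // n_channels) % n_channels
        w[i, p] = 1.0
        w[i, s] = 0.6
    if n_classes >= 8 and n_channels >= 4:
        w[7] = w[6].copy()
        w[7, 2] += 0.125
        w[7, 3] += 0.125
    return w


def _default_bands(n_classes: int) -> list[tuple[float, float]]:
    """Per-class carrier bands spread across 25-405 Hz; classes 7/8 shared."""
    bands = [(25.0 + 20.0 * i, 105.0 + 20.0 * i) for i in range(n_classes)]
    if n_classes >= 8:
        bands[7] = bands[6]
    return bands


@dataclass
class GestureProtocol:
    """The recording protocol the generator emulates.

    Defaults: 16 gestures, 6 channels at 2 kHz, 3 s of contraction per
    trial with 1 s rest before each, 3 repetitions of the full gesture set,
    white noise floor at 5% of the unit carrier amplitude.
    """

    n_classes: int = 16
    n_channels: int = 6
    fs: float = 2000.0
    activation_matrix: np.ndarray | None = None
    carrier_bands: list[tuple[float, float]] | None = None
    trial_duration_s: float = 3.0
    rest_duration_s: float = 1.0
    repetitions: int = 3
    ramp_s: float = 0.2
    noise_floor: float = 0.05
    seed: int = 0
    subject_id: str = "SYN1"

    def __post_init__(self) -> None:
        if self.activation_matrix is None:
            self.activation_matrix = _default_activations(self.n_classes, self.n_channels)
        self.activation_matrix = np.asarray(self.activation_matrix, dtype=np.float64)
        if self.activation_matrix.shape != (self.n_classes, self.n_channels):
            raise ValueError("activation_matrix must be n_classes x n_channels")
        if (self.activation_matrix < 0).any() or (self.activation_matrix > 1).any():
            raise ValueError("activation weights must lie in [0, 1]")
        if self.carrier_bands is None:
            self.carrier_bands = _default_bands(self.n_classes)
        if len(self.carrier_bands) != self.n_classes:
            raise ValueError("one carrier band per class required")
        nyq = self.fs / 2.0
        for lo, hi in self.carrier_bands:
            if not (20.0 <= lo < hi < nyq):
                raise ValueError(f"degenerate carrier band ({lo}, {hi}) Hz for fs={self.fs}")
        dists = np.abs(
            self.activation_matrix[:, None, :] - self.activation_matrix[None, :, :]
        ).sum(axis=2)
        np.fill_diagonal(dists, np.inf)
        if (dists <= 0.2).any():
            i, j = np.unravel_index(np.argmin(dists), dists.shape)
            raise ValueError(
                f"activation rows {i + 1} and {j + 1} are too close (L1={dists[i, j]:.3f})"
            )

    @property
    def trial_samples(self) -> int:
        return int(round(self.trial_duration_s * self.fs))

    @property
    def rest_samples(self) -> int:
        return int(round(self.rest_duration_s * self.fs))


def _envelope(n: int, ramp: int) -> np.ndarray:
    """Raised-cosine onset/offset around a flat plateau."""
    env = np.ones(n)
    ramp = min(ramp, n // 2)
    if ramp > 0:
        t = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
        env[:ramp] = t
        env[-ramp:] = t[::-1]
    return env


def _band_noise(
    rng: np.random.Generator, n: int, band: tuple[float, float], fs: float
) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise."""
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    return x / np.sqrt(np.mean(np.square(x)))


def generate_trial(
    protocol: GestureProtocol, gesture: int, rng: np.random.Generator
) -> np.ndarray:
    """One contraction segment for ``gesture`` (1-based): array (n, channels)."""
    n = protocol.trial_samples
    env = _envelope(n, int(round(protocol.ramp_s * protocol.fs)))
    band = protocol.carrier_bands[gesture - 1]
    weights = protocol.activation_matrix[gesture - 1]
    out = np.empty((n, protocol.n_channels))
    for ch in range(protocol.n_channels):
        carrier = _band_noise(rng, n, band, protocol.fs)
        out[:, ch] = weights[ch] * env * carrier
    out += protocol.noise_floor * rng.standard_normal(out.shape)
    return out


def generate_trials(protocol: GestureProtocol) -> list[RawRecording]:
    """All labelled contraction segments, trial ids ``rep<k>-g<class>``.

    Deterministic for a fixed ``protocol.seed``; the draw order is
    repetition-major then class-major, matching :func:`generate`.
    """
    rng = np.random.default_rng(protocol.seed)
    trials = []
    for rep in range(1, protocol.repetitions + 1):
        for g in range(1, protocol.n_classes + 1):
            rng_trial = np.random.default_rng(rng.integers(2**31))
            trials.append(
                RawRecording(
                    generate_trial(protocol, g, rng_trial),
                    fs=protocol.fs,
                    subject_id=protocol.subject_id,
                    trial_id=f"rep{rep}-g{g:02d}",
                    gesture_label=g,
                )
            )
    return trials


def generate(protocol: GestureProtocol) -> tuple[RawRecording, pd.DataFrame]:
    """One continuous recording (rest + trial per gesture per repetition)
    plus the label sidecar marking each contraction segment."""
    rng = np.random.default_rng(protocol.seed)
    segments, rows = [], []
    cursor = 0
    for rep in range(1, protocol.repetitions + 1):
        for g in range(1, protocol.n_classes + 1):
            rng_trial = np.random.default_rng(rng.integers(2**31))
            rest = protocol.noise_floor * rng_trial.standard_normal(
                (protocol.rest_samples, protocol.n_channels)
            )
            trial = generate_trial(protocol, g, rng_trial)
            segments += [rest, trial]
            start = cursor + protocol.rest_samples
            rows.append(
                {
                    "trial_id": f"rep{rep}-g{g:02d}",
                    "subject_id": protocol.subject_id,
                    "gesture_label": g,
                    "start_sample": start,
                    "end_sample": start + protocol.trial_samples,
                }
            )
            cursor += protocol.rest_samples + protocol.trial_samples
    rec = RawRecording(
        np.vstack(segments), fs=protocol.fs, subject_id=protocol.subject_id
    )
    return rec, pd.DataFrame(rows, columns=LABEL_COLUMNS)


def extract_labelled_trials(rec: RawRecording, labels: pd.DataFrame) -> list[RawRecording]:
    """Cut a continuous recording into labelled trial segments per sidecar."""
    trials = []
    for row in labels.itertuples(index=False):
        seg = rec.slice(int(row.start_sample), int(row.end_sample))
        seg.trial_id = str(row.trial_id)
        seg.subject_id = str(row.subject_id)
        seg.gesture_label = int(row.gesture_label)
        trials.append(seg)
    return trials
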