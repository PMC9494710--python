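"""Raw multichannel sEMG recordings and their on-disk CSV dialect.

A recording is a dense ``n_samples x n_channels`` float array sampled at a
fixed rate (2 kHz by default in this project's acquisition protocol), plus
provenance identifiers.  Raw signals travel as plain CSV (one row per
sample, one column per channel); trial boundaries and gesture labels travel
in a sidecar CSV with columns ``trial_id, subject_id, gesture_label,
start_sample, end_sample``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

DEFAULT_FS = 2000.0
DEFAULT_N_CHANNELS = 6

LABEL_COLUMNS = ["trial_id", "subject_id", "gesture_label", "start_sample", "end_sample"]


@dataclass
class RawRecording:
    """A sampled multichannel sEMG signal.

    Parameters
    ----------
    samples
        ``(n_samples, n_channels)`` float array, arbitrary amplitude units.
    fs
        Sampling frequency in Hz; must be positive.
    channel_names
        Ordered channel labels; defaults to ``ch1..chN``.
    subject_id, trial_id, gesture_label
        Provenance identifiers (``gesture_label`` is 1-based, 0 = unlabelled).
    """

    samples: np.ndarray
    fs: float = DEFAULT_FS
    channel_names: list[str] = field(default_factory=list)
    subject_id: str = "S0"
    trial_id: str = "T0"
    gesture_label: int = 0

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=np.float64))
        if self.samples.ndim != 2:
            raise ValueError(f"samples must be 2-D, got shape {self.samples.shape}")
        if self.samples.shape[0] < 1:
            raise ValueError("recording must contain at least one sample")
        if not np.isfinite(self.samples).all():
            raise ValueError("recording contains non-finite values")
        if self.fs <= 0:
            raise ValueError(f"sampling frequency must be positive, got {self.fs}")
        if not self.channel_names:
            self.channel_names = [f"ch{i + 1}" for i in range(self.n_channels)]
        if len(self.channel_names) != self.n_channels:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {self.n_channels} channels"
            )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def with_samples(self, samples: np.ndarray) -> "RawRecording":
        """Copy of this recording with the signal replaced (metadata kept)."""
        return replace(self, samples=samples)

    def slice(self, start: int, stop: int) -> "RawRecording":
        """Sub-recording over the half-open sample range ``[start, stop)``."""
        if not 0 <= start < stop <= self.n_samples:
            raise ValueError(f"invalid slice [{start}, {stop}) of {self.n_samples} samples")
        return replace(self, samples=self.samples[start:stop].copy())


def read_raw_csv(
    path,
    n_channels: int = DEFAULT_N_CHANNELS,
    fs: float = DEFAULT_FS,
    **meta,
) -> RawRecording:
    """Load a raw-signal CSV (one row per sample, one numeric column per channel).

    A header row of channel names is detected automatically.  Ragged rows or
    non-numeric cells raise with the offending row number; a column count
    different from ``n_channels`` is a configuration error.
    """
    try:
        df = pd.read_csv(path, header=None, dtype=str)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed CSV {path}: {exc}") from None
    header = None
    first = df.iloc[0]
    if not first.map(_is_number).all():
        header = [str(v) for v in first]
        df = df.iloc[1:]
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    bad = df.isna().any(axis=1) | ~df.map(_is_number).all(axis=1)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + (2 if header else 1)
        raise ValueError(f"{path}: non-numeric or missing cell at row {row}")
    values = df.to_numpy(dtype=np.float64)
    if values.shape[1] != n_channels:
        raise ValueError(
            f"{path}: expected {n_channels} channels, found {values.shape[1]} columns"
        )
    return RawRecording(values, fs=fs, channel_names=header or [], **meta)


def write_raw_csv(rec: RawRecording, path, header: bool = True) -> None:
    """Write the raw-signal CSV dialect read by :func:`read_raw_csv`.

    Floats are printed with 12 significant digits, enough for a write-read
    round trip to reproduce the array to that precision.
    """
    df = pd.DataFrame(rec.samples, columns=rec.channel_names)
    df.to_csv(path, index=False, header=header, float_format="%.12g")


def read_labels(path) -> pd.DataFrame:
    """Load a label sidecar CSV; validates columns and label range 1..16+."""
    df = pd.read_csv(path)
    missing = [c for c in LABEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: label sidecar missing columns {missing}")
    if (df["gesture_label"] < 1).any():
        raise ValueError(f"{path}: gesture labels must be >= 1")
    if (df["end_sample"] <= df["start_sample"]).any():
        raise ValueError(f"{path}: empty or inverted label intervals")
    return df[LABEL_COLUMNS].copy()


def write_labels(labels: pd.DataFrame, path) -> None:
    labels[LABEL_COLUMNS].to_csv(path, index=False)


def _is_number(s) -> bool:
    try:
        float(s)
        return True
    except (TypeError, ValueError):
        return False
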