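"""Labelled window collections and leakage-free split construction.

Two evaluation protocols are supported:

* intra-experiment — each trial is cut into contiguous thirds, the first
  two thirds train (with a validation tail) and the last third tests.  The
  cut is made on the raw signal, before preprocessing, so normalization
  statistics never leak from test into train;
* inter-experiment — one full repetition of the gesture protocol trains,
  another tests.

A leakage guard asserts on every dataset that no window (identified by
subject, trial and window start) sits in more than one split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import FeatureTensor, WindowSpec, build_feature_tensors
from .preprocess import FilterSettings, highpass, lowpass, notch
from .recording import RawRecording

SPLITS = ("train", "val", "test")


class LeakageError(AssertionError):
    """A window was assigned to more than one split."""


@dataclass
class GestureDataset:
    """Feature tensors plus a train/val/test assignment per window."""

    tensors: list[FeatureTensor]
    split_assignments: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.split_assignments) != len(self.tensors):
            raise ValueError("one split assignment per tensor is required")
        bad = set(self.split_assignments) - set(SPLITS)
        if bad:
            raise ValueError(f"unknown split names {sorted(bad)}")
        self.assert_no_leakage()

    def assert_no_leakage(self) -> None:
        seen: dict[tuple, str] = {}
        for t, split in zip(self.tensors, self.split_assignments):
            key = (t.subject_id, t.trial_id, t.window_start)
            if key in seen and seen[key] != split:
                raise LeakageError(
                    f"window {key} assigned to both {seen[key]!r} and {split!r}"
                )
            seen[key] = split

    def indices(self, split: str) -> np.ndarray:
        return np.flatnonzero(np.array(self.split_assignments) == split)

    def arrays(self, split: str) -> tuple[np.ndarray, np.ndarray]:
        """(X, y) for one split; X is float32 NHWC, y 0-based int classes."""
        idx = self.indices(split)
        if idx.size == 0:
            raise ValueError(f"split {split!r} is empty")
        x = np.stack([self.tensors[i].data for i in idx]).astype(np.float32)
        y = np.array([self.tensors[i].label - 1 for i in idx], dtype=np.int64)
        return x, y

    @property
    def n_classes(self) -> int:
        return int(max(t.label for t in self.tensors))

    def counts(self) -> dict[str, int]:
        return {s: int(self.indices(s).size) for s in SPLITS}


def _by_trial(tensors: list[FeatureTensor]) -> dict[tuple[str, str], list[int]]:
    groups: dict[tuple[str, str], list[int]] = {}
    for i, t in enumerate(tensors):
        groups.setdefault((t.subject_id, t.trial_id), []).append(i)
    for idxs in groups.values():
        idxs.sort(key=lambda i: tensors[i].window_start)
    return groups


def split_intra(
    tensors: list[FeatureTensor],
    train_fraction: float = 2.0 / 3.0,
    val_fraction: float = 0.1,
) -> GestureDataset:
    """Per trial: leading ``train_fraction`` of windows train, rest tests;
    a ``val_fraction`` tail of the training block becomes validation."""
    assignments = [""] * len(tensors)
    for (subj, trial), idxs in _by_trial(tensors).items():
        n = len(idxs)
        if n < 3:
            raise ValueError(
                f"trial {subj}/{trial} has only {n} windows; need >= 3 for three parts"
            )
        n_trainval = int(np.floor(n * train_fraction))
        n_val = int(np.floor(n_trainval * val_fraction))
        for pos, i in enumerate(idxs):
            if pos < n_trainval - n_val:
                assignments[i] = "train"
            elif pos < n_trainval:
                assignments[i] = "val"
            else:
                assignments[i] = "test"
    return GestureDataset(tensors, assignments)


def split_inter(
    tensors: list[FeatureTensor],
    train_experiment: str,
    test_experiment: str,
    experiment_of=lambda trial_id: trial_id.split("-")[0],
    val_fraction: float = 0.1,
) -> GestureDataset:
    """All windows of one protocol repetition train, another repetition tests.

    ``experiment_of`` maps a trial id to its repetition id (by default the
    leading ``rep<k>`` token of ids like ``rep1-g03``).
    """
    exps = {experiment_of(t.trial_id) for t in tensors}
    for e in (train_experiment, test_experiment):
        if e not in exps:
            raise ValueError(f"experiment {e!r} not present; have {sorted(exps)}")
    keep, assignments = [], []
    for t in tensors:
        e = experiment_of(t.trial_id)
        if e == train_experiment:
            keep.append(t)
            assignments.append("train")
        elif e == test_experiment:
            keep.append(t)
            assignments.append("test")
    # validation tail carved per trial from the training repetition
    ds_idx = [i for i, s in enumerate(assignments) if s == "train"]
    for (_, _), idxs in _by_trial([keep[i] for i in ds_idx]).items():
        n_val = int(np.floor(len(idxs) * val_fraction))
        for pos in range(len(idxs) - n_val, len(idxs)):
            assignments[ds_idx[idxs[pos]]] = "val"
    return GestureDataset(keep, assignments)


def _cut_thirds(rec: RawRecording, train_fraction: float) -> tuple[RawRecording, RawRecording]:
    n = rec.n_samples
    cut = int(np.floor(n * train_fraction))
    if cut < 1 or cut >= n:
        raise ValueError(f"trial {rec.trial_id} too short to split: {n} samples")
    return rec.slice(0, cut), rec.slice(cut, n)


def _filtered(rec: RawRecording, settings: FilterSettings | None) -> RawRecording:
    """High-pass (+ optional low-pass) + notch, without amplitude scaling."""
    settings = settings or FilterSettings()
    settings.validate_against_fs(rec.fs)
    out = highpass(rec, settings)
    if settings.lowpass_cutoff_hz is not None:
        out = lowpass(out, settings)
    return notch(out, settings)


def _train_minmax(train_recs: list[RawRecording]) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel min/max pooled over all training portions."""
    mins = np.min([r.samples.min(axis=0) for r in train_recs], axis=0)
    maxs = np.max([r.samples.max(axis=0) for r in train_recs], axis=0)
    return mins, maxs


def _scale(rec: RawRecording, mins: np.ndarray, maxs: np.ndarray) -> RawRecording:
    span = maxs - mins
    safe = np.where(span == 0, 1.0, span)
    out = (rec.samples - mins) / safe
    out[:, span == 0] = 0.5
    return rec.with_samples(out)


def build_dataset_intra(
    trials: list[RawRecording],
    feature_kind: str = "FFT_RMS",
    window_spec: WindowSpec | None = None,
    filter_settings: FilterSettings | None = None,
    train_fraction: float = 2.0 / 3.0,
    val_fraction: float = 0.1,
) -> GestureDataset:
    """Intra-experiment pipeline honouring split-before-preprocessing.

    Each labelled trial is filtered and cut into contiguous thirds; the
    per-channel min-max scaling is computed over the pooled *training*
    portions only and applied affinely to both portions, so amplitude
    relations between gestures survive normalization but no test statistic
    leaks into training.  The validation tail is carved from the training
    windows.
    """
    window_spec = window_spec or WindowSpec()
    settings = filter_settings or FilterSettings()
    pairs = [_cut_thirds(_filtered(rec, settings), train_fraction) for rec in trials]
    if settings.normalize:
        mins, maxs = _train_minmax([tr for tr, _ in pairs])
        pairs = [(_scale(tr, mins, maxs), _scale(te, mins, maxs)) for tr, te in pairs]
    tensors: list[FeatureTensor] = []
    assignments: list[str] = []
    for train_rec, test_rec in pairs:
        train_t = build_feature_tensors(train_rec, feature_kind, window_spec)
        test_t = build_feature_tensors(test_rec, feature_kind, window_spec)
        # test windows are re-offset so their ids stay distinct from train ids
        for t in test_t:
            t.window_start += train_rec.n_samples
        n_val = int(np.floor(len(train_t) * val_fraction))
        assignments += ["train"] * (len(train_t) - n_val) + ["val"] * n_val
        tensors += train_t
        assignments += ["test"] * len(test_t)
        tensors += test_t
    return GestureDataset(tensors, assignments)


def build_dataset_inter(
    trials: list[RawRecording],
    train_experiment: str,
    test_experiment: str,
    feature_kind: str = "FFT_RMS",
    window_spec: WindowSpec | None = None,
    filter_settings: FilterSettings | None = None,
    experiment_of=lambda trial_id: trial_id.split("-")[0],
    val_fraction: float = 0.1,
) -> GestureDataset:
    """Inter-experiment pipeline: whole repetitions train/test, with the
    min-max statistics taken from the training repetition only."""
    window_spec = window_spec or WindowSpec()
    settings = filter_settings or FilterSettings()
    keep = [
        _filtered(rec, settings)
        for rec in trials
        if experiment_of(rec.trial_id) in (train_experiment, test_experiment)
    ]
    if settings.normalize:
        mins, maxs = _train_minmax(
            [r for r in keep if experiment_of(r.trial_id) == train_experiment]
        )
        keep = [_scale(r, mins, maxs) for r in keep]
    tensors: list[FeatureTensor] = []
    for rec in keep:
        tensors += build_feature_tensors(rec, feature_kind, window_spec)
    return split_inter(
        tensors, train_experiment, test_experiment,
        experiment_of=experiment_of, val_fraction=val_fraction,
    )
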