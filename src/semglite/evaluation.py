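"""Confusion-matrix evaluation and the feature x architecture comparison grid."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import GestureDataset
from .model import size_estimate
from .training import TrainConfig, TrainedModel, train

log = logging.getLogger(__name__)


@dataclass
class EvalReport:
    """Test-split performance of one trained model.

    ``confusion[i, j]`` counts windows of true class ``i+1`` predicted as
    class ``j+1``.  ``per_class_accuracy`` is NaN for classes absent from
    the test split (undefined, not zero).
    """

    confusion: np.ndarray
    per_class_accuracy: np.ndarray
    overall_accuracy: float
    model_bytes: int | None = None

    def normalized_confusion(self) -> np.ndarray:
        """Row-normalized percentages; NaN rows for absent classes."""
        totals = self.confusion.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return 100.0 * self.confusion / totals

    def to_frame(self) -> pd.DataFrame:
        n = self.confusion.shape[0]
        labels = [str(i + 1) for i in range(n)]
        return pd.DataFrame(self.confusion, index=labels, columns=labels)


def evaluate(
    model: TrainedModel, data: GestureDataset, split: str = "test"
) -> EvalReport:
    """Confusion matrix and accuracies of ``model`` on one split."""
    data.assert_no_leakage()
    x, y = data.arrays(split)
    n_classes = model.spec.n_classes
    pred = model.network.predict(x)
    confusion = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(confusion, (y, pred), 1)
    totals = confusion.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_class = np.where(totals > 0, np.diag(confusion) / totals, np.nan)
    overall = float(np.trace(confusion) / len(y))
    return EvalReport(confusion, per_class, overall)


def plot_confusion(report: EvalReport, path, normalized: bool = True) -> None:
    """Render the confusion matrix as a heat-map image (PNG/PDF by suffix)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mat = report.normalized_confusion() if normalized else report.confusion.astype(float)
    n = mat.shape[0]
    fig, ax = plt.subplots(figsize=(0.5 * n + 2, 0.5 * n + 2))
    im = ax.imshow(np.nan_to_num(mat), cmap="Blues")
    ax.set_xlabel("predicted gesture")
    ax.set_ylabel("true gesture")
    ax.set_xticks(range(n), [str(i + 1) for i in range(n)])
    ax.set_yticks(range(n), [str(i + 1) for i in range(n)])
    fig.colorbar(im, ax=ax, label="% of true class" if normalized else "windows")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def compare_grid(
    feature_kinds: list[str],
    variants: list[str],
    datasets: dict[str, GestureDataset],
    cfg: TrainConfig | None = None,
    arch_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Train/evaluate every (feature, variant) pair; one row per combination.

    ``datasets`` maps feature kind to a pre-built dataset (features are
    computed once per kind, not per variant).  Returns columns
    ``feature, variant, accuracy, size_estimate_kb, trainable_params``.
    """
    from .model import build_architecture  # local to keep import light

    if not feature_kinds or not variants:
        raise ValueError("need at least one feature kind and one variant")
    missing = [k for k in feature_kinds if k not in datasets]
    if missing:
        raise ValueError(f"no dataset provided for feature kind(s) {missing}")
    rows = []
    for kind in feature_kinds:
        data = datasets[kind]
        for variant in variants:
            spec = build_architecture(variant, **(arch_kwargs or {}))
            model, _ = train(spec, data, cfg)
            report = evaluate(model, data)
            size = size_estimate(spec)
            rows.append(
                {
                    "feature": kind,
                    "variant": variant,
                    "accuracy": report.overall_accuracy,
                    "size_estimate_kb": size.kilobytes,
                    "trainable_params": size.trainable_params,
                }
            )
            log.info("grid: %s x %s -> accuracy %.3f", kind, variant, rows[-1]["accuracy"])
    return pd.DataFrame(rows)
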