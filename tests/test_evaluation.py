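"""Confusion-matrix bookkeeping and the comparison grid."""

import numpy as np
import pytest

from semglite import GestureDataset, build_architecture, evaluate
from semglite.evaluation import EvalReport
from semglite.training import TrainedModel
from semglite.model import build_network

from test_dataset import make_tensors


class _FixedPredictor:
    """Stands in for a network; returns predictions from a lookup table."""

    def __init__(self, preds):
        self.preds = np.asarray(preds)

    def predict(self, x, batch=256):
        return self.preds[: len(x)]


def _dataset(labels_per_class=4, n_classes=3):
    tensors = []
    for g in range(1, n_classes + 1):
        tensors += make_tensors(labels_per_class, trial_id=f"rep1-g{g:02d}", label=g)
    return GestureDataset(tensors, ["test"] * len(tensors))


def _model_with(preds, n_classes=3):
    spec = build_architecture(
        "CNN", input_shape=(8, 2, 1), n_classes=n_classes,
        conv1_kernel=(3, 2), conv1_maps=4,
    )
    model = TrainedModel(spec, build_network(spec, seed=0))
    model.network = _FixedPredictor(preds)
    return model


class TestEvaluate:
    def test_perfect_predictor(self):
        data = _dataset()
        truth = np.concatenate([[g] * 4 for g in range(3)])
        report = evaluate(_model_with(truth), data)
        assert report.overall_accuracy == 1.0
        np.testing.assert_array_equal(np.diag(report.confusion), [4, 4, 4])
        assert report.confusion.sum() == np.trace(report.confusion)

    def test_constant_predictor_on_balanced_data(self):
        data = _dataset()
        report = evaluate(_model_with(np.zeros(12, dtype=int)), data)
        assert report.overall_accuracy == pytest.approx(1 / 3)

    def test_hand_built_prediction_tally(self):
        data = _dataset(labels_per_class=2)
        preds = np.array([0, 1, 1, 1, 2, 0])  # truth: 0 0 1 1 2 2
        report = evaluate(_model_with(preds), data)
        expected = np.zeros((3, 3), dtype=int)
        for t, p in zip([0, 0, 1, 1, 2, 2], preds):
            expected[t, p] += 1
        np.testing.assert_array_equal(report.confusion, expected)
        assert report.overall_accuracy == pytest.approx(np.trace(expected) / 6)

    def test_row_sums_equal_class_counts(self):
        data = _dataset(labels_per_class=5)
        rng = np.random.default_rng(0)
        report = evaluate(_model_with(rng.integers(0, 3, 15)), data)
        np.testing.assert_array_equal(report.confusion.sum(axis=1), [5, 5, 5])

    def test_absent_class_accuracy_is_nan_not_zero(self):
        tensors = make_tensors(4, trial_id="rep1-g01", label=1)
        data = GestureDataset(tensors, ["test"] * 4)
        report = evaluate(_model_with(np.zeros(4, dtype=int)), data)
        assert np.isnan(report.per_class_accuracy[1])
        assert report.per_class_accuracy[0] == 1.0


class TestCompareGrid:
    @pytest.fixture(scope="class")
    def spectral_trials(self):
        """Three classes separable almost only by carrier band: activation
        rows differ by just over the distinctness floor, bands are disjoint."""
        from semglite import GestureProtocol, generate_trials

        w = np.full((3, 6), 0.6)
        w[1, 0] += 0.25
        w[2, 1] += 0.25
        proto = GestureProtocol(
            n_classes=3,
            activation_matrix=w,
            carrier_bands=[(25.0, 70.0), (150.0, 195.0), (330.0, 375.0)],
            trial_duration_s=1.5,
            rest_duration_s=0.2,
            repetitions=2,
            seed=21,
        )
        return generate_trials(proto)

    def test_one_row_per_combination_with_sizes(self, spectral_trials):
        from semglite import TrainConfig, build_dataset_intra, compare_grid

        datasets = {
            kind: build_dataset_intra(spectral_trials, kind) for kind in ("RAW", "FFT_RMS")
        }
        cfg = TrainConfig(epochs=1, batch_size=16, seed=0, early_stop_train_loss=0.0)
        small = dict(conv1_maps=8, conv2_maps=4, lstm_units=8, n_classes=3)
        table = compare_grid(["RAW", "FFT_RMS"], ["CNN2D_LSTM"], datasets, cfg, small)
        assert len(table) == 2
        assert set(table.columns) >= {"feature", "variant", "accuracy", "size_estimate_kb"}
        assert (table["size_estimate_kb"] > 0).all()

    def test_spectral_features_beat_raw_on_band_separated_classes(self, spectral_trials):
        from semglite import TrainConfig, build_dataset_intra, compare_grid

        datasets = {
            kind: build_dataset_intra(spectral_trials, kind) for kind in ("RAW", "FFT_RMS")
        }
        cfg = TrainConfig(epochs=6, batch_size=16, seed=3, early_stop_train_loss=0.0)
        small = dict(conv1_maps=8, conv2_maps=4, lstm_units=8, n_classes=3)
        table = compare_grid(["RAW", "FFT_RMS"], ["CNN2D_LSTM"], datasets, cfg, small)
        acc = table.set_index("feature")["accuracy"]
        assert acc["FFT_RMS"] >= acc["RAW"]
        assert acc["FFT_RMS"] >= 0.6  # well above the 1/3 chance level

    def test_empty_grid_rejected(self):
        from semglite import compare_grid

        with pytest.raises(ValueError, match="at least one"):
            compare_grid([], ["CNN"], {})


class TestNormalizedConfusion:
    def test_rows_sum_to_hundred(self):
        report = EvalReport(
            confusion=np.array([[3, 1], [0, 4]]),
            per_class_accuracy=np.array([0.75, 1.0]),
            overall_accuracy=7 / 8,
        )
        np.testing.assert_allclose(report.normalized_confusion().sum(axis=1), 100.0)

    def test_heatmap_rendered_to_file(self, tmp_path):
        from semglite.evaluation import plot_confusion

        report = EvalReport(
            confusion=np.array([[3, 1], [0, 4]]),
            per_class_accuracy=np.array([0.75, 1.0]),
            overall_accuracy=7 / 8,
        )
        out = tmp_path / "confusion.png"
        plot_confusion(report, out)
        assert out.stat().st_size > 0
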