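"""Splits, training contract, confusion matrices and the repeat protocol."""

import numpy as np
import pytest

from tempobal.encode import EncodedDataset
from tempobal.errors import ConfigError, InsufficientDataError
from tempobal.network import NetworkSpec, build_network
from tempobal.train_eval import (
    EvalReport,
    TrainConfig,
    ablation_compare,
    evaluate_model,
    pairwise_accuracy,
    repeat_protocol,
    split_dataset,
    train_model,
)

CLASSES = ["N", "D0.25", "D0.5"]


def _toy_dataset(n_per_class=12, w=12, seed=0, separation=0.6):
    """Linearly separable toy tensors: class shifts the mean of the matrices."""
    rng = np.random.default_rng(seed)
    present, ancient, labels = [], [], []
    for ci, cls in enumerate(CLASSES):
        p_on = 0.15 + separation * ci / 2
        for _ in range(n_per_class):
            present.append((rng.random((8, w)) < p_on).astype(np.uint8))
            ancient.append((rng.random((4, 4, w)) < p_on).astype(np.uint8))
            labels.append(cls)
    return EncodedDataset(
        present=np.stack(present),
        ancient=np.stack(ancient),
        labels=np.array(labels),
        classes=CLASSES,
    )


def _splits(ds, seed=0):
    tr, va, te = split_dataset(ds.labels, (0.6, 0.2, 0.2), seed)
    return {"train": ds.subset(tr), "val": ds.subset(va), "test": ds.subset(te)}


SPEC = NetworkSpec(n_filters=8, n_residual_blocks=1, dropout=0.0, seed=0)


class TestSplitDataset:
    def test_stratified_counts(self):
        labels = np.repeat(CLASSES, 300)
        tr, va, te = split_dataset(labels, (0.8, 0.1, 0.1), seed=1)
        assert len(tr) == 720 and len(va) == 90 and len(te) == 90
        for part, n in ((tr, 240), (va, 30), (te, 30)):
            for cls in CLASSES:
                assert (labels[part] == cls).sum() == n
        assert len(set(tr) | set(va) | set(te)) == 900

    def test_deterministic(self):
        labels = np.repeat(CLASSES, 30)
        a = split_dataset(labels, (0.8, 0.1, 0.1), seed=7)
        b = split_dataset(labels, (0.8, 0.1, 0.1), seed=7)
        for x, y in zip(a, b):
            assert np.array_equal(x, y)

    def test_insufficient_class(self):
        labels = ["N"] * 30 + ["D0.25"] * 2 + ["D0.5"] * 30
        with pytest.raises(InsufficientDataError):
            split_dataset(labels, (0.8, 0.1, 0.1), seed=0)

    def test_bad_fractions(self):
        with pytest.raises(ConfigError):
            split_dataset(np.repeat(CLASSES, 10), (0.5, 0.2, 0.2), seed=0)


class TestTrainModel:
    def test_zero_learning_rate_keeps_losses_constant(self):
        ds = _toy_dataset()
        data = _splits(ds)
        cfg = TrainConfig(
            batch_size=8, learning_rate=0.0, max_epochs=4, patience=10,
            n_repeats=1, base_seed=0,
        )
        _, hist = train_model(SPEC, cfg, data, seed=0)
        assert np.allclose(hist["train_loss"], hist["train_loss"][0], atol=1e-6)
        assert np.allclose(hist["val_loss"], hist["val_loss"][0], atol=1e-12)

    def test_same_seed_identical_history(self):
        ds = _toy_dataset()
        data = _splits(ds)
        cfg = TrainConfig(batch_size=8, max_epochs=3, n_repeats=1, base_seed=0)
        _, h1 = train_model(SPEC, cfg, data, seed=3)
        _, h2 = train_model(SPEC, cfg, data, seed=3)
        assert h1 == h2

    def test_learns_separable_toy_data(self):
        ds = _toy_dataset(n_per_class=20)
        data = _splits(ds)
        cfg = TrainConfig(batch_size=8, max_epochs=25, patience=25, n_repeats=1)
        model, _ = train_model(SPEC, cfg, data, seed=1)
        _, acc = evaluate_model(model, data["test"])
        assert acc > 0.8


class TestEvaluateModel:
    class _Stub:
        """Model stub with prescribed predictions."""

        def __init__(self, preds):
            self.preds = np.asarray(preds)

        def predict(self, present, ancient):
            return self.preds

    def test_prescribed_confusion(self):
        ds = _toy_dataset(n_per_class=2, w=4)
        y = ds.y  # 0,0,1,1,2,2
        preds = np.array([0, 1, 1, 1, 2, 2])
        cm, acc = evaluate_model(self._Stub(preds), ds)
        assert np.array_equal(cm, [[1, 1, 0], [0, 2, 0], [0, 0, 2]])
        assert acc == pytest.approx(5 / 6)
        assert cm.sum() == len(ds)

    def test_perfect_predictions(self):
        ds = _toy_dataset(n_per_class=2, w=4)
        cm, acc = evaluate_model(self._Stub(ds.y), ds)
        assert np.array_equal(cm, np.diag([2, 2, 2]))
        assert acc == 1.0


class TestPairwiseAccuracy:
    def test_restricted_count_example(self):
        cm = np.array([[5, 0, 0], [0, 8, 2], [0, 3, 7]])
        assert pairwise_accuracy(cm, 1, 2) == pytest.approx(15 / 20)

    def test_empty_submatrix(self):
        assert np.isnan(pairwise_accuracy(np.zeros((3, 3), dtype=int)))


class TestRepeatProtocol:
    def test_report_structure_and_intervals(self):
        ds = _toy_dataset(n_per_class=10)
        data = _splits(ds)
        cfg = TrainConfig(batch_size=8, max_epochs=2, n_repeats=3, base_seed=5)
        report = repeat_protocol(SPEC, cfg, data)
        assert report.matrices.shape == (3, 3, 3)
        assert report.seeds == [5, 6, 7]
        assert all(m.sum() == len(data["test"]) for m in report.matrices)
        rows = report.normalized.sum(axis=1)
        assert np.allclose(rows, 1.0, atol=1e-9)
        lo, hi = report.ci95
        assert lo <= report.mean_accuracy <= hi

    def test_single_repeat_interval_undefined(self):
        acc = np.array([0.5])
        report = EvalReport(
            mode="both", classes=CLASSES,
            matrices=np.ones((1, 3, 3), dtype=np.int64),
            accuracies=acc, seeds=[0],
        )
        assert report.ci95 is None

    def test_zero_variance_interval(self):
        report = EvalReport(
            mode="both", classes=CLASSES,
            matrices=np.ones((3, 3, 3), dtype=np.int64),
            accuracies=np.array([0.4, 0.4, 0.4]), seeds=[0, 1, 2],
        )
        lo, hi = report.ci95
        assert lo == pytest.approx(hi)


class TestAblationCompare:
    def test_three_modes_reported(self):
        ds = _toy_dataset(n_per_class=10)
        data = _splits(ds)
        cfg = TrainConfig(batch_size=8, max_epochs=2, n_repeats=2, base_seed=0)
        result = ablation_compare(cfg, data, SPEC)
        assert set(result.reports) == {"both", "present_only", "ancient_only"}
        assert result.pair_classes == ("D0.25", "D0.5")
        for mode, rep in result.reports.items():
            assert rep.mode == mode
            assert 0.0 <= result.pairwise[mode] <= 1.0
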