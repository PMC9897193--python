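"""Training protocol and evaluation reports.

The protocol mirrors a simulation-based supervised study: one stratified
train/validation/test split of the encoded dataset, ``n_repeats`` independent
trainings (fresh initialisation and batch order per repeat, split held fixed
so the interval isolates training variance), per-repeat 3x3 confusion
matrices on the held-out test set, and a t-based 95% interval on accuracy
over repeats. Branch ablations retrain single-branch models from scratch on
identical splits and seed streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from ._nn import Adam, cross_entropy
from .encode import EncodedDataset
from .errors import ConfigError, InsufficientDataError, TrainingDivergedError
from .network import MODES, NetworkSpec, TwoBranchNet, build_network

__all__ = [
    "TrainConfig",
    "EvalReport",
    "AblationResult",
    "split_dataset",
    "train_model",
    "evaluate_model",
    "repeat_protocol",
    "ablation_compare",
    "pairwise_accuracy",
]


@dataclass(frozen=True)
class TrainConfig:
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)  # train/val/test
    batch_size: int = 32
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    max_epochs: int = 50
    patience: int = 10  # early stopping on validation accuracy
    n_repeats: int = 10
    base_seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9 or any(f <= 0 for f in self.fractions):
            raise ConfigError("split fractions must be positive and sum to 1")
        if self.batch_size < 1 or self.max_epochs < 1 or self.patience < 0:
            raise ConfigError("batch_size/max_epochs/patience out of range")
        if self.optimizer != "adam":
            raise ConfigError("only the 'adam' optimiser is implemented")
        if self.n_repeats < 1:
            raise ConfigError("n_repeats must be >= 1")


def split_dataset(
    labels: Sequence, fractions: tuple[float, float, float], seed: int
):
    """Disjoint, exhaustive, label-stratified (train, validation, test) index
    arrays; per-class counts are within one sample of the global fractions."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigError("split fractions must sum to 1")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train, val, test = [], [], []
    for cls in np.unique(labels):
        idx = np.nonzero(labels == cls)[0]
        n = idx.size
        n_tr = round(fractions[0] * n)
        n_va = round(fractions[1] * n)
        n_te = n - n_tr - n_va
        if min(n_tr, n_va, n_te) < 1:
            raise InsufficientDataError(
                f"class {cls!r} has {n} samples; cannot fill all three splits "
                f"with fractions {fractions}"
            )
        perm = rng.permutation(idx)
        train.append(perm[:n_tr])
        val.append(perm[n_tr : n_tr + n_va])
        test.append(perm[n_tr + n_va :])
    return (
        np.sort(np.concatenate(train)),
        np.sort(np.concatenate(val)),
        np.sort(np.concatenate(test)),
    )


def _accuracy(model: TwoBranchNet, ds: EncodedDataset, batch: int = 256):
    """(mean cross-entropy, accuracy) of the model in evaluation mode."""
    y = ds.y
    losses = 0.0
    correct = 0
    for lo in range(0, len(ds), batch):
        sl = slice(lo, lo + batch)
        logits = model.forward(ds.present[sl], ds.ancient[sl])
        loss, _ = cross_entropy(logits, y[sl])
        losses += loss * logits.shape[0]
        correct += int((logits.argmax(axis=1) == y[sl]).sum())
    return losses / len(ds), correct / len(ds)


def train_model(
    spec: NetworkSpec,
    train_cfg: TrainConfig,
    data: dict,
    seed: Optional[int] = None,
):
    """Train one model; returns (model with best-validation weights, history).

    ``data`` maps 'train' and 'val' to :class:`EncodedDataset`. ``seed``
    (default ``train_cfg.base_seed``) drives initialisation, batch order and
    dropout; identical seeds reproduce identical histories.
    """
    if seed is None:
        seed = train_cfg.base_seed
    train_ds: EncodedDataset = data["train"]
    val_ds: EncodedDataset = data["val"]
    for name, ds in (("train", train_ds), ("val", val_ds)):
        if len(np.unique(ds.labels)) < len(ds.classes):
            raise InsufficientDataError(f"{name} split lacks at least one class")

    model = build_network(
        replace(spec, seed=seed), n_ancient_channels=train_ds.ancient.shape[1]
    )
    optimiser = Adam(model.params(), lr=train_cfg.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))
    y = train_ds.y
    n = len(train_ds)

    history = {"train_loss": [], "train_acc": [], "val_loss": [], "val_acc": []}
    best_acc = -1.0
    best_weights = model.get_weights()
    best_epoch = 0
    since_best = 0

    for epoch in range(train_cfg.max_epochs):
        order = rng.permutation(n)
        loss_sum = 0.0
        correct = 0
        for lo in range(0, n, train_cfg.batch_size):
            idx = order[lo : lo + train_cfg.batch_size]
            loss, n_ok = model.train_step(
                train_ds.present[idx], train_ds.ancient[idx], y[idx], optimiser, rng
            )
            if not np.isfinite(loss):
                raise TrainingDivergedError(f"non-finite loss at epoch {epoch}")
            loss_sum += loss * idx.size
            correct += n_ok
        val_loss, val_acc = _accuracy(model, val_ds)
        history["train_loss"].append(loss_sum / n)
        history["train_acc"].append(correct / n)
        history["val_loss"].append(val_loss)
        history["val_acc"].append(val_acc)
        if val_acc > best_acc:
            best_acc = val_acc
            best_weights = model.get_weights()
            best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best > train_cfg.patience:
                break

    model.set_weights(best_weights)
    history["best_epoch"] = best_epoch
    return model, history


def evaluate_model(model: TwoBranchNet, test_ds: EncodedDataset):
    """3x3 confusion matrix (rows = true, columns = predicted) and accuracy."""
    if len(test_ds) == 0:
        raise InsufficientDataError("empty test set")
    y = test_ds.y
    pred = np.concatenate(
        [
            model.predict(test_ds.present[lo : lo + 256], test_ds.ancient[lo : lo + 256])
            for lo in range(0, len(test_ds), 256)
        ]
    )
    k = len(test_ds.classes)
    cm = np.zeros((k, k), dtype=np.int64)
    np.add.at(cm, (y, pred), 1)
    return cm, float(np.trace(cm) / cm.sum())


@dataclass
class EvalReport:
    """Per-repeat confusion matrices with aggregated accuracy."""

    mode: str
    classes: list[str]
    matrices: np.ndarray  # (n_repeats, k, k) int64
    accuracies: np.ndarray  # (n_repeats,)
    seeds: list[int]
    mean_accuracy: float = field(init=False)
    ci95: Optional[tuple[float, float]] = field(init=False)
    normalized: np.ndarray = field(init=False)  # row-stochastic, mean over repeats

    def __post_init__(self) -> None:
        self.mean_accuracy = float(np.mean(self.accuracies))
        n = len(self.accuracies)
        if n >= 2:
            sd = float(np.std(self.accuracies, ddof=1))
            half = stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
            self.ci95 = (self.mean_accuracy - half, self.mean_accuracy + half)
        else:
            self.ci95 = None  # undefined for a single repeat
        rows = self.matrices.sum(axis=2, keepdims=True)
        self.normalized = (self.matrices / rows).mean(axis=0)

    @property
    def n_repeats(self) -> int:
        return self.matrices.shape[0]

    def to_summary_dict(self) -> dict:
        return {
            "mode": self.mode,
            "classes": self.classes,
            "n_repeats": self.n_repeats,
            "mean_accuracy": self.mean_accuracy,
            "ci95": list(self.ci95) if self.ci95 is not None else None,
            "per_repeat_accuracy": [float(a) for a in self.accuracies],
            "normalized_confusion": self.normalized.tolist(),
            "seeds": self.seeds,
        }

    def to_long_rows(self):
        """Long-format rows (repeat, true, predicted, count) for TSV export."""
        rows = []
        for r in range(self.n_repeats):
            for i, t in enumerate(self.classes):
                for j, p in enumerate(self.classes):
                    rows.append((r, t, p, int(self.matrices[r, i, j])))
        return rows


def repeat_protocol(
    spec: NetworkSpec, train_cfg: TrainConfig, data: dict
) -> EvalReport:
    """Run train + evaluate ``n_repeats`` times with seeds ``base_seed ..
    base_seed + n - 1`` on the same split; report matrices, mean accuracy and
    the 95% t-interval over repeats."""
    test_ds: EncodedDataset = data["test"]
    matrices, accs, seeds = [], [], []
    for r in range(train_cfg.n_repeats):
        seed = train_cfg.base_seed + r
        model, _ = train_model(spec, train_cfg, data, seed=seed)
        cm, acc = evaluate_model(model, test_ds)
        matrices.append(cm)
        accs.append(acc)
        seeds.append(seed)
    return EvalReport(
        mode=spec.mode,
        classes=list(test_ds.classes),
        matrices=np.stack(matrices),
        accuracies=np.array(accs),
        seeds=seeds,
    )


def pairwise_accuracy(cm: np.ndarray, i: int = 1, j: int = 2) -> float:
    """Discrimination accuracy between classes ``i`` and ``j``: correct calls
    among all samples whose true class is one of the two (confusion-matrix
    rows ``i`` and ``j``)."""
    total = cm[[i, j], :].sum()
    return float((cm[i, i] + cm[j, j]) / total) if total else float("nan")


@dataclass
class AblationResult:
    reports: dict[str, EvalReport]
    pairwise: dict[str, float]  # mean weak-vs-moderate accuracy per mode
    pair_classes: tuple[str, str]

    def to_summary_dict(self) -> dict:
        return {
            "pair_classes": list(self.pair_classes),
            "modes": {
                m: {
                    **r.to_summary_dict(),
                    "pairwise_accuracy": self.pairwise[m],
                }
                for m, r in self.reports.items()
            },
        }


def ablation_compare(
    train_cfg: TrainConfig,
    data: dict,
    base_spec: Optional[NetworkSpec] = None,
    modes: Sequence[str] = MODES,
    pair: tuple[int, int] = (1, 2),
) -> AblationResult:
    """Repeat the protocol for the two-branch model and both single-branch
    ablations on identical splits and seed streams; also report the weak vs
    moderate pairwise discrimination accuracy per mode."""
    if base_spec is None:
        base_spec = NetworkSpec()
    classes = data["test"].classes
    reports: dict[str, EvalReport] = {}
    pairwise: dict[str, float] = {}
    for mode in modes:
        if mode not in MODES:
            raise ConfigError(f"unknown mode {mode!r}")
        report = repeat_protocol(replace(base_spec, mode=mode), train_cfg, data)
        reports[mode] = report
        pairwise[mode] = float(
            np.mean([pairwise_accuracy(m, *pair) for m in report.matrices])
        )
    return AblationResult(
        reports=reports,
        pairwise=pairwise,
        pair_classes=(classes[pair[0]], classes[pair[1]]),
    )
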