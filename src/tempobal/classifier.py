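"""Scikit-learn style front end to the two-branch network.

:class:`BalancingSelectionClassifier` wraps network construction, the
training loop and prediction behind the familiar ``fit`` / ``predict`` /
``predict_proba`` surface, so the model composes with sklearn tools and
pipelines (via :class:`tempobal.encode.HaplotypeEncoder`, which maps lists of
:class:`TemporalSample` to the stacked tensors this estimator consumes).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .encode import EncodedDataset
from .errors import ConfigError
from .network import NetworkSpec, TwoBranchNet
from .train_eval import TrainConfig, split_dataset, train_model

__all__ = ["BalancingSelectionClassifier"]


class BalancingSelectionClassifier(ClassifierMixin, BaseEstimator):
    """Ternary classifier of neutrality vs weak vs moderate overdominance.

    Parameters mirror :class:`NetworkSpec` and :class:`TrainConfig`; the
    estimator carves a stratified validation split from the training data and
    keeps the weights of the best validation-accuracy epoch.

    Attributes (after ``fit``): ``classes_``, ``model_``, ``history_``,
    ``spec_``.
    """

    def __init__(
        self,
        mode: str = "both",
        n_filters: int = 64,
        kernel: tuple[int, int] = (3, 3),
        n_residual_blocks: int = 2,
        dropout: float = 0.25,
        exchangeable_present: bool = False,
        batch_size: int = 32,
        learning_rate: float = 1e-3,
        max_epochs: int = 50,
        patience: int = 10,
        validation_fraction: float = 0.15,
        random_state: int = 0,
    ):
        self.mode = mode
        self.n_filters = n_filters
        self.kernel = kernel
        self.n_residual_blocks = n_residual_blocks
        self.dropout = dropout
        self.exchangeable_present = exchangeable_present
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # ------------------------------------------------------------------

    def _spec(self) -> NetworkSpec:
        kernel = tuple(self.kernel)
        return NetworkSpec(
            mode=self.mode,
            n_filters=self.n_filters,
            kernel=kernel,
            padding=(kernel[0] // 2, kernel[1] // 2),
            n_residual_blocks=self.n_residual_blocks,
            dropout=self.dropout,
            exchangeable_present=self.exchangeable_present,
            seed=self.random_state,
        )

    @staticmethod
    def _as_dataset(X, y=None) -> EncodedDataset:
        if isinstance(X, EncodedDataset):
            return X
        try:
            present, ancient = X
        except (TypeError, ValueError) as exc:
            raise ConfigError(
                "X must be an EncodedDataset or a (present, ancient) pair"
            ) from exc
        if y is None:
            raise ConfigError("y is required when X is a raw (present, ancient) pair")
        labels = np.asarray(y).astype(str)
        return EncodedDataset(
            present=np.asarray(present),
            ancient=np.asarray(ancient),
            labels=labels,
            classes=sorted(np.unique(labels).tolist()),
        )

    def fit(self, X, y=None) -> "BalancingSelectionClassifier":
        ds = self._as_dataset(X, y)
        if not 0.0 < self.validation_fraction < 0.5:
            raise ConfigError("validation_fraction must be in (0, 0.5)")
        f_val = self.validation_fraction
        train_idx, val_idx, extra = split_dataset(
            ds.labels, (1.0 - 1.5 * f_val, f_val, 0.5 * f_val), self.random_state
        )
        # the split helper always reserves a third bucket; fold it into training
        train_idx = np.sort(np.concatenate([train_idx, extra]))
        cfg = TrainConfig(
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            max_epochs=self.max_epochs,
            patience=self.patience,
            n_repeats=1,
            base_seed=self.random_state,
        )
        model, history = train_model(
            self._spec(),
            cfg,
            {"train": ds.subset(train_idx), "val": ds.subset(val_idx)},
            seed=self.random_state,
        )
        self.model_: TwoBranchNet = model
        self.history_ = history
        self.spec_ = self._spec()
        self.classes_ = np.asarray(ds.classes)
        return self

    # ------------------------------------------------------------------

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise ConfigError("this classifier has not been fitted yet")

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        ds = X if isinstance(X, EncodedDataset) else None
        present, ancient = (
            (ds.present, ds.ancient) if ds is not None else (X[0], X[1])
        )
        return np.concatenate(
            [
                self.model_.predict_proba(
                    present[lo : lo + 256], ancient[lo : lo + 256]
                )
                for lo in range(0, present.shape[0], 256)
            ]
        )

    def predict(self, X) -> np.ndarray:
        self._check_fitted()
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def score(self, X, y=None, sample_weight=None) -> float:
        ds = X if isinstance(X, EncodedDataset) else None
        if y is None:
            if ds is None:
                raise ConfigError("y is required when X is not an EncodedDataset")
            y = ds.labels
        pred = self.predict(X)
        return float(np.mean(np.asarray(y).astype(str) == pred))
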