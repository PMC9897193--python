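"""Two-branch residual convolutional classifier for temporal haplotype data.

One branch receives the present-day haplotype matrix (one input channel), the
other the stacked ancient blocks (one channel per sampling time, oldest
first). Each branch is a convolutional stem followed by residual blocks
(64-filter 3x3 convolutions with 1x1 'same' padding by default) interleaved
with 2x2 max pooling, reduced to a fixed-length embedding by global average
pooling. Branch embeddings are concatenated and a single dense layer produces
the three class logits (neutral / weak / moderate overdominance).

Permutation invariance over haplotypes within a block is supplied upstream by
the canonical frequency sorting in :mod:`tempobal.encode`; an optional
exchangeable present-branch variant (row-shared 1x3 convolutions, so rows are
never mixed before the mean reduction) is available via
``exchangeable_present=True``.

Single-branch ablations (``mode='present_only'`` / ``'ancient_only'``) build
only that branch feeding the dense head; they are independent models trained
from scratch, not masked variants of the two-branch model.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Optional

import numpy as np

from ._nn import (
    F32,
    Adam,
    Conv2d,
    Dense,
    Dropout,
    GlobalAvgPool,
    MaxPool2d,
    ReLU,
    ResidualBlock,
    cross_entropy,
    softmax,
)
from .errors import ConfigError

__all__ = ["NetworkSpec", "TwoBranchNet", "build_network", "predict", "MODES"]

MODES = ("both", "present_only", "ancient_only")


@dataclass(frozen=True)
class NetworkSpec:
    mode: str = "both"
    n_filters: int = 64
    kernel: tuple[int, int] = (3, 3)
    padding: tuple[int, int] = (1, 1)
    n_residual_blocks: int = 2
    n_classes: int = 3
    pooling: str = "mean"  # reduction to the branch embedding
    dropout: float = 0.25
    exchangeable_present: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ConfigError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.n_classes != 3:
            raise ConfigError("the classifier is ternary: n_classes must be 3")
        kh, kw = self.kernel
        if self.padding != (kh // 2, kw // 2):
            raise ConfigError(
                "padding must equal kernel // 2 ('same') so residual blocks "
                f"preserve shape; expected {(kh // 2, kw // 2)}"
            )
        if self.pooling != "mean":
            raise ConfigError("only the 'mean' (global average) reduction is implemented")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigError("dropout must be in [0, 1)")
        if self.n_residual_blocks < 0:
            raise ConfigError("n_residual_blocks must be >= 0")

    @property
    def embedding_dim(self) -> int:
        return self.n_filters * (2 if self.mode == "both" else 1)

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "NetworkSpec":
        d = json.loads(text)
        d["kernel"] = tuple(d["kernel"])
        d["padding"] = tuple(d["padding"])
        return cls(**d)


class _Branch:
    """Stem convolution + (pool, residual)*n + global mean reduction."""

    def __init__(self, c_in: int, spec: NetworkSpec, kernel: tuple[int, int], rng):
        self.stem = Conv2d(c_in, spec.n_filters, kernel, rng)
        self.relu = ReLU()
        pool_kernel = (1, 2) if kernel[0] == 1 else (2, 2)
        self.stages = [
            (MaxPool2d(pool_kernel), ResidualBlock(spec.n_filters, kernel, rng))
            for _ in range(spec.n_residual_blocks)
        ]
        self.gap = GlobalAvgPool()

    def params(self):
        ps = self.stem.params()
        for _, res in self.stages:
            ps += res.params()
        return ps

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = self.relu.forward(self.stem.forward(x))
        for pool, res in self.stages:
            h = res.forward(pool.forward(h))
        return self.gap.forward(h)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dh = self.gap.backward(dy)
        for pool, res in reversed(self.stages):
            dh = pool.backward(res.backward(dh))
        return self.stem.backward(self.relu.backward(dh))


class TwoBranchNet:
    """The assembled model; ``spec.mode`` decides which branches exist."""

    def __init__(self, spec: NetworkSpec, n_ancient_channels: int = 4):
        self.spec = spec
        self.n_ancient_channels = n_ancient_channels
        rng = np.random.default_rng(spec.seed)
        self.present_branch: Optional[_Branch] = None
        self.ancient_branch: Optional[_Branch] = None
        if spec.mode in ("both", "present_only"):
            kernel = (1, spec.kernel[1]) if spec.exchangeable_present else spec.kernel
            self.present_branch = _Branch(1, spec, kernel, rng)
        if spec.mode in ("both", "ancient_only"):
            self.ancient_branch = _Branch(n_ancient_channels, spec, spec.kernel, rng)
        self.dropout = Dropout(spec.dropout)
        self.head = Dense(spec.embedding_dim, spec.n_classes, rng)

    # -- parameters -----------------------------------------------------

    def params(self):
        ps = []
        if self.present_branch is not None:
            ps += self.present_branch.params()
        if self.ancient_branch is not None:
            ps += self.ancient_branch.params()
        ps += self.head.params()
        return ps

    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def set_weights(self, weights) -> None:
        params = self.params()
        if len(weights) != len(params):
            raise ValueError("weight list does not match the model's parameters")
        for p, w in zip(params, weights):
            if p.value.shape != w.shape:
                raise ValueError("weight shape mismatch")
            p.value = w.astype(F32).copy()

    # -- forward / backward ---------------------------------------------

    @staticmethod
    def _as_float(present, ancient):
        """Convert (B, H, W) present and (B, T, H, W) ancient inputs to the
        channels-last layout the layers use internally."""
        p = a = None
        if present is not None:
            p = np.asarray(present, dtype=F32)
            if p.ndim == 3:
                p = p[..., None]  # (B, H, W, 1)
        if ancient is not None:
            a = np.asarray(ancient, dtype=F32)
            if a.ndim == 4:
                a = np.ascontiguousarray(a.transpose(0, 2, 3, 1))  # (B, H, W, T)
        return p, a

    def embeddings(self, present, ancient) -> np.ndarray:
        """Concatenated branch embeddings (before dropout and the head)."""
        p, a = self._as_float(present, ancient)
        parts = []
        if self.present_branch is not None:
            if p is None:
                raise ConfigError("model mode requires the present-day tensor")
            parts.append(self.present_branch.forward(p))
        if self.ancient_branch is not None:
            if a is None:
                raise ConfigError("model mode requires the ancient tensor")
            if a.shape[-1] != self.n_ancient_channels:
                raise ValueError(
                    f"expected {self.n_ancient_channels} ancient time-point "
                    f"channels, got {a.shape[-1]}"
                )
            parts.append(self.ancient_branch.forward(a))
        return np.concatenate(parts, axis=1)

    def head_forward(self, emb: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        return self.head.forward(self.dropout.forward(emb, train, rng))

    def forward(self, present, ancient, train: bool = False, rng=None) -> np.ndarray:
        return self.head_forward(self.embeddings(present, ancient), train, rng)

    def predict_proba(self, present, ancient) -> np.ndarray:
        return softmax(self.forward(present, ancient).astype(np.float64))

    def predict(self, present, ancient) -> np.ndarray:
        return self.forward(present, ancient).argmax(axis=1)

    def train_step(self, present, ancient, y, optimiser: Adam, rng):
        """One optimiser step; returns (mean loss, correct count) on the batch
        (computed from the training-mode logits)."""
        optimiser.zero_grad()
        logits = self.forward(present, ancient, train=True, rng=rng)
        loss, dlogits = cross_entropy(logits, y)
        demb = self.dropout.backward(self.head.backward(dlogits))
        off = 0
        if self.present_branch is not None:
            self.present_branch.backward(demb[:, off : off + self.spec.n_filters])
            off += self.spec.n_filters
        if self.ancient_branch is not None:
            self.ancient_branch.backward(demb[:, off : off + self.spec.n_filters])
        optimiser.step()
        return loss, int((logits.argmax(axis=1) == y).sum())


def build_network(spec: NetworkSpec, n_ancient_channels: int = 4) -> TwoBranchNet:
    """Construct the (seeded) model for ``spec``; two builds with the same
    spec have identical initial parameters."""
    return TwoBranchNet(spec, n_ancient_channels=n_ancient_channels)


def predict(model: TwoBranchNet, x) -> np.ndarray:
    """Class-probability triple(s) for one FeatureTensor or an encoded batch."""
    from .encode import EncodedDataset, FeatureTensor

    if isinstance(x, FeatureTensor):
        present = x.present[None]
        ancient = x.ancient[None]
        return model.predict_proba(present, ancient)[0]
    if isinstance(x, EncodedDataset):
        return model.predict_proba(x.present, x.ancient)
    present, ancient = x
    return model.predict_proba(present, ancient)
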