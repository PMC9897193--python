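"""Conversion of serial haplotype samples into fixed-shape network inputs.

A :class:`TemporalSample` becomes a :class:`FeatureTensor`:

* ``present``: the age-0 block, haplotypes sorted by frequency, windowed to
  ``W`` SNP columns around the focal position (locus centre for neutral loci);
* ``ancient``: the ancient blocks, individually sorted the same way, stacked
  as channels ordered oldest to youngest (T x n_ancient x W).

Row sorting groups identical haplotypes and orders groups by descending
multiplicity, ties broken by descending lexicographic order of the row bits,
giving a canonical form invariant to the original haplotype ordering. SNP
columns are left in positional order (no column sorting) so local linkage
structure is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ConfigError
from .simulate import TemporalSample

__all__ = [
    "FeatureTensor",
    "EncodedDataset",
    "sort_by_frequency",
    "window_and_pad",
    "build_feature_tensor",
    "encode_samples",
    "HaplotypeEncoder",
]


@dataclass
class FeatureTensor:
    present: np.ndarray  # (n_present, W) uint8
    ancient: np.ndarray  # (T, n_ancient, W) uint8
    label: str
    focal_column: Optional[int] = None

    @property
    def width(self) -> int:
        return self.present.shape[1]


@dataclass
class EncodedDataset:
    """Stacked feature tensors ready for training."""

    present: np.ndarray  # (n, n_present, W)
    ancient: np.ndarray  # (n, T, n_ancient, W)
    labels: np.ndarray  # (n,) str
    classes: list[str]  # label -> index mapping, fixed order

    @property
    def y(self) -> np.ndarray:
        index = {c: i for i, c in enumerate(self.classes)}
        return np.array([index[l] for l in self.labels], dtype=np.int64)

    def __len__(self) -> int:
        return self.present.shape[0]

    def subset(self, idx) -> "EncodedDataset":
        idx = np.asarray(idx)
        return EncodedDataset(
            present=self.present[idx],
            ancient=self.ancient[idx],
            labels=self.labels[idx],
            classes=list(self.classes),
        )


def sort_by_frequency(M: np.ndarray) -> np.ndarray:
    """Canonical row order: identical haplotypes grouped, groups by descending
    count, ties by descending lexicographic order of the bits."""
    M = np.asarray(M, dtype=np.uint8)
    if M.ndim != 2 or M.shape[0] < 1:
        raise ValueError("expected a non-empty 2-D haplotype matrix")
    if M.shape[1] == 0:
        return M.copy()
    uniq, counts = np.unique(M, axis=0, return_counts=True)  # ascending lex
    # primary: count descending; secondary: lex descending (= index descending)
    order = np.lexsort((-np.arange(uniq.shape[0]), -counts))
    return np.repeat(uniq[order], counts[order], axis=0)


def _window_columns(positions: np.ndarray, centre: float, w: int) -> np.ndarray:
    """Indices of the ``w`` columns whose positions are nearest ``centre``,
    in positional order; deterministic distance/position tie-break."""
    dist = np.abs(positions - centre)
    picked = np.lexsort((positions, dist))[:w]
    return np.sort(picked)


def window_and_pad(sample: TemporalSample, width: int) -> TemporalSample:
    """Restrict every block to the ``width`` SNP columns nearest the focal
    position (locus centre for neutral samples); if fewer exist, zero columns
    are appended symmetrically (extra column on the right when odd).

    Column selection is shared across blocks, so the windowed sample keeps the
    shared-positions invariant. Padded columns carry synthetic positions
    immediately outside the retained range.
    """
    if width < 1:
        raise ConfigError("window width must be >= 1")
    n_sites = sample.n_sites
    if sample.focal_site_index is not None:
        centre = float(sample.positions[sample.focal_site_index])
    else:
        centre = sample.locus_length / 2.0

    cols = _window_columns(sample.positions, centre, width)
    kept = cols.size
    pad_left = (width - kept) // 2
    pad_right = width - kept - pad_left

    def pad_block(M: np.ndarray) -> np.ndarray:
        Mw = M[:, cols]
        if pad_left or pad_right:
            Mw = np.pad(Mw, ((0, 0), (pad_left, pad_right)))
        return np.ascontiguousarray(Mw, dtype=np.uint8)

    positions = sample.positions[cols]
    if pad_left or pad_right:
        eps = max(sample.locus_length, 1.0) * 1e-9
        lo = positions[0] if kept else sample.locus_length / 2.0
        hi = positions[-1] if kept else sample.locus_length / 2.0
        left = lo - eps * np.arange(pad_left, 0, -1)
        right = hi + eps * np.arange(1, pad_right + 1)
        positions = np.concatenate([left, positions, right])

    focal = sample.focal_site_index
    if focal is not None:
        hit = np.nonzero(cols == focal)[0]
        focal = int(hit[0]) + pad_left if hit.size else None

    return TemporalSample(
        blocks=[(age, pad_block(M)) for age, M in sample.blocks],
        positions=positions,
        focal_site_index=focal,
        label=sample.label,
        locus_length=sample.locus_length,
        provenance=dict(sample.provenance),
    )


def build_feature_tensor(sample: TemporalSample, width: int) -> FeatureTensor:
    """Window, canonically sort and stack one sample for the network."""
    ages = sample.ages
    if ages.count(0.0) != 1:
        raise ConfigError("sample must contain exactly one age-0 (present-day) block")
    ancient = [(a, M) for a, M in sample.blocks if a != 0.0]
    if ancient:
        n_rows = {M.shape[0] for _, M in ancient}
        if len(n_rows) != 1:
            raise ConfigError(f"ancient blocks have unequal row counts: {sorted(n_rows)}")
    windowed = window_and_pad(sample, width)
    present = sort_by_frequency(windowed.block(0.0))
    ancient_sorted = [
        sort_by_frequency(M)
        for a, M in sorted(
            ((a, M) for a, M in windowed.blocks if a != 0.0), key=lambda x: -x[0]
        )
    ]
    ancient_tensor = (
        np.stack(ancient_sorted)
        if ancient_sorted
        else np.zeros((0, 0, width), dtype=np.uint8)
    )
    return FeatureTensor(
        present=present,
        ancient=ancient_tensor,
        label=sample.label,
        focal_column=windowed.focal_site_index,
    )


def encode_samples(
    samples: Sequence[TemporalSample], width: int, classes: Optional[list[str]] = None
) -> EncodedDataset:
    tensors = [build_feature_tensor(s, width) for s in samples]
    if classes is None:
        classes = sorted({t.label for t in tensors})
    return EncodedDataset(
        present=np.stack([t.present for t in tensors]),
        ancient=np.stack([t.ancient for t in tensors]),
        labels=np.array([t.label for t in tensors]),
        classes=classes,
    )


class HaplotypeEncoder(TransformerMixin, BaseEstimator):
    """Transformer from lists of :class:`TemporalSample` to stacked feature
    tensors; composes with the classifier in a pipeline.

    Parameters
    ----------
    width : int
        Number of SNP columns retained around the focal position.
    classes : list of str, optional
        Fixed label order; inferred (sorted) when omitted.
    """

    def __init__(self, width: int = 128, classes: Optional[list[str]] = None):
        self.width = width
        self.classes = classes

    def fit(self, X: Sequence[TemporalSample], y=None) -> "HaplotypeEncoder":
        self.classes_ = (
            list(self.classes)
            if self.classes is not None
            else sorted({s.label for s in X})
        )
        return self

    def transform(self, X: Sequence[TemporalSample]) -> EncodedDataset:
        if not hasattr(self, "classes_"):
            self.fit(X)
        return encode_samples(X, self.width, list(self.classes_))
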