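"""Deterministic synthetic fixtures for tests and calibration checks.

These generators build :class:`TemporalSample` objects directly (no
population simulation), so they are instant and fully seeded:

* ``tiny``      — 6 samples (2 per class) for format round-trip tests;
* ``null``      — classes identically distributed (neutral-like site
                  frequency spectrum, exchangeable rows), so any classifier's
                  ternary accuracy is 1/3 in expectation;
* ``separable`` — a planted, trivially separable signal: the derived-allele
                  frequency of a central column band differs by class, which
                  even a linear classifier on column means can pick up.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np

from .errors import ConfigError
from .simulate import TemporalSample

__all__ = ["make_fixture", "FIXTURE_KINDS", "FIXTURE_CLASSES"]

FIXTURE_KINDS = ("separable", "null", "tiny")
FIXTURE_CLASSES = ["N", "D0.25", "D0.5"]

_SCHEME = ((8000.0, 10), (4000.0, 10), (2000.0, 10), (1000.0, 10), (0.0, 40))
_LOCUS = 50_000.0


def _neutral_frequencies(n_sites: int, total_rows: int, rng) -> np.ndarray:
    """Derived-allele counts with the 1/k neutral spectrum over the pooled rows."""
    k = np.arange(1, total_rows)
    p = (1.0 / k) / (1.0 / k).sum()
    return rng.choice(k, size=n_sites, p=p)


def _one_sample(
    label: str,
    rng,
    n_sites: int = 60,
    scheme=_SCHEME,
    band_freq: Optional[float] = None,
    band_width: int = 16,
) -> TemporalSample:
    total = sum(n for _, n in scheme)
    positions = np.sort(rng.uniform(0.0, _LOCUS, size=n_sites))
    counts = _neutral_frequencies(n_sites, total, rng)
    if band_freq is not None:
        centre = np.argsort(np.abs(positions - _LOCUS / 2))[:band_width]
        counts = counts.astype(np.int64)
        counts[centre] = rng.binomial(total, band_freq, size=centre.size).clip(1, total - 1)
    pooled = np.zeros((total, n_sites), dtype=np.uint8)
    for j, c in enumerate(counts):
        pooled[rng.choice(total, size=int(c), replace=False), j] = 1
    blocks = []
    row = 0
    for age, n in scheme:
        blocks.append((age, pooled[row : row + n].copy()))
        row += n
    return TemporalSample(
        blocks=blocks,
        positions=positions,
        focal_site_index=None,
        label=label,
        locus_length=_LOCUS,
        provenance={"seed": None, "attempts": 1},
    )


def make_fixture(
    kind: str,
    seed: int,
    n_per_class: int = 150,
    out_dir: Optional[object] = None,
) -> list[TemporalSample]:
    """Generate a fixture dataset; optionally write it to ``out_dir`` in the
    ms-style format plus metadata TSV."""
    if kind not in FIXTURE_KINDS:
        raise ConfigError(f"unknown fixture kind {kind!r}; expected {FIXTURE_KINDS}")
    rng = np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(FIXTURE_KINDS.index(kind),))
    )
    samples: list[TemporalSample] = []
    if kind == "tiny":
        for label in FIXTURE_CLASSES:
            for _ in range(2):
                samples.append(_one_sample(label, rng, n_sites=12))
    elif kind == "null":
        # identically distributed classes: labels assigned round-robin
        for i in range(3 * n_per_class):
            samples.append(_one_sample(FIXTURE_CLASSES[i % 3], rng))
    else:  # separable
        band = {"N": 0.08, "D0.25": 0.45, "D0.5": 0.85}
        for i in range(3 * n_per_class):
            label = FIXTURE_CLASSES[i % 3]
            samples.append(_one_sample(label, rng, band_freq=band[label]))
    if out_dir is not None:
        from .msio import write_ms_like

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_ms_like(
            samples, out_dir / "data.ms.txt", out_dir / "metadata.tsv"
        )
    return samples
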