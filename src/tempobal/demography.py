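"""Piecewise population-size histories.

A :class:`DemographicModel` is an ordered list of epochs, oldest first. Epoch
``start_time`` is the number of generations before present at which the epoch
begins (its oldest boundary); the epoch extends toward the present until the
next epoch starts. The oldest epoch also describes all time before its own
``start_time`` at its starting size (the ancestral population), so its
``growth_rate`` must be 0. Within an epoch the diploid size is

    N(t) = size * exp(growth_rate * (start_time - t))

for ``t`` generations before present, i.e. exponential change running forward
in time from the epoch boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ConfigError


@dataclass(frozen=True)
class Epoch:
    start_time: float  # generations before present at which the epoch begins
    size: float  # diploid size at start_time
    growth_rate: float = 0.0  # per-generation exponential rate (forward in time)


@dataclass(frozen=True)
class DemographicModel:
    epochs: tuple[Epoch, ...]
    generation_time: float = 25.0  # years per generation

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ConfigError("demography needs at least one epoch")
        starts = [e.start_time for e in self.epochs]
        if any(a <= b for a, b in zip(starts, starts[1:])):
            raise ConfigError("epoch start_times must strictly decrease toward present")
        if any(e.size < 2 for e in self.epochs):
            raise ConfigError("all epoch diploid sizes must be >= 2")
        if self.generation_time <= 0:
            raise ConfigError("generation_time must be > 0")
        if self.epochs[0].growth_rate != 0.0:
            raise ConfigError("the oldest (ancestral) epoch must have growth_rate 0")

    @property
    def ancestral_size(self) -> int:
        return max(2, round(self.epochs[0].size))

    def size_at(self, t: float) -> int:
        """Diploid population size ``t`` generations before present (t >= 0)."""
        epoch = self.epochs[0]
        for e in self.epochs:
            if e.start_time >= t:
                epoch = e
            else:
                break
        n = epoch.size * math.exp(epoch.growth_rate * (epoch.start_time - t)) \
            if epoch.start_time >= t else epoch.size
        return max(2, round(n))

    def history_start(self) -> float:
        """Oldest generation at which the size can differ from the ancestral size."""
        if len(self.epochs) == 1 and self.epochs[0].growth_rate == 0.0:
            return 0.0
        return self.epochs[1].start_time if len(self.epochs) > 1 else 0.0

    def rescaled(self, lam: float) -> "DemographicModel":
        """Divide sizes and times by ``lam``; generation_time is inflated so that
        conversions from years keep yielding the rescaled generation count."""
        epochs = tuple(
            Epoch(
                start_time=max(1.0, round(e.start_time / lam)),
                size=e.size / lam,
                growth_rate=e.growth_rate * lam,
            )
            for e in self.epochs
        )
        return DemographicModel(
            epochs=epochs, generation_time=self.generation_time * lam
        )


def constant_size(n: float, generation_time: float = 25.0) -> DemographicModel:
    return DemographicModel(
        epochs=(Epoch(start_time=1.0, size=n),), generation_time=generation_time
    )


def european_like(generation_time: float = 25.0) -> DemographicModel:
    """Bundled stand-in for a European-style history: ancestral size, an
    out-of-Africa-like bottleneck, then recent exponential growth.

    This is a documented placeholder with round numbers, not a reproduction of
    any published fitted model; all parameters are configurable.
    """
    growth = math.log(50_000 / 5_000) / 200  # ~1.15%/generation over 5 kyr
    return DemographicModel(
        epochs=(
            Epoch(start_time=5_000, size=10_000),
            Epoch(start_time=2_000, size=2_000),
            Epoch(start_time=400, size=5_000),
            Epoch(start_time=200, size=5_000, growth_rate=growth),
        ),
        generation_time=generation_time,
    )
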