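"""Run configuration: schema, validation, defaults and hashing.

A single structured file (YAML or JSON) drives the whole pipeline. The schema
is strict — unknown fields are rejected with their path — and the defaults
reproduce the full-scale study design: 50 kbp loci under a European-like
demography, an overdominant de novo variant at the locus centre arising 10k
years ago with s = 0.25% (weak) or 0.5% (moderate), 40 present-day haplotypes
plus 10 ancient haplotypes at 8k/4k/2k/1k years ago, a 64-filter 3x3/1x1
two-branch network, and the 10-repeat training protocol.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import demography as _demog
from .errors import ConfigError
from .network import NetworkSpec
from .simulate import BurnIn, SelectionModel, SimConfig, rescale_parameters
from .train_eval import TrainConfig

__all__ = [
    "RunConfig",
    "load_config",
    "config_hash",
    "sim_configs",
    "network_spec",
    "train_config",
    "bundled_config_path",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class EpochCfg(_Strict):
    start_time: float  # generations before present
    size: float
    growth_rate: float = 0.0


class DemographyCfg(_Strict):
    # Stand-in European-like history: ancestral size, out-of-Africa-style
    # bottleneck, recent exponential growth. Round numbers, fully configurable.
    epochs: list[EpochCfg] = Field(
        default_factory=lambda: [
            EpochCfg(start_time=e.start_time, size=e.size, growth_rate=e.growth_rate)
            for e in _demog.european_like().epochs
        ]
    )
    generation_time: float = 25.0  # years per generation

    def build(self) -> _demog.DemographicModel:
        return _demog.DemographicModel(
            epochs=tuple(
                _demog.Epoch(e.start_time, e.size, e.growth_rate) for e in self.epochs
            ),
            generation_time=self.generation_time,
        )


class ClassCfg(_Strict):
    name: str
    s: Optional[float] = None  # None -> neutral class (no focal variant)


class BurnInCfg(_Strict):
    mode: Literal["forward", "coalescent"] = "forward"
    factor: float = 10.0


class SimulationCfg(_Strict):
    locus_length: float = 50_000.0
    mu: float = 1.25e-8
    rho: float = 1.25e-8
    demography: DemographyCfg = Field(default_factory=DemographyCfg)
    selection_onset_time: float = 10_000.0  # years before present
    focal_position: Optional[float] = None  # None -> locus centre
    sampling_scheme: list[tuple[float, int]] = Field(
        default_factory=lambda: [
            (8000.0, 10),
            (4000.0, 10),
            (2000.0, 10),
            (1000.0, 10),
            (0.0, 40),
        ]
    )
    rescale_factor: float = 1.0
    burn_in: BurnInCfg = Field(default_factory=BurnInCfg)
    max_condition_attempts: int = 100


class DatasetCfg(_Strict):
    classes: list[ClassCfg] = Field(
        default_factory=lambda: [
            ClassCfg(name="N", s=None),
            ClassCfg(name="D0.25", s=0.0025),
            ClassCfg(name="D0.5", s=0.005),
        ]
    )
    n_per_class: int = 2000


class EncodingCfg(_Strict):
    width: int = 128  # SNP columns kept around the focal position


class NetworkCfg(_Strict):
    mode: Literal["both", "present_only", "ancient_only"] = "both"
    n_filters: int = 64
    kernel: tuple[int, int] = (3, 3)
    padding: tuple[int, int] = (1, 1)
    n_residual_blocks: int = 2
    dropout: float = 0.25
    exchangeable_present: bool = False


class TrainingCfg(_Strict):
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    batch_size: int = 32
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    max_epochs: int = 50
    patience: int = 10
    n_repeats: int = 10


class RunConfig(_Strict):
    simulation: SimulationCfg = Field(default_factory=SimulationCfg)
    dataset: DatasetCfg = Field(default_factory=DatasetCfg)
    encoding: EncodingCfg = Field(default_factory=EncodingCfg)
    network: NetworkCfg = Field(default_factory=NetworkCfg)
    training: TrainingCfg = Field(default_factory=TrainingCfg)
    seed: int = 0


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration; unknown or invalid
    fields raise :class:`ConfigError` naming the offending path."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    try:
        return RunConfig.model_validate(data)
    except ValidationError as exc:
        locs = "; ".join(
            ".".join(str(p) for p in err["loc"]) + ": " + err["msg"]
            for err in exc.errors()
        )
        raise ConfigError(f"invalid configuration ({locs})") from exc


def config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(cfg.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def sim_configs(cfg: RunConfig) -> list[SimConfig]:
    """One (rescaled) :class:`SimConfig` per class, in the configured order."""
    sim = cfg.simulation
    out = []
    for cls in cfg.dataset.classes:
        selection = (
            None
            if cls.s is None
            else SelectionModel(
                s=cls.s,
                onset_time=sim.selection_onset_time,
                focal_position=sim.focal_position,
            )
        )
        base = SimConfig(
            locus_length=sim.locus_length,
            mu=sim.mu,
            rho=sim.rho,
            demography=sim.demography.build(),
            selection=selection,
            sampling_scheme=tuple((a, n) for a, n in sim.sampling_scheme),
            burn_in=BurnIn(mode=sim.burn_in.mode, factor=sim.burn_in.factor),
            max_condition_attempts=sim.max_condition_attempts,
            label=cls.name,
        )
        out.append(rescale_parameters(base, sim.rescale_factor))
    return out


def network_spec(cfg: RunConfig, mode: Optional[str] = None, seed: int = 0) -> NetworkSpec:
    net = cfg.network
    return NetworkSpec(
        mode=mode or net.mode,
        n_filters=net.n_filters,
        kernel=tuple(net.kernel),
        padding=tuple(net.padding),
        n_residual_blocks=net.n_residual_blocks,
        dropout=net.dropout,
        exchangeable_present=net.exchangeable_present,
        seed=seed,
    )


def train_config(cfg: RunConfig, base_seed: Optional[int] = None) -> TrainConfig:
    tr = cfg.training
    return TrainConfig(
        fractions=tuple(tr.fractions),
        batch_size=tr.batch_size,
        learning_rate=tr.learning_rate,
        optimizer=tr.optimizer,
        max_epochs=tr.max_epochs,
        patience=tr.patience,
        n_repeats=tr.n_repeats,
        base_seed=cfg.seed if base_seed is None else base_seed,
    )


def bundled_config_path(name: str) -> Path:
    """Path of a configuration shipped with the package ('default' or
    'desk_scale')."""
    p = Path(__file__).parent / "configs" / f"{name}.yaml"
    if not p.exists():
        raise ConfigError(f"no bundled config named {name!r}")
    return p
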