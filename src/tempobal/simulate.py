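"""Forward-in-time Wright-Fisher simulation of a recombining locus under
overdominance, with serial (ancient + present-day) sampling.

The model: a diploid population of size N(t) given by a piecewise demography,
an L-bp locus with infinite-sites mutation (per-bp rate ``mu``) and Poisson
crossover recombination (per-bp rate ``rho``). Balancing selection is modelled
as symmetric heterozygote advantage at a single focal site: genotype fitnesses
1 : 1+s : 1 (ancestral homozygote, heterozygote, derived homozygote), so the
deterministic equilibrium frequency is 1/2. The focal variant arises de novo
on one haplotype at a configured onset time, and selected replicates are
conditioned on it still segregating in the present-day sample.

Haplotypes are 0/1 rows (0 = ancestral allele); the population is the full
2N x S matrix over currently tracked sites. Each generation: parents are drawn
proportionally to fitness, each offspring haplotype is a (possibly recombined)
gamete from one diploid parent, and new mutations fall as a Poisson rain on
random haplotypes at uniform positions.

Forward simulation at human scale is expensive, so configurations support the
standard rescaling by a factor lambda: population sizes and times shrink by
lambda while s, mu and rho grow by lambda, preserving N*s, N*mu*L, N*rho*L and
times in units of N generations.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .demography import DemographicModel, constant_size
from .errors import (
    ConditioningError,
    ConfigError,
    InvalidFitnessError,
    OverRescaledError,
)

__all__ = [
    "SelectionModel",
    "BurnIn",
    "SimConfig",
    "TemporalSample",
    "Population",
    "rescale_parameters",
    "deterministic_update",
    "evolve_generation",
    "simulate_locus",
    "simulate_dataset",
    "compute_summaries",
]


# ---------------------------------------------------------------------------
# configuration types


@dataclass(frozen=True)
class SelectionModel:
    """Symmetric overdominance at one focal site (fitnesses 1 : 1+s : 1)."""

    s: float  # heterozygote advantage
    onset_time: float  # years before present at which the variant arises
    focal_position: Optional[float] = None  # bp; None -> locus centre

    def __post_init__(self) -> None:
        if not 0.0 <= self.s < 1.0:
            raise InvalidFitnessError(f"selection coefficient s={self.s} outside [0, 1)")
        if self.onset_time <= 0:
            raise ConfigError("selection onset_time must be > 0")


@dataclass(frozen=True)
class BurnIn:
    """How the equilibrium ancestral population is produced.

    ``forward``: evolve a monomorphic population for ``factor * N_ancestral``
    neutral generations. ``coalescent``: draw the starting haplotypes from a
    coalescent simulation at the ancestral size (msprime), which is
    statistically equivalent at equilibrium and much cheaper.
    """

    mode: str = "forward"
    factor: float = 10.0

    def __post_init__(self) -> None:
        if self.mode not in ("forward", "coalescent"):
            raise ConfigError(f"unknown burn-in mode {self.mode!r}")
        if self.factor < 0:
            raise ConfigError("burn-in factor must be >= 0")


@dataclass(frozen=True)
class SimConfig:
    locus_length: float = 50_000.0  # bp
    mu: float = 1.25e-8  # mutations / bp / generation
    rho: float = 1.25e-8  # crossovers / bp / generation
    demography: DemographicModel = field(default_factory=lambda: constant_size(10_000))
    selection: Optional[SelectionModel] = None
    # (age in years before present, number of haplotypes); age 0 = present day
    sampling_scheme: tuple[tuple[float, int], ...] = ((0.0, 40),)
    rescale_factor: float = 1.0
    burn_in: BurnIn = field(default_factory=BurnIn)
    max_condition_attempts: int = 100
    label: Optional[str] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.locus_length <= 0:
            raise ConfigError("locus_length must be > 0")
        if self.mu < 0 or self.rho < 0:
            raise ConfigError("mu and rho must be >= 0")
        ages = [a for a, _ in self.sampling_scheme]
        if any(a < 0 for a in ages):
            raise ConfigError("sampling ages must be non-negative")
        if 0.0 not in ages:
            raise ConfigError("sampling_scheme must include age 0 (present day)")
        if any(n < 1 for _, n in self.sampling_scheme):
            raise ConfigError("each sampling block needs >= 1 haplotype")
        if self.rescale_factor < 1:
            raise ConfigError("rescale_factor must be >= 1")
        if self.max_condition_attempts < 1:
            raise ConfigError("max_condition_attempts must be >= 1")
        if self.selection is not None:
            fp = self.focal_position
            if not 0.0 <= fp <= self.locus_length:
                raise ConfigError("focal_position outside the locus")

    @property
    def focal_position(self) -> Optional[float]:
        if self.selection is None:
            return None
        fp = self.selection.focal_position
        return self.locus_length / 2.0 if fp is None else fp

    @property
    def class_label(self) -> str:
        if self.label is not None:
            return self.label
        if self.selection is None:
            return "N"
        return f"D{100.0 * self.selection.s:g}"

    def sample_generations(self) -> list[tuple[int, int]]:
        """Sampling ages converted to generations, sorted oldest first."""
        gt = self.demography.generation_time
        gens = [(round(age / gt), n) for age, n in self.sampling_scheme]
        return sorted(gens, key=lambda x: -x[0])

    def onset_generation(self) -> Optional[int]:
        if self.selection is None:
            return None
        return max(1, round(self.selection.onset_time / self.demography.generation_time))


# ---------------------------------------------------------------------------
# results


@dataclass
class TemporalSample:
    """Serially sampled haplotypes from one simulated locus.

    ``blocks`` is ordered oldest to youngest; every block shares the same
    columns: the sites segregating in the pooled sample (plus the focal site,
    which is always reported for selected replicates even if momentarily
    fixed at some sampling time).
    """

    blocks: list[tuple[float, np.ndarray]]  # (age_years, n x S uint8 matrix)
    positions: np.ndarray  # bp, strictly increasing
    focal_site_index: Optional[int]
    label: str
    locus_length: float
    provenance: dict = field(default_factory=dict)

    @property
    def ages(self) -> list[float]:
        return [age for age, _ in self.blocks]

    def block(self, age: float) -> np.ndarray:
        for a, m in self.blocks:
            if a == age:
                return m
        raise KeyError(f"no block sampled at age {age}")

    @property
    def n_sites(self) -> int:
        return int(self.positions.size)


# ---------------------------------------------------------------------------
# single-site deterministic dynamics (used as an oracle by the test-suite and
# for quick power calculations)


def deterministic_update(p: float, s: float) -> float:
    """Expected next-generation derived-allele frequency under symmetric
    overdominance: p' = (p^2 + p(1-p)(1+s)) / (1 + 2 p (1-p) s).

    Fixed points at 0, 1/2 and 1.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"allele frequency p={p} outside [0, 1]")
    if not 0.0 <= s < 1.0:
        raise ValueError(f"selection coefficient s={s} outside [0, 1)")
    q = 1.0 - p
    wbar = 1.0 + 2.0 * p * q * s
    return (p * p + p * q * (1.0 + s)) / wbar


# ---------------------------------------------------------------------------
# rescaling


def rescale_parameters(cfg: SimConfig, lam: float) -> SimConfig:
    """Apply the standard forward-simulation rescaling by ``lam`` >= 1.

    Sizes and generation counts shrink by ``lam``; s, mu and rho grow by
    ``lam``. Sampling/onset times are stored in years, so the conversion is
    carried by inflating the demography's generation_time, which leaves the
    compound parameters N*s, N*mu*L, N*rho*L and times in coalescent units
    unchanged.
    """
    if lam < 1:
        raise ConfigError(f"rescaling factor must be >= 1, got {lam}")
    if lam == 1:
        return cfg
    if any(e.size / lam < 2 for e in cfg.demography.epochs):
        raise OverRescaledError(
            f"rescaling by {lam} pushes a diploid epoch size below 2"
        )
    selection = cfg.selection
    if selection is not None:
        s_new = selection.s * lam
        if s_new >= 1.0:
            raise InvalidFitnessError(
                f"rescaled selection coefficient {s_new} >= 1 (s={selection.s}, lam={lam})"
            )
        selection = replace(selection, s=s_new)
    return replace(
        cfg,
        demography=cfg.demography.rescaled(lam),
        mu=cfg.mu * lam,
        rho=cfg.rho * lam,
        selection=selection,
        rescale_factor=cfg.rescale_factor * lam,
    )


# ---------------------------------------------------------------------------
# population state and one Wright-Fisher cycle


@dataclass
class Population:
    """2N haplotypes over the currently tracked sites.

    Diploid individual ``i`` consists of rows ``2i`` and ``2i+1``. Sites carry
    stable integer ids so that sampled blocks can be aligned after columns are
    pruned or appended.
    """

    haplotypes: np.ndarray  # (2N, S) uint8
    positions: np.ndarray  # (S,) float64, bp
    ids: np.ndarray  # (S,) int64
    focal_id: int = -1  # -1: no focal variant
    next_id: int = 0

    @classmethod
    def monomorphic(cls, n_diploid: int) -> "Population":
        return cls(
            haplotypes=np.zeros((2 * n_diploid, 0), dtype=np.uint8),
            positions=np.empty(0, dtype=np.float64),
            ids=np.empty(0, dtype=np.int64),
        )

    @property
    def n_diploid(self) -> int:
        return self.haplotypes.shape[0] // 2

    def focal_index(self) -> Optional[int]:
        if self.focal_id < 0:
            return None
        idx = np.nonzero(self.ids == self.focal_id)[0]
        return int(idx[0]) if idx.size else None

    def focal_frequency(self) -> Optional[float]:
        idx = self.focal_index()
        if idx is None:
            return None
        return float(self.haplotypes[:, idx].mean())

    def inject_focal(self, position: float, rng: np.random.Generator) -> None:
        """Place a de novo derived allele at ``position`` on one random haplotype."""
        col = np.zeros((self.haplotypes.shape[0], 1), dtype=np.uint8)
        col[rng.integers(0, self.haplotypes.shape[0])] = 1
        self.haplotypes = np.concatenate([self.haplotypes, col], axis=1)
        self.positions = np.append(self.positions, position)
        self.ids = np.append(self.ids, self.next_id)
        self.focal_id = self.next_id
        self.next_id += 1

    def prune(self, keep_fixed: bool = False) -> None:
        """Drop lost sites, and fixed sites unless ``keep_fixed``; the focal
        column is always retained once present."""
        if self.haplotypes.shape[1] == 0:
            return
        counts = self.haplotypes.sum(axis=0, dtype=np.int64)
        two_n = self.haplotypes.shape[0]
        keep = counts > 0 if keep_fixed else (counts > 0) & (counts < two_n)
        if self.focal_id >= 0:
            keep |= self.ids == self.focal_id
        if not keep.all():
            self.haplotypes = self.haplotypes[:, keep]
            self.positions = self.positions[keep]
            self.ids = self.ids[keep]

    def sample(self, n: int, rng: np.random.Generator) -> "SampledBlock":
        rows = rng.choice(self.haplotypes.shape[0], size=n, replace=False)
        return SampledBlock(
            haplotypes=self.haplotypes[rows].copy(),
            positions=self.positions.copy(),
            ids=self.ids.copy(),
        )

    def copy(self) -> "Population":
        return Population(
            haplotypes=self.haplotypes.copy(),
            positions=self.positions.copy(),
            ids=self.ids.copy(),
            focal_id=self.focal_id,
            next_id=self.next_id,
        )


@dataclass
class SampledBlock:
    haplotypes: np.ndarray
    positions: np.ndarray
    ids: np.ndarray


def evolve_generation(
    pop: Population,
    cfg: SimConfig,
    n_next: Optional[int] = None,
    *,
    selection_active: bool = False,
    rng: np.random.Generator,
) -> Population:
    """One Wright-Fisher cycle: fitness-proportional parent choice at the focal
    site (when selection is active), random mating, Poisson recombination and
    Poisson infinite-sites mutation. Returns a new Population of ``n_next``
    diploids (defaults to the current size)."""
    H = pop.haplotypes
    two_n = H.shape[0]
    n_par = two_n // 2
    if n_next is None:
        n_next = n_par
    n_gam = 2 * n_next
    L = cfg.locus_length

    s = cfg.selection.s if (selection_active and cfg.selection is not None) else 0.0
    focal = pop.focal_index()
    if s > 0.0 and focal is not None:
        col = H[:, focal].astype(np.int64)
        geno = col[0 : 2 * n_par : 2] + col[1 : 2 * n_par : 2]
        w = np.where(geno == 1, 1.0 + s, 1.0)
        parents = rng.choice(n_par, size=n_gam, p=w / w.sum())
    else:
        parents = rng.integers(0, n_par, size=n_gam)

    start = rng.integers(0, 2, size=n_gam)
    gametes = H[2 * parents + start]

    # recombination: most gametes carry no crossover at desk-scale rho*L
    if cfg.rho > 0.0 and H.shape[1] > 0:
        n_x = rng.poisson(cfg.rho * L, size=n_gam)
        for i in np.nonzero(n_x)[0]:
            a = H[2 * parents[i] + start[i]]
            b = H[2 * parents[i] + 1 - start[i]]
            breaks = np.sort(rng.uniform(0.0, L, size=n_x[i]))
            seg = np.searchsorted(breaks, pop.positions, side="right")
            gametes[i] = np.where(seg % 2 == 1, b, a)

    positions = pop.positions
    ids = pop.ids
    next_id = pop.next_id
    if cfg.mu > 0.0:
        m = rng.poisson(cfg.mu * L * n_gam)
        if m > 0:
            new_cols = np.zeros((n_gam, m), dtype=np.uint8)
            new_cols[rng.integers(0, n_gam, size=m), np.arange(m)] = 1
            gametes = np.concatenate([gametes, new_cols], axis=1)
            positions = np.concatenate([positions, rng.uniform(0.0, L, size=m)])
            ids = np.concatenate([ids, np.arange(next_id, next_id + m)])
            next_id += m

    return Population(
        haplotypes=gametes,
        positions=positions,
        ids=ids,
        focal_id=pop.focal_id,
        next_id=next_id,
    )


# ---------------------------------------------------------------------------
# whole-locus simulation


def _coalescent_init(cfg: SimConfig, n_diploid: int, rng: np.random.Generator) -> Population:
    import msprime

    seed = int(rng.integers(1, 2**31 - 1))
    ts = msprime.sim_ancestry(
        samples=n_diploid,
        population_size=cfg.demography.ancestral_size,
        sequence_length=cfg.locus_length,
        recombination_rate=cfg.rho,
        discrete_genome=False,
        random_seed=seed,
    )
    ts = msprime.sim_mutations(
        ts,
        rate=cfg.mu,
        model=msprime.BinaryMutationModel(),
        discrete_genome=False,
        random_seed=seed + 1,
    )
    H = ts.genotype_matrix().T.astype(np.uint8)
    positions = ts.sites_position.astype(np.float64)
    order = np.argsort(positions, kind="stable")
    return Population(
        haplotypes=np.ascontiguousarray(H[:, order]),
        positions=positions[order],
        ids=np.arange(order.size, dtype=np.int64),
        next_id=int(order.size),
    )


def _forward_burn_in(cfg: SimConfig, n_diploid: int, rng: np.random.Generator) -> Population:
    pop = Population.monomorphic(n_diploid)
    n_gen = round(cfg.burn_in.factor * n_diploid)
    for _ in range(n_gen):
        pop = evolve_generation(pop, cfg, n_diploid, rng=rng)
        pop.prune()
    return pop


def _assemble(
    cfg: SimConfig,
    blocks: list[tuple[float, SampledBlock]],
    focal_id: int,
    attempts: int,
    seed,
) -> TemporalSample:
    """Align sampled blocks on the union of sites segregating in the pooled
    sample (plus the focal site) and order columns by position."""
    blocks = sorted(blocks, key=lambda x: -x[0])
    total_rows = sum(b.haplotypes.shape[0] for _, b in blocks)
    counts: dict[int, int] = {}
    pos_of: dict[int, float] = {}
    for _, b in blocks:
        if b.ids.size == 0:
            continue
        colsum = b.haplotypes.sum(axis=0, dtype=np.int64)
        for i, c, p in zip(b.ids.tolist(), colsum.tolist(), b.positions.tolist()):
            counts[i] = counts.get(i, 0) + c
            pos_of.setdefault(i, p)
    keep = [i for i, c in counts.items() if 0 < c < total_rows]
    if focal_id >= 0 and focal_id in pos_of and focal_id not in keep:
        keep.append(focal_id)
    keep_ids = np.array(sorted(keep, key=lambda i: (pos_of[i], i)), dtype=np.int64)
    positions = np.array([pos_of[i] for i in keep_ids], dtype=np.float64)
    col_of = {i: j for j, i in enumerate(keep_ids.tolist())}

    out_blocks: list[tuple[float, np.ndarray]] = []
    for age, b in blocks:
        mat = np.zeros((b.haplotypes.shape[0], keep_ids.size), dtype=np.uint8)
        if b.ids.size:
            src = [k for k, i in enumerate(b.ids.tolist()) if i in col_of]
            dst = [col_of[b.ids[k]] for k in src]
            if src:
                mat[:, dst] = b.haplotypes[:, src]
        out_blocks.append((age, mat))

    focal_index = col_of.get(focal_id) if focal_id >= 0 else None
    return TemporalSample(
        blocks=out_blocks,
        positions=positions,
        focal_site_index=focal_index,
        label=cfg.class_label,
        locus_length=cfg.locus_length,
        provenance={"seed": seed, "attempts": attempts},
    )


def _descend(pop, cfg, t_from, t_to, rng, blocks, gens, selection_active):
    """Evolve from the population at generation ``t_from + 1`` down to ``t_to``
    inclusive, drawing the scheduled samples in ``gens`` as each generation is
    created. Fixed sites are retained once any block has been collected."""
    demog = cfg.demography
    for t in range(t_from, t_to - 1, -1):
        pop = evolve_generation(
            pop, cfg, demog.size_at(t), selection_active=selection_active, rng=rng
        )
        for g, n in gens:
            if g == t:
                blocks.append((g, pop.sample(n, rng)))
        pop.prune(keep_fixed=len(blocks) > 0)
    return pop


def simulate_locus(cfg: SimConfig, seed=None) -> TemporalSample:
    """Simulate one locus end-to-end and return the serial sample.

    The run is seeded from ``seed`` (or ``cfg.seed``); identical (config, seed)
    pairs reproduce bit-identical output. For selected configurations the
    focal variant is injected at the onset generation and the replicate is
    conditioned on it segregating (frequency strictly in (0,1)) in the
    present-day sample; failed attempts restart from the cached pre-onset
    state, up to ``cfg.max_condition_attempts``.
    """
    if seed is None:
        seed = cfg.seed
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    ss_init, ss_descent, ss_attempts = ss.spawn(3)

    demog = cfg.demography
    sample_gens = cfg.sample_generations()
    if len({g for g, _ in sample_gens}) != len(sample_gens):
        raise ConfigError(
            "sampling ages collide after conversion to generations; "
            "reduce the rescaling factor or merge the blocks"
        )
    oldest_sample = sample_gens[0][0]
    onset = cfg.onset_generation()
    t0 = max(int(demog.history_start()), oldest_sample, onset or 0, 1)

    rng_init = np.random.default_rng(ss_init)
    n_anc = demog.ancestral_size
    if cfg.burn_in.mode == "coalescent":
        pop = _coalescent_init(cfg, n_anc, rng_init)
    else:
        pop = _forward_burn_in(cfg, n_anc, rng_init)

    rng_descent = np.random.default_rng(ss_descent)
    blocks_pre: list[tuple[int, SampledBlock]] = []

    if onset is None:
        # neutral class: single unconditioned pass to the present
        for g, n in sample_gens:
            if g == t0:
                blocks_pre.append((g, pop.sample(n, rng_descent)))
        _descend(pop, cfg, t0 - 1, 0, rng_descent, blocks_pre, sample_gens, False)
        return _assemble(cfg, _to_years(blocks_pre, cfg), -1, 1, _seed_info(ss))

    # selected (or conditioned-neutral, s=0) class: neutral pre-onset phase,
    # then repeatable onset-to-present attempts from the cached state
    gens_pre = [(g, n) for g, n in sample_gens if g > onset]
    gens_post = [(g, n) for g, n in sample_gens if g < onset]
    gens_onset = [(g, n) for g, n in sample_gens if g == onset]
    for g, n in gens_pre:
        if g == t0:
            blocks_pre.append((g, pop.sample(n, rng_descent)))
    if t0 > onset:
        pop = _descend(pop, cfg, t0 - 1, onset, rng_descent, blocks_pre, gens_pre, False)
    base = pop  # population at the onset generation, before the focal mutation

    for attempt in range(1, cfg.max_condition_attempts + 1):
        rng_a = np.random.default_rng(ss_attempts.spawn(1)[0])
        pop = base.copy()
        pop.inject_focal(cfg.focal_position, rng_a)
        blocks = list(blocks_pre)
        for g, n in gens_onset:
            blocks.append((g, pop.sample(n, rng_a)))
        pop = _descend(pop, cfg, onset - 1, 0, rng_a, blocks, gens_post, True)
        present = next(b for g, b in blocks if g == 0)
        fi = np.nonzero(present.ids == pop.focal_id)[0]
        freq = float(present.haplotypes[:, fi[0]].mean()) if fi.size else 0.0
        if 0.0 < freq < 1.0:
            return _assemble(
                cfg, _to_years(blocks, cfg), pop.focal_id, attempt, _seed_info(ss)
            )
    raise ConditioningError(cfg.max_condition_attempts)


def _seed_info(ss: np.random.SeedSequence) -> dict:
    return {
        "entropy": int(ss.entropy) if ss.entropy is not None else None,
        "spawn_key": [int(k) for k in ss.spawn_key],
    }


def _to_years(blocks, cfg):
    """Map sampled generations back to the configured ages in years."""
    gt = cfg.demography.generation_time
    gen_to_age = {round(age / gt): age for age, _n in cfg.sampling_scheme}
    return [(gen_to_age[g], b) for g, b in blocks]


def simulate_dataset(
    configs: Sequence[SimConfig],
    n_per_class: int,
    base_seed: int,
    progress: bool = False,
) -> list[TemporalSample]:
    """Simulate ``n_per_class`` replicates for each class configuration.

    Every replicate draws its own independent stream from the single base
    seed via ``SeedSequence(base_seed, spawn_key=(class_index, replicate))``.
    """
    samples: list[TemporalSample] = []
    for ci, cfg in enumerate(configs):
        for ri in range(n_per_class):
            ss = np.random.SeedSequence(base_seed, spawn_key=(ci, ri))
            samples.append(simulate_locus(cfg, seed=ss))
    return samples


# ---------------------------------------------------------------------------
# diagnostics


def compute_summaries(sample: TemporalSample, age: float):
    """(segregating sites, mean pairwise difference, focal frequency) for the
    block sampled at ``age``; focal frequency is None for neutral samples."""
    M = sample.block(age)  # KeyError for unknown age
    n = M.shape[0]
    counts = M.sum(axis=0, dtype=np.int64)
    seg = int(((counts > 0) & (counts < n)).sum())
    if n < 2:
        pi = 0.0
    else:
        pi = float((counts * (n - counts)).sum() / (n * (n - 1) / 2))
    freq = None
    if sample.focal_site_index is not None:
        freq = float(M[:, sample.focal_site_index].mean())
    return seg, pi, freq
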