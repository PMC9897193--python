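"""Unit and property tests of the Wright-Fisher simulator."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tempobal.demography import DemographicModel, Epoch, constant_size
from tempobal.errors import (
    ConditioningError,
    ConfigError,
    InvalidFitnessError,
    OverRescaledError,
)
from tempobal.simulate import (
    BurnIn,
    Population,
    SelectionModel,
    SimConfig,
    compute_summaries,
    deterministic_update,
    evolve_generation,
    rescale_parameters,
    simulate_locus,
)

from conftest import small_sim_config


# ---------------------------------------------------------------------------
# deterministic single-site dynamics


class TestDeterministicUpdate:
    def test_matches_mean_fitness_oracle(self):
        # independent computation from genotype fitnesses 1 : 1+s : 1
        p, s = 0.1, 0.5
        w_dd, w_dh, w_aa = 1.0, 1.0 + s, 1.0
        q = 1 - p
        wbar = p * p * w_dd + 2 * p * q * w_dh + q * q * w_aa
        expected = (p * p * w_dd + p * q * w_dh) / wbar
        assert expected == pytest.approx(0.13303, abs=1e-5)
        assert deterministic_update(p, s) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("p", [0.0, 0.5, 1.0])
    def test_fixed_points(self, p):
        for s in (0.0, 0.1, 0.9):
            assert deterministic_update(p, s) == pytest.approx(p, abs=1e-15)

    @given(st.floats(0, 1), st.floats(0, 0.99))
    def test_stays_in_unit_interval_and_moves_toward_half(self, p, s):
        p2 = deterministic_update(p, s)
        assert 0.0 <= p2 <= 1.0
        # overdominance pushes frequencies toward the 1/2 equilibrium
        assert abs(p2 - 0.5) <= abs(p - 0.5) + 1e-12

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            deterministic_update(1.2, 0.1)
        with pytest.raises(ValueError):
            deterministic_update(0.5, 1.0)


# ---------------------------------------------------------------------------
# rescaling


class TestRescaling:
    def base(self):
        return SimConfig(
            mu=1.25e-8,
            rho=1.25e-8,
            demography=DemographicModel(
                epochs=(Epoch(400.0, 10_000.0),), generation_time=25.0
            ),
            selection=SelectionModel(s=0.005, onset_time=10_000.0),
        )

    def test_identity(self):
        cfg = self.base()
        assert rescale_parameters(cfg, 1) is cfg

    def test_arithmetic(self):
        out = rescale_parameters(self.base(), 10)
        assert out.demography.epochs[0].size == pytest.approx(1_000)
        assert out.demography.epochs[0].start_time == pytest.approx(40)
        assert out.selection.s == pytest.approx(0.05)
        assert out.mu == pytest.approx(1.25e-7)
        assert out.rho == pytest.approx(1.25e-7)
        # onset expressed in generations: 10000 yr / (25 yr * 10) = 40
        assert out.onset_generation() == 40

    def test_compound_parameters_preserved(self):
        cfg = self.base()
        out = rescale_parameters(cfg, 8)
        n0, n1 = cfg.demography.epochs[0].size, out.demography.epochs[0].size
        assert n1 * out.selection.s == pytest.approx(n0 * cfg.selection.s)
        assert n1 * out.mu == pytest.approx(n0 * cfg.mu)
        assert n1 * out.rho == pytest.approx(n0 * cfg.rho)
        # times in units of N generations
        assert out.onset_generation() / n1 == pytest.approx(
            cfg.onset_generation() / n0
        )

    def test_invalid_fitness(self):
        cfg = SimConfig(selection=SelectionModel(s=0.5, onset_time=1000.0))
        with pytest.raises(InvalidFitnessError):
            rescale_parameters(cfg, 10)

    def test_over_rescaled(self):
        cfg = SimConfig(demography=constant_size(10))
        with pytest.raises(OverRescaledError):
            rescale_parameters(cfg, 8)


# ---------------------------------------------------------------------------
# one Wright-Fisher cycle


def _single_site_population(two_n: int, p: float) -> Population:
    col = np.zeros((two_n, 1), dtype=np.uint8)
    col[: round(p * two_n)] = 1
    rng = np.random.default_rng(0)
    rng.shuffle(col)
    return Population(
        haplotypes=col,
        positions=np.array([25_000.0]),
        ids=np.array([0], dtype=np.int64),
        focal_id=0,
        next_id=1,
    )


class TestEvolveGeneration:
    def test_neutral_drift_is_unbiased(self):
        # binomial-resampling oracle: mean frequency change 0 within 3 SE
        cfg = SimConfig(mu=0.0, rho=0.0, demography=constant_size(100))
        pop = _single_site_population(200, 0.3)
        rng = np.random.default_rng(42)
        deltas = []
        for _ in range(2000):
            nxt = evolve_generation(pop, cfg, rng=rng)
            deltas.append(nxt.haplotypes.mean() - 0.3)
        se = np.std(deltas, ddof=1) / np.sqrt(len(deltas))
        assert abs(np.mean(deltas)) < 3 * se

    def test_selection_matches_deterministic_oracle_at_large_n(self):
        n = 50_000
        p, s = 0.1, 0.05
        cfg = SimConfig(
            mu=0.0,
            rho=0.0,
            demography=constant_size(n),
            selection=SelectionModel(s=s, onset_time=1000.0),
        )
        pop = _single_site_population(2 * n, p)
        expected = deterministic_update(p, s) - p
        rng = np.random.default_rng(7)
        deltas = [
            evolve_generation(pop, cfg, selection_active=True, rng=rng).haplotypes.mean() - p
            for _ in range(200)
        ]
        se = np.std(deltas, ddof=1) / np.sqrt(len(deltas))
        assert np.mean(deltas) == pytest.approx(expected, abs=3 * se)

    def test_monomorphic_stays_monomorphic_without_mutation(self):
        cfg = SimConfig(mu=0.0, rho=1e-7, demography=constant_size(50))
        pop = Population.monomorphic(50)
        rng = np.random.default_rng(3)
        for _ in range(20):
            pop = evolve_generation(pop, cfg, rng=rng)
        assert pop.haplotypes.shape == (100, 0)

    def test_demographic_resize(self):
        cfg = SimConfig(mu=0.0, demography=constant_size(50))
        pop = Population.monomorphic(50)
        nxt = evolve_generation(pop, cfg, n_next=80, rng=np.random.default_rng(0))
        assert nxt.haplotypes.shape[0] == 160


# ---------------------------------------------------------------------------
# whole-locus simulation


class TestSimulateLocus:
    def test_serial_design_block_shapes(self, selected_sample):
        ages = [age for age, _ in selected_sample.blocks]
        rows = [M.shape[0] for _, M in selected_sample.blocks]
        assert ages == [600.0, 300.0, 150.0, 75.0, 0.0]
        assert rows == [10, 10, 10, 10, 40]
        widths = {M.shape[1] for _, M in selected_sample.blocks}
        assert widths == {selected_sample.n_sites}
        assert np.all(np.diff(selected_sample.positions) > 0)
        assert selected_sample.positions.min() >= 0
        assert selected_sample.positions.max() <= selected_sample.locus_length

    def test_no_mutation_means_no_sites(self):
        cfg = small_sim_config(mu=0.0, selection=None, burn_in=BurnIn("forward", 1.0))
        sample = simulate_locus(cfg, seed=1)
        assert sample.n_sites == 0
        assert all(M.shape == (n, 0) for (_, M), n in zip(sample.blocks, (10,) * 4 + (40,)))

    def test_bit_identical_reproducibility(self):
        cfg = small_sim_config()
        a = simulate_locus(cfg, seed=5)
        b = simulate_locus(cfg, seed=5)
        assert np.array_equal(a.positions, b.positions)
        for (age_a, m_a), (age_b, m_b) in zip(a.blocks, b.blocks):
            assert age_a == age_b and np.array_equal(m_a, m_b)
        assert a.focal_site_index == b.focal_site_index
        assert a.provenance == b.provenance

    def test_conditioning_keeps_focal_segregating(self, selected_sample):
        present = selected_sample.block(0.0)
        freq = present[:, selected_sample.focal_site_index].mean()
        assert 0.0 < freq < 1.0

    def test_conditioning_failure_raises(self):
        cfg = small_sim_config(
            mu=0.0,
            demography=constant_size(30),
            selection=SelectionModel(s=0.0, onset_time=2500.0),  # 100 generations
            sampling_scheme=((0.0, 20),),
            burn_in=BurnIn("forward", 0.0),
            max_condition_attempts=2,
        )
        with pytest.raises(ConditioningError) as err:
            simulate_locus(cfg, seed=0)
        assert err.value.attempts == 2

    def test_selection_pushes_focal_toward_equilibrium(self):
        """Conditioned overdominant runs sit nearer 1/2 than conditioned-neutral
        de novo alleles of the same age."""
        sel, neu = [], []
        for i in range(25):
            s_sel = simulate_locus(small_sim_config(), seed=np.random.SeedSequence(100, spawn_key=(i,)))
            cfg_n = small_sim_config(
                selection=SelectionModel(s=0.0, onset_time=750.0)
            )
            s_neu = simulate_locus(cfg_n, seed=np.random.SeedSequence(200, spawn_key=(i,)))
            sel.append(compute_summaries(s_sel, 0.0)[2])
            neu.append(compute_summaries(s_neu, 0.0)[2])
        assert abs(np.mean(sel) - 0.5) < abs(np.mean(neu) - 0.5)

    def test_label_assignment(self, selected_sample, neutral_sample):
        assert selected_sample.label == "D30"
        assert neutral_sample.label == "N"


class TestComputeSummaries:
    def test_identical_haplotypes(self):
        sample = _toy_sample(np.zeros((4, 3), dtype=np.uint8))
        assert compute_summaries(sample, 0.0) == (0, 0.0, None)

    def test_single_pair(self):
        m = np.array([[1, 0, 1], [0, 1, 0]], dtype=np.uint8)
        assert compute_summaries(_toy_sample(m), 0.0)[1] == pytest.approx(3.0)

    def test_focal_frequency(self):
        m = np.zeros((40, 1), dtype=np.uint8)
        m[:12, 0] = 1
        sample = _toy_sample(m, focal=0)
        assert compute_summaries(sample, 0.0)[2] == pytest.approx(0.3)

    def test_unknown_age(self, neutral_sample):
        with pytest.raises(KeyError):
            compute_summaries(neutral_sample, 123.0)


def _toy_sample(matrix, focal=None):
    from tempobal.simulate import TemporalSample

    return TemporalSample(
        blocks=[(0.0, matrix)],
        positions=np.linspace(1, 2, matrix.shape[1]),
        focal_site_index=focal,
        label="N",
        locus_length=50_000.0,
    )


# ---------------------------------------------------------------------------
# configuration invariants


class TestConfigValidation:
    def test_sampling_scheme_requires_present_day(self):
        with pytest.raises(ConfigError):
            SimConfig(sampling_scheme=((1000.0, 10),))

    def test_selection_bounds(self):
        with pytest.raises(InvalidFitnessError):
            SelectionModel(s=1.0, onset_time=100.0)
        with pytest.raises(ConfigError):
            SelectionModel(s=0.1, onset_time=-5.0)

    def test_epoch_ordering_enforced(self):
        with pytest.raises(ConfigError):
            DemographicModel(epochs=(Epoch(10.0, 100.0), Epoch(20.0, 100.0)))
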