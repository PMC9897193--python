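"""Two-branch network: construction, prediction contracts, invariances."""

import numpy as np
import pytest

from tempobal._nn import Adam
from tempobal.encode import build_feature_tensor, encode_samples
from tempobal.errors import ConfigError
from tempobal.network import NetworkSpec, build_network, predict


def _random_batch(rng, b=6, w=16):
    present = (rng.random((b, 40, w)) < 0.3).astype(np.uint8)
    ancient = (rng.random((b, 4, 10, w)) < 0.3).astype(np.uint8)
    return present, ancient


SMALL = dict(n_filters=8, n_residual_blocks=1, dropout=0.0)


class TestBuildNetwork:
    def test_seeded_initialisation_is_identical(self):
        m1 = build_network(NetworkSpec(seed=9, **SMALL))
        m2 = build_network(NetworkSpec(seed=9, **SMALL))
        for a, b in zip(m1.get_weights(), m2.get_weights()):
            assert np.array_equal(a, b)

    def test_modes_construct_expected_branches(self):
        both = build_network(NetworkSpec(mode="both", **SMALL))
        po = build_network(NetworkSpec(mode="present_only", **SMALL))
        ao = build_network(NetworkSpec(mode="ancient_only", **SMALL))
        assert both.present_branch and both.ancient_branch
        assert po.present_branch and po.ancient_branch is None
        assert ao.ancient_branch and ao.present_branch is None
        assert both.spec.embedding_dim == 16
        assert po.spec.embedding_dim == 8

    def test_invalid_mode_rejected(self):
        with pytest.raises(ConfigError):
            NetworkSpec(mode="nonsense")

    def test_padding_must_match_kernel(self):
        with pytest.raises(ConfigError):
            NetworkSpec(kernel=(3, 3), padding=(2, 2))


class TestPredict:
    def test_probabilities_normalised(self):
        rng = np.random.default_rng(0)
        present, ancient = _random_batch(rng)
        model = build_network(NetworkSpec(seed=1, **SMALL))
        proba = model.predict_proba(present, ancient)
        assert proba.shape == (6, 3)
        assert np.all(proba >= 0)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-6)

    def test_ancient_only_ignores_present_matrix(self):
        rng = np.random.default_rng(1)
        present, ancient = _random_batch(rng)
        model = build_network(NetworkSpec(mode="ancient_only", seed=2, **SMALL))
        p1 = model.predict_proba(present, ancient)
        p2 = model.predict_proba(rng.permutation(present.ravel()).reshape(present.shape), ancient)
        assert np.array_equal(p1, p2)

    def test_end_to_end_haplotype_permutation_invariance(self, selected_sample):
        """Shuffling raw haplotype rows leaves predictions bit-identical, for
        every mode, because encoding canonicalises row order."""
        from tempobal.simulate import TemporalSample

        rng = np.random.default_rng(3)
        shuffled = TemporalSample(
            blocks=[(a, M[rng.permutation(M.shape[0])]) for a, M in selected_sample.blocks],
            positions=selected_sample.positions,
            focal_site_index=selected_sample.focal_site_index,
            label=selected_sample.label,
            locus_length=selected_sample.locus_length,
        )
        for mode in ("both", "present_only", "ancient_only"):
            model = build_network(NetworkSpec(mode=mode, seed=4, **SMALL))
            pa = predict(model, build_feature_tensor(selected_sample, 16))
            pb = predict(model, build_feature_tensor(shuffled, 16))
            assert np.array_equal(pa, pb)

    def test_fresh_initialisations_average_to_uniform(self):
        rng = np.random.default_rng(5)
        present, ancient = _random_batch(rng, b=12)
        mean_proba = np.zeros(3)
        n_init = 50
        for seed in range(n_init):
            model = build_network(NetworkSpec(seed=seed, **SMALL))
            mean_proba += model.predict_proba(present, ancient).mean(axis=0)
        mean_proba /= n_init
        assert np.allclose(mean_proba, 1 / 3, atol=0.05)

    def test_shape_mismatch_raises(self):
        model = build_network(NetworkSpec(seed=0, **SMALL), n_ancient_channels=4)
        rng = np.random.default_rng(6)
        present, ancient = _random_batch(rng)
        with pytest.raises(ValueError):
            model.predict_proba(present, ancient[:, :3])


class TestStructure:
    def test_zero_masked_ancient_embedding_equals_head_on_present_only(self):
        """Silencing consistency: the dense head applied to (present embedding,
        zeros) equals the full model with the ancient embedding zeroed."""
        rng = np.random.default_rng(7)
        present, ancient = _random_batch(rng)
        model = build_network(NetworkSpec(seed=8, **SMALL))
        emb = model.embeddings(present, ancient)
        masked = emb.copy()
        masked[:, model.spec.n_filters :] = 0.0
        out_masked = model.head_forward(masked)
        pres_emb = model.present_branch.forward(
            np.asarray(present, dtype=np.float32)[..., None]
        )
        rebuilt = np.concatenate([pres_emb, np.zeros_like(pres_emb)], axis=1)
        assert np.array_equal(out_masked, model.head_forward(rebuilt))

    def test_exchangeable_present_variant_never_mixes_rows(self):
        """With row-shared 1-D kernels the present branch commutes with row
        permutations even without canonical sorting."""
        rng = np.random.default_rng(8)
        present, ancient = _random_batch(rng)
        model = build_network(
            NetworkSpec(
                mode="present_only",
                kernel=(1, 3),
                padding=(0, 1),
                exchangeable_present=True,
                seed=9,
                **SMALL,
            )
        )
        p1 = model.predict_proba(present, None)
        p2 = model.predict_proba(present[:, rng.permutation(40)], None)
        assert np.allclose(p1, p2, atol=1e-6)

    def test_overfit_capacity_on_twenty_samples(self, selected_sample, neutral_sample):
        """The model can memorise a 20-sample, 3-class training set."""
        from tempobal.train_eval import TrainConfig, train_model

        rng = np.random.default_rng(10)
        samples = []
        for i in range(20):
            base = selected_sample if i % 2 else neutral_sample
            # jitter rows to make samples distinct, label cyclically
            blocks = [
                (a, M[rng.permutation(M.shape[0])][: M.shape[0]])
                for a, M in base.blocks
            ]
            from tempobal.simulate import TemporalSample

            samples.append(
                TemporalSample(
                    blocks=[(a, (M ^ (rng.random(M.shape) < 0.05)).astype(np.uint8)) for a, M in blocks],
                    positions=base.positions,
                    focal_site_index=base.focal_site_index,
                    label=["N", "D0.25", "D0.5"][i % 3],
                    locus_length=base.locus_length,
                )
            )
        ds = encode_samples(samples, 16, ["N", "D0.25", "D0.5"])
        cfg = TrainConfig(
            batch_size=10,
            learning_rate=3e-3,
            max_epochs=120,
            patience=120,
            n_repeats=1,
            base_seed=0,
        )
        spec = NetworkSpec(n_filters=8, n_residual_blocks=1, dropout=0.0, seed=0)
        model, history = train_model(spec, cfg, {"train": ds, "val": ds}, seed=0)
        assert max(history["train_acc"]) == 1.0
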