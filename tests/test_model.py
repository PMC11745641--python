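"""Model core: gated-attention arithmetic against a hand oracle, fusion
layout, permutation invariance, dropout semantics, gradient correctness and
checkpoint round-trips."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pathomil.losses import LossWeights
from pathomil.model import (
    FusionMILModel,
    ModelConfig,
    OmicsStandardizer,
    fuse,
    gated_attention,
)
from pathomil.training import batch_loss_and_grads
from pathomil.types import FeatureBag, OmicsSchema, OmicsVector


def _bag(features):
    features = np.asarray(features, dtype=float)
    coords = np.zeros((features.shape[0], 2), dtype=int)
    return FeatureBag(sample_id="b", features=features, coords=coords)


class TestGatedAttention:
    def test_single_patch_weight_one(self):
        rng = np.random.default_rng(0)
        V, U, w = rng.normal(size=(4, 3)), rng.normal(size=(4, 3)), rng.normal(size=4)
        profile, pooled = gated_attention(_bag([[1.0, -2.0, 0.5]]), V, U, w)
        assert profile.weights.tolist() == [1.0]
        assert np.allclose(pooled, [1.0, -2.0, 0.5])

    def test_identical_patches_uniform_weights(self):
        rng = np.random.default_rng(1)
        V, U, w = rng.normal(size=(4, 3)), rng.normal(size=(4, 3)), rng.normal(size=4)
        h = np.tile([0.3, -1.0, 2.0], (5, 1))
        profile, pooled = gated_attention(_bag(h), V, U, w)
        assert np.allclose(profile.weights, 0.2)
        assert np.allclose(pooled, h[0])

    def test_hand_computed_two_patch_case(self):
        # K=2, d=2, h_dim=2, every parameter entry 0.5; oracle is plain
        # scalar arithmetic of a_k = w . (tanh(V h_k) * sigmoid(U h_k))
        V = np.full((2, 2), 0.5)
        U = np.full((2, 2), 0.5)
        w = np.full(2, 0.5)
        h1, h2 = (1.0, 0.0), (0.25, -0.5)

        def raw(h):
            pre = 0.5 * h[0] + 0.5 * h[1]  # same for both hidden units
            gate = math.tanh(pre) * (1.0 / (1.0 + math.exp(-pre)))
            return 0.5 * gate + 0.5 * gate

        a1, a2 = raw(h1), raw(h2)
        z = math.exp(a1) + math.exp(a2)
        expected = (math.exp(a1) / z, math.exp(a2) / z)

        profile, pooled = gated_attention(_bag([h1, h2]), V, U, w)
        assert profile.weights == pytest.approx(expected, abs=1e-12)
        exp_pooled = np.outer(expected, np.ones(2)) * np.array([h1, h2])
        assert np.allclose(pooled, exp_pooled.sum(axis=0))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            gated_attention(_bag([[1.0, 2.0]]), np.zeros((3, 5)), np.zeros((3, 5)), np.zeros(3))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=1, max_value=9), st.integers(min_value=0, max_value=10_000))
    def test_weights_normalize_and_shift_invariant(self, k, seed):
        rng = np.random.default_rng(seed)
        V, U, w = rng.normal(size=(3, 4)), rng.normal(size=(3, 4)), rng.normal(size=3)
        h = rng.normal(size=(k, 4))
        profile, _ = gated_attention(_bag(h), V, U, w)
        assert profile.weights.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.all(profile.weights >= 0)
        # adding a constant to all raw scores leaves the softmax unchanged
        shifted = np.exp(profile.raw_scores + 3.7)
        assert np.allclose(shifted / shifted.sum(), profile.weights)


class TestFuse:
    def test_paper_scale_fusion_width(self):
        schema = OmicsSchema(n_mrna=1004, n_mutations=22, n_immune=64, n_clinical=0)
        omics = OmicsVector(
            mrna=np.zeros(1004), mutations=np.zeros(22), immune=np.zeros(64)
        )
        fused = fuse(np.zeros(512), omics, schema)
        assert fused.size == 1602

    def test_pooled_passes_through_exactly(self):
        schema = OmicsSchema(n_mrna=3, n_mutations=2, n_immune=2, n_clinical=0)
        pooled = np.array([1.5, -2.0])
        omics = OmicsVector(mrna=np.zeros(3), mutations=np.zeros(2), immune=np.zeros(2))
        fused = fuse(pooled, omics, schema)
        assert np.array_equal(fused[:2], pooled)

    def test_clinical_block_width_accounted(self):
        base = OmicsSchema(n_mrna=3, n_mutations=2, n_immune=2, n_clinical=0)
        with_clin = OmicsSchema(n_mrna=3, n_mutations=2, n_immune=2, n_clinical=4)
        o_base = OmicsVector(mrna=np.zeros(3), mutations=np.zeros(2), immune=np.zeros(2))
        o_clin = OmicsVector(
            mrna=np.zeros(3), mutations=np.zeros(2), immune=np.zeros(2), clinical=np.zeros(4)
        )
        assert fuse(np.zeros(5), o_clin, with_clin).size - fuse(np.zeros(5), o_base, base).size == 4

    def test_schema_mismatch_names_block(self):
        schema = OmicsSchema(n_mrna=3, n_mutations=2, n_immune=2)
        omics = OmicsVector(mrna=np.zeros(4), mutations=np.zeros(2), immune=np.zeros(2))
        with pytest.raises(ValueError, match="mrna"):
            fuse(np.zeros(5), omics, schema)

    def test_masked_omics_contributes_zeros(self):
        schema = OmicsSchema(n_mrna=3, n_mutations=2, n_immune=2)
        std = OmicsStandardizer(mean=np.full(7, 5.0), scale=np.full(7, 2.0))
        omics = OmicsVector(mrna=np.ones(3), mutations=np.ones(2), immune=np.ones(2))
        fused = fuse(np.ones(4), omics.zeroed(), schema, std)
        assert np.array_equal(fused[4:], np.zeros(7))


class TestForward:
    def test_eval_deterministic(self, tiny_cohort, tiny_model):
        s = tiny_cohort.samples()[0]
        a = tiny_model.forward(s.bag, s.omics, mode="eval")
        b = tiny_model.forward(s.bag, s.omics, mode="eval")
        assert a[0] == b[0]
        assert np.array_equal(a[1].weights, b[1].weights)

    def test_permutation_invariance_over_50_permutations(self, tiny_cohort, tiny_model):
        s = tiny_cohort.samples()[1]
        base, _ = tiny_model.forward(s.bag, s.omics, mode="eval")
        rng = np.random.default_rng(0)
        for _ in range(50):
            perm = rng.permutation(s.bag.n_patches)
            shuffled = FeatureBag(
                sample_id=s.bag.sample_id,
                features=s.bag.features[perm],
                coords=s.bag.coords[perm],
            )
            pred, _ = tiny_model.forward(shuffled, s.omics, mode="eval")
            assert pred.lnm_probability == pytest.approx(base.lnm_probability, abs=1e-12)
            assert pred.dfs_risk_score == pytest.approx(base.dfs_risk_score, abs=1e-12)
            assert pred.predicted_time == pytest.approx(base.predicted_time, abs=1e-12)

    def test_zero_params_give_half_probability(self, tiny_cohort):
        config = ModelConfig(
            feature_dim=6, omics_schema=tiny_cohort.omics[0].schema,
            d_img=5, attention_hidden=4, dropout=0.0,
        )
        model = FusionMILModel(config, seed=0)  # heads init to zero
        s = tiny_cohort.samples()[2]
        pred, _ = model.forward(s.bag, s.omics, mode="eval")
        assert pred.lnm_probability == 0.5

    def test_outputs_within_contracts(self, tiny_cohort, tiny_model):
        for s in tiny_cohort.samples()[:10]:
            pred, profile = tiny_model.forward(s.bag, s.omics, mode="eval")
            assert 0.0 <= pred.lnm_probability <= 1.0
            assert pred.predicted_time >= 0.0
            assert profile.weights.size == s.bag.n_patches

    def test_train_mode_requires_rng_with_dropout(self, tiny_cohort):
        config = ModelConfig(
            feature_dim=6, omics_schema=tiny_cohort.omics[0].schema,
            d_img=5, attention_hidden=4, dropout=0.25,
        )
        model = FusionMILModel(config, seed=0)
        s = tiny_cohort.samples()[0]
        with pytest.raises(ValueError, match="rng"):
            model.forward(s.bag, s.omics, mode="train")

    def test_nan_omics_fails_fast(self, tiny_cohort, tiny_model):
        s = tiny_cohort.samples()[0]
        bad = OmicsVector(
            mrna=np.full(12, np.nan), mutations=np.zeros(4), immune=np.zeros(5)
        )
        with pytest.raises(ValueError):
            tiny_model.forward(s.bag, bad, mode="eval")


class TestGradients:
    def test_full_model_gradient_matches_finite_differences(self, tiny_cohort, tiny_model):
        """Central finite differences on every parameter of a small batch."""
        samples = tiny_cohort.samples()[:5]
        weights = LossWeights(lambda_ce=1.0, lambda_mse=0.05)
        _, _, grads = batch_loss_and_grads(tiny_model, samples, weights, mode="eval")
        eps = 1e-6
        for key, grad in grads.items():
            tensor = tiny_model.params.tensors[key]
            it = np.nditer(tensor, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = tensor[idx]
                tensor[idx] = orig + eps
                lp, _, _ = batch_loss_and_grads(tiny_model, samples, weights, mode="eval")
                tensor[idx] = orig - eps
                lm, _, _ = batch_loss_and_grads(tiny_model, samples, weights, mode="eval")
                tensor[idx] = orig
                fd = (lp - lm) / (2 * eps)
                # 1e-4 relative, with an absolute floor at the FD noise level
                tol = 1e-8 + 1e-4 * max(abs(fd), abs(float(grad[idx])))
                assert abs(fd - grad[idx]) < tol, f"{key}{idx}: fd={fd} an={grad[idx]}"


class TestCheckpoint:
    def test_roundtrip(self, tiny_cohort, tiny_model, tmp_path):
        path = tmp_path / "model.npz"
        tiny_model.save(str(path))
        loaded = FusionMILModel.load(str(path))
        assert loaded.params.checksum() == tiny_model.params.checksum()
        s = tiny_cohort.samples()[0]
        a, _ = tiny_model.forward(s.bag, s.omics, mode="eval")
        b, _ = loaded.forward(s.bag, s.omics, mode="eval")
        assert a == b
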