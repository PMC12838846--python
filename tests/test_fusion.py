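"""The fusion core: Hadamard token, QFM, attention, head, composition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qfusion import (FusionConfig, FusionModel, ValidationError,
                     build_token_sequence, classify, hadamard_interaction,
                     init_classifier_head, init_mha_params, init_qfm_params,
                     mha_forward, qfm_forward)
from oracles import classify_oracle, fusion_oracle, mha_oracle, qfm_oracle


class TestHadamardInteraction:
    def test_hand_example_with_unequal_dims(self):
        out = hadamard_interaction(np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0]))
        np.testing.assert_allclose(out, [4.0, 10.0])

    def test_all_ones_is_multiplicative_identity(self, rng):
        z = rng.normal(size=12)
        np.testing.assert_allclose(hadamard_interaction(np.ones(12), z), z)

    def test_equal_dims_preserve_dimension(self, rng):
        out = hadamard_interaction(rng.normal(size=768), rng.normal(size=768))
        assert out.shape == (768,)

    def test_commutative_when_dims_equal(self, rng):
        a, b = rng.normal(size=9), rng.normal(size=9)
        np.testing.assert_allclose(hadamard_interaction(a, b),
                                   hadamard_interaction(b, a))

    def test_empty_vector_rejected(self):
        with pytest.raises(ValidationError):
            hadamard_interaction(np.array([]), np.array([1.0]))


class TestQFM:
    def test_zero_phase_case(self):
        # W=0, b=0 forces theta=0 so cos=1, sin=0; with U=0 the low-rank
        # interaction vanishes as well
        P, r, d = 4, 2, 3
        p = init_qfm_params(d, P, r, rng=np.random.default_rng(0))
        p.W[...] = 0.0
        p.b[...] = 0.0
        p.U[...] = 0.0
        z = np.array([0.3, -0.1, 2.0])
        theta = p.W @ z + p.b
        np.testing.assert_allclose(np.cos(theta), 1.0)
        np.testing.assert_allclose(np.sin(theta), 0.0)
        # f~ = [1...1, 0...0, 0...0]; check via the public forward against
        # the loop oracle
        psi = qfm_forward(z, p)
        expect = qfm_oracle(z.tolist(), p.W.tolist(), p.b.tolist(), p.U.tolist(),
                            p.V.tolist(), p.W0.tolist(), p.b0.tolist(), p.eps)
        np.testing.assert_allclose(psi, expect, atol=1e-12)

    def test_zero_projection_gives_exact_zero_output(self):
        p = init_qfm_params(3, 4, 2, rng=np.random.default_rng(1))
        p.W0[...] = 0.0
        p.b0[...] = 0.0
        psi = qfm_forward(np.array([1.0, 2.0, 3.0]), p)
        np.testing.assert_array_equal(psi, np.zeros(4))

    @pytest.mark.parametrize("alt", [False, True])
    def test_matches_scalar_loop_oracle(self, alt):
        rng = np.random.default_rng(42)
        p = init_qfm_params(d=5, P=8, r=3, rng=rng, alt_phase_interaction=alt)
        for _ in range(25):
            z = rng.normal(size=5)
            expect = qfm_oracle(z.tolist(), p.W.tolist(), p.b.tolist(),
                                p.U.tolist(), p.V.tolist(), p.W0.tolist(),
                                p.b0.tolist(), p.eps, alt)
            np.testing.assert_allclose(qfm_forward(z, p), expect, atol=1e-6)

    def test_norm_strictly_below_one_and_limit(self, rng):
        p = init_qfm_params(6, 8, 3, eps=1e-6, rng=rng)
        for scale in (1e-3, 1.0, 1e3):
            psi = qfm_forward(scale * rng.normal(size=6), p)
            assert np.linalg.norm(psi) < 1.0
        # large-norm limit: scale the output projection so ||f|| >> eps
        p.W0[...] *= 1e6
        psi = qfm_forward(rng.normal(size=6), p)
        assert np.linalg.norm(psi) > 1.0 - 1e-4

    def test_norm_equals_f_over_f_plus_eps(self, rng):
        p = init_qfm_params(5, 8, 3, eps=1e-2, rng=rng)
        z = rng.normal(size=5)
        # oracle with eps -> 0 recovers the unit direction f / ||f||
        f_dir = np.array(qfm_oracle(z.tolist(), p.W.tolist(), p.b.tolist(),
                                    p.U.tolist(), p.V.tolist(), p.W0.tolist(),
                                    p.b0.tolist(), 1e-300))
        psi = qfm_forward(z, p)
        n = np.linalg.norm(psi)
        assert 0.0 < n < 1.0
        np.testing.assert_allclose(psi / n, f_dir, atol=1e-9)
        # invert the scaling: ||f|| = eps * n / (1 - n), then n = ||f||/(||f||+eps)
        f_norm = p.eps * n / (1.0 - n)
        np.testing.assert_allclose(n, f_norm / (f_norm + p.eps), atol=1e-12)

    def test_phase_periodicity_in_bias(self, rng):
        # adding 2*pi to any component of b leaves the output unchanged
        p = init_qfm_params(5, 8, 3, rng=rng)
        z = rng.normal(size=5)
        before = qfm_forward(z, p)
        p.b[3] += 2.0 * np.pi
        np.testing.assert_allclose(qfm_forward(z, p), before, atol=1e-9)

    def test_dim_mismatch_rejected(self, rng):
        p = init_qfm_params(5, 8, 3, rng=rng)
        with pytest.raises(ValidationError):
            qfm_forward(np.ones(4), p)

    def test_nonpositive_eps_rejected(self, rng):
        with pytest.raises(ValidationError):
            init_qfm_params(5, 8, 3, eps=0.0, rng=rng)


class TestTokenSequence:
    def test_stacks_three_tokens_in_order(self):
        T = build_token_sequence(np.array([1.0, 0.0]), np.array([0.0, 1.0]),
                                 np.array([1.0, 1.0]))
        np.testing.assert_array_equal(T, [[1, 0], [0, 1], [1, 1]])

    def test_study_scale_shape(self, rng):
        T = build_token_sequence(*(rng.normal(size=256) for _ in range(3)))
        assert T.shape == (3, 256)

    def test_dim_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            build_token_sequence(np.ones(4), np.ones(4), np.ones(5))


class TestMHA:
    def test_zero_query_key_gives_uniform_attention(self, rng):
        p = init_mha_params(8, n_heads=2, rng=rng)
        p.WQ[...] = 0.0
        p.WK[...] = 0.0
        T = rng.normal(size=(3, 8))
        out, A = mha_forward(T, p, return_attention=True)
        np.testing.assert_allclose(A, 1.0 / 3.0)
        # pre-WO each head output is the mean of its V rows
        V = (T @ p.WV).reshape(3, 2, 4).transpose(1, 0, 2)
        concat = np.concatenate([np.repeat(V[h].mean(0, keepdims=True), 3, axis=0)
                                 for h in range(2)], axis=1)
        np.testing.assert_allclose(out, concat @ p.WO, atol=1e-12)

    def test_attention_rows_sum_to_one(self, rng):
        p = init_mha_params(8, n_heads=4, rng=rng)
        for _ in range(10):
            _, A = mha_forward(rng.normal(size=(3, 8)), p, return_attention=True)
            np.testing.assert_allclose(A.sum(axis=-1), 1.0, atol=1e-6)

    def test_matches_scalar_loop_oracle_single_head(self):
        rng = np.random.default_rng(7)
        p = init_mha_params(4, n_heads=1, rng=rng)
        T = rng.normal(size=(3, 4))
        expect = mha_oracle(T.tolist(), p.WQ.tolist(), p.WK.tolist(),
                            p.WV.tolist(), p.WO.tolist(), 1)
        np.testing.assert_allclose(mha_forward(T, p), expect, atol=1e-6)

    def test_matches_scalar_loop_oracle_multi_head(self, rng):
        p = init_mha_params(8, n_heads=4, rng=rng)
        T = rng.normal(size=(3, 8))
        expect = mha_oracle(T.tolist(), p.WQ.tolist(), p.WK.tolist(),
                            p.WV.tolist(), p.WO.tolist(), 4)
        np.testing.assert_allclose(mha_forward(T, p), expect, atol=1e-6)

    def test_indivisible_heads_rejected(self, rng):
        with pytest.raises(ValidationError):
            init_mha_params(10, n_heads=4, rng=rng)


class TestClassifierHead:
    def test_zero_weights_give_uniform_probabilities(self):
        head = init_classifier_head(4, 6, n_classes=5, rng=np.random.default_rng(0))
        for arr in (head.W1, head.b1, head.W2, head.b2):
            arr[...] = 0.0
        probs = classify(np.zeros((3, 4)), head)
        np.testing.assert_allclose(probs, 0.2)

    def test_probabilities_sum_to_one_and_argmax_is_prediction(self, rng):
        head = init_classifier_head(4, 6, n_classes=3, rng=rng)
        probs = classify(rng.normal(size=(3, 4)), head)
        assert probs.shape == (3,)
        np.testing.assert_allclose(probs.sum(), 1.0, atol=1e-6)
        assert (probs >= 0).all()

    def test_matches_scalar_loop_oracle(self, rng):
        head = init_classifier_head(4, 6, n_classes=3, rng=rng)
        att = rng.normal(size=(3, 4))
        expect = classify_oracle(att.tolist(), head.W1.tolist(), head.b1.tolist(),
                                 head.W2.tolist(), head.b2.tolist())
        np.testing.assert_allclose(classify(att, head), expect, atol=1e-6)

    def test_too_few_classes_rejected(self, rng):
        with pytest.raises(ValidationError):
            init_classifier_head(4, 6, n_classes=1, rng=rng)


class TestFusionModel:
    def test_composition_matches_stage_oracles(self, toy_model, rng):
        for _ in range(20):
            zA = rng.normal(size=6)
            zB = rng.normal(size=5)
            expect = fusion_oracle(zA, zB, toy_model)
            np.testing.assert_allclose(toy_model.forward(zA, zB), expect, atol=1e-5)

    def test_inference_is_deterministic(self, toy_model, rng):
        zA, zB = rng.normal(size=(4, 6)), rng.normal(size=(4, 5))
        np.testing.assert_array_equal(toy_model.forward(zA, zB),
                                      toy_model.forward(zA, zB))

    def test_hadamard_token_symmetric_under_branch_swap(self, rng):
        # with dA == dB, swapping the inputs leaves z_H unchanged
        cfg = FusionConfig(dA=6, dB=6, P=8, r=3, n_heads=2, hidden_dim=7,
                           n_classes=4, dropout_rate=0.0, seed=0)
        m = FusionModel(cfg)
        zA, zB = rng.normal(size=6), rng.normal(size=6)
        np.testing.assert_allclose(hadamard_interaction(zA, zB),
                                   hadamard_interaction(zB, zA))
        # and the full model is invariant if the branch params are swapped too
        m2 = FusionModel(cfg)
        m2.qfm_a, m2.qfm_b = m.qfm_b, m.qfm_a
        m2.qfm_h, m2.mha, m2.head = m.qfm_h, m.mha, m.head
        T1 = build_token_sequence(*(qfm_forward(z, p) for z, p in
                                    [(zA, m.qfm_a), (zB, m.qfm_b),
                                     (hadamard_interaction(zA, zB), m.qfm_h)]))
        T2 = build_token_sequence(*(qfm_forward(z, p) for z, p in
                                    [(zB, m2.qfm_a), (zA, m2.qfm_b),
                                     (hadamard_interaction(zB, zA), m2.qfm_h)]))
        np.testing.assert_allclose(T1[2], T2[2], atol=1e-12)

    def test_gradients_match_finite_differences(self, toy_model, rng):
        zA, zB = rng.normal(size=(5, 6)), rng.normal(size=(5, 5))
        y = np.array([0, 1, 2, 3, 4])
        loss, grads = toy_model.loss_and_grads(zA, zB, y, train=False)
        params = toy_model.parameters()
        h = 1e-6
        for name, arr in params.items():
            idxs = [tuple(rng.integers(0, s) for s in arr.shape) for _ in range(3)]
            for idx in idxs:
                orig = arr[idx]
                arr[idx] = orig + h
                lp, _ = toy_model.loss_and_grads(zA, zB, y, train=False)
                arr[idx] = orig - h
                lm, _ = toy_model.loss_and_grads(zA, zB, y, train=False)
                arr[idx] = orig
                num = (lp - lm) / (2 * h)
                assert abs(num - grads[name][idx]) < 1e-5 * max(1.0, abs(num)), name

    def test_checkpoint_round_trip(self, toy_model, rng, tmp_path):
        zA, zB = rng.normal(size=(3, 6)), rng.normal(size=(3, 5))
        toy_model.save(tmp_path / "ckpt.npz", tmp_path / "manifest.json")
        reloaded = FusionModel.load(tmp_path / "ckpt.npz", tmp_path / "manifest.json")
        np.testing.assert_array_equal(toy_model.forward(zA, zB),
                                      reloaded.forward(zA, zB))

    def test_feature_dim_mismatch_rejected(self, toy_model):
        with pytest.raises(ValidationError):
            toy_model.forward(np.ones((2, 7)), np.ones((2, 5)))


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1), st.floats(0.01, 100.0))
def test_qfm_norm_conservation_property(seed, scale):
    """||psi|| = ||f|| / (||f|| + eps) lies in [0, 1) for any input scale."""
    rng = np.random.default_rng(seed)
    p = init_qfm_params(4, 8, 2, eps=1e-6, rng=rng)
    psi = qfm_forward(scale * rng.normal(size=4), p)
    n = np.linalg.norm(psi)
    assert 0.0 <= n < 1.0


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1))
def test_attention_row_stochastic_property(seed):
    rng = np.random.default_rng(seed)
    p = init_mha_params(8, n_heads=2, rng=rng)
    _, A = mha_forward(rng.normal(size=(3, 8)) * rng.uniform(0.1, 10),
                       p, return_attention=True)
    assert (A >= 0).all()
    np.testing.assert_allclose(A.sum(axis=-1), 1.0, atol=1e-6)
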