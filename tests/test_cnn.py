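"""Convolutional sequence feature extractor: shapes, oracles, masking."""

import numpy as np
import pytest

from hetdti import autodiff as ad
from hetdti.autodiff import Tensor
from hetdti.cnn import (
    AggregationBlockParams,
    CnnConfig,
    RefineConvParams,
    RegionConvParams,
    aggregate_block,
    conv_refine,
    extract_features,
    forward_batch,
    init_cnn_params,
    region_embed,
)
from hetdti.sequences import (
    DrugSmiles,
    build_smiles_vocabulary,
    encode_drug,
)


def region_params(W: np.ndarray, b: np.ndarray) -> RegionConvParams:
    return RegionConvParams(W=Tensor(W), b=Tensor(b))


def naive_region_conv(X: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Sliding-window triple-loop oracle for the region convolution."""
    C, L = X.shape
    _, _, N = W.shape
    out = np.zeros((L - 2, N))
    for p in range(L - 2):
        for n in range(N):
            out[p, n] = b[n]
            for w in range(3):
                for c in range(C):
                    out[p, n] += W[w, c, n] * X[c, p + w]
    return out


class TestRegionEmbed:
    def test_output_length_is_L_minus_2(self):
        X = np.zeros((4, 10))
        p = region_params(np.zeros((3, 4, 6)), np.zeros(6))
        assert region_embed(X, p).shape == (8, 6)

    def test_zero_input_zero_bias_gives_zero(self):
        X = np.zeros((4, 10))
        p = region_params(np.random.default_rng(0).normal(0, 1, (3, 4, 2)), np.zeros(2))
        assert np.allclose(region_embed(X, p), 0.0)

    def test_center_tap_kernel_reproduces_shifted_channel(self):
        # kernel reads only the window center of channel 0
        W = np.zeros((3, 2, 1))
        W[1, 0, 0] = 1.0
        X = np.zeros((2, 6))
        X[0] = [1, 2, 3, 4, 5, 6]
        out = region_embed(X, region_params(W, np.zeros(1)))
        assert np.allclose(out[:, 0], [2, 3, 4, 5])

    def test_matches_naive_oracle_on_random_instances(self):
        rng = np.random.default_rng(7)
        with ad.precision("float64"):
            for _ in range(20):
                C, L, N = rng.integers(1, 6), rng.integers(3, 12), rng.integers(1, 5)
                X = rng.normal(0, 1, (C, L))
                W = rng.normal(0, 1, (3, C, N))
                b = rng.normal(0, 1, N)
                got = region_embed(X, region_params(W, b))
                np.testing.assert_allclose(got, naive_region_conv(X, W, b), rtol=1e-6)

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError):
            region_embed(np.zeros((4, 2)), region_params(np.zeros((3, 4, 1)), np.zeros(1)))


class TestConvRefine:
    def test_hand_oracle_length5(self):
        # 1 channel, 1 kernel, weights [1,1,1], input [1..5] -> [6, 9, 12]
        p = RefineConvParams(W=Tensor(np.ones((3, 1))), b=Tensor(np.zeros(1)))
        out = conv_refine(np.array([[1.0], [2.0], [3.0], [4.0], [5.0]]), p)
        assert np.allclose(out[:, 0], [6, 9, 12])

    def test_rectifier_passthrough_for_nonnegative_input(self):
        rng = np.random.default_rng(1)
        X = np.abs(rng.normal(0, 1, (7, 2)))
        p = RefineConvParams(W=Tensor(rng.normal(0, 1, (6, 2))), b=Tensor(np.zeros(2)))
        with_relu = conv_refine(X, p)
        plain = ad.windows3(Tensor(X[None])).data[0] @ p.W.data + p.b.data
        np.testing.assert_allclose(with_relu, plain, rtol=1e-6)

    def test_negative_channel_suppressed(self):
        X = np.full((5, 1), -3.0)
        p = RefineConvParams(W=Tensor(np.ones((3, 1))), b=Tensor(np.zeros(1)))
        assert np.allclose(conv_refine(X, p), 0.0)

    def test_depthwise_option_keeps_own_channel_only(self):
        rng = np.random.default_rng(2)
        X = np.abs(rng.normal(0, 1, (6, 2)))
        W = rng.normal(0, 1, (6, 2))
        p = RefineConvParams(W=Tensor(W), b=Tensor(np.zeros(2)))
        got = conv_refine(X, p, depthwise=True)
        # channel 0 output must not depend on channel 1 input
        X2 = X.copy()
        X2[:, 1] = 0.0
        got2 = conv_refine(X2, p, depthwise=True)
        np.testing.assert_allclose(got[:, 0], got2[:, 0], rtol=1e-6)


class TestAggregateBlock:
    @staticmethod
    def zero_theta(n: int) -> AggregationBlockParams:
        return AggregationBlockParams(
            W1=Tensor(np.zeros((n, n))), b1=Tensor(np.zeros(n)),
            W2=Tensor(np.zeros((n, n))), b2=Tensor(np.zeros(n)),
        )

    def test_zero_theta_reduces_to_max_pooling(self):
        X = np.array([[1.0], [3.0], [2.0], [2.0]])
        out = aggregate_block(X, self.zero_theta(1))
        assert np.allclose(out[:, 0], [3, 2])

    def test_length_halves_per_block(self):
        X = np.random.default_rng(0).normal(0, 1, (64, 4))
        p = self.zero_theta(4)
        once = aggregate_block(X, p)
        twice = aggregate_block(once, p)
        assert once.shape == (32, 4) and twice.shape == (16, 4)

    def test_residual_addition(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (8, 2))
        p = AggregationBlockParams(
            W1=Tensor(rng.normal(0, 1, (2, 2))), b1=Tensor(rng.normal(0, 1, 2)),
            W2=Tensor(rng.normal(0, 1, (2, 2))), b2=Tensor(rng.normal(0, 1, 2)),
        )
        pooled = aggregate_block(X, self.zero_theta(2))
        theta = np.maximum(pooled @ p.W1.data + p.b1.data, 0) @ p.W2.data + p.b2.data
        np.testing.assert_allclose(aggregate_block(X, p), pooled + theta, rtol=1e-5)


@pytest.fixture(scope="module")
def vocab():
    return build_smiles_vocabulary()


class TestExtractFeatures:
    def test_padding_never_changes_output(self, vocab):
        params = init_cnn_params(vocab.size, CnnConfig(n_kernels=8),
                                 np.random.default_rng(5))
        d = DrugSmiles("d", "CC(=O)Nc1ccc(O)cc1CCO")
        short = extract_features(encode_drug(d, vocab, 24), params)
        long = extract_features(encode_drug(d, vocab, 64), params)
        np.testing.assert_array_equal(short, long)

    def test_output_dimension_independent_of_length(self, vocab):
        params = init_cnn_params(vocab.size, CnnConfig(n_kernels=8),
                                 np.random.default_rng(5))
        a = extract_features(encode_drug(DrugSmiles("a", "CC(=O)Nc1ccc(O)cc1"), vocab, 32), params)
        b = extract_features(
            encode_drug(DrugSmiles("b", "CC(C)Cc1ccc(C(C)C(=O)O)cc1CCCC"), vocab, 32), params
        )
        assert a.shape == b.shape == (8,)

    def test_deterministic_given_parameters(self, vocab):
        params = init_cnn_params(vocab.size, CnnConfig(n_kernels=8),
                                 np.random.default_rng(5))
        emb = encode_drug(DrugSmiles("d", "c1ccc2c(c1)[nH]c1ccccc12"), vocab, 32)
        assert np.array_equal(extract_features(emb, params), extract_features(emb, params))

    def test_sequence_below_minimum_length_rejected(self, vocab):
        cfg = CnnConfig(n_kernels=4)
        params = init_cnn_params(vocab.size, cfg, np.random.default_rng(5))
        emb = encode_drug(DrugSmiles("d", "CCOCC"), vocab, 16)
        assert emb.n_valid < cfg.min_valid_length
        with pytest.raises(ValueError, match="valid positions"):
            extract_features(emb, params)

    def test_gradient_against_finite_differences(self):
        from test_autodiff import numerical_grad

        with ad.precision("float64"):
            rng = np.random.default_rng(11)
            params = init_cnn_params(5, CnnConfig(n_kernels=3, n_blocks=1), rng)
            tokens = rng.integers(0, 5, (2, 14))
            valid = np.array([14, 11])
            w = rng.normal(0, 1, (2, 3))

            def scalar():
                return float(np.sum(forward_batch(tokens, valid, params).data * w))

            out = forward_batch(tokens, valid, params)
            out.backward(w)
            checked = 0
            for p in params.tensors()[:4]:
                num = numerical_grad(scalar, p.data, eps=1e-6)
                np.testing.assert_allclose(p.grad, num, rtol=1e-4, atol=1e-6)
                checked += 1
            assert checked == 4

    def test_batched_path_matches_single(self, vocab):
        params = init_cnn_params(vocab.size, CnnConfig(n_kernels=6),
                                 np.random.default_rng(9))
        embs = [
            encode_drug(DrugSmiles(f"d{i}", s), vocab, 40)
            for i, s in enumerate(["CC(=O)Nc1ccc(O)cc1", "CC(C)Cc1ccc(C(C)C(=O)O)cc1"])
        ]
        tokens = np.stack([e.indices for e in embs])
        valid = np.array([e.n_valid for e in embs])
        batch = forward_batch(tokens, valid, params).data
        for i, e in enumerate(embs):
            np.testing.assert_allclose(batch[i], extract_features(e, params), rtol=1e-5)
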