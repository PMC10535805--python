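"""Relational GCN/GAT encoder: propagation oracles, attention
normalization, fusion wiring, loss values, training contracts."""

import numpy as np
import pytest

from hetdti import autodiff as ad
from hetdti.autodiff import Tensor
from hetdti.graph import (
    EncoderConfig,
    GatLayerParams,
    GcnLayerParams,
    GraphStructure,
    JointRepresentationModel,
    bce_loss,
    encode_nodes,
    gat_attention,
    gat_propagate,
    gcn_propagate,
    init_encoder_params,
    pair_scores,
    train_encoder,
)
from hetdti.hetnet import RELATIONS, HeterogeneousNetwork, normalized_adjacency
from hetdti.pipeline import RandomFeatureSource


def random_network(rng: np.random.Generator, nd: int, nt: int) -> HeterogeneousNetwork:
    n = nd + nt
    relations = {}
    for r in RELATIONS:
        S = np.zeros((n, n), dtype=bool)
        if r.startswith("drug_drug"):
            blk = rng.random((nd, nd)) < 0.3
            S[:nd, :nd] = np.triu(blk, 1) | np.triu(blk, 1).T
        elif r.startswith("target_target"):
            blk = rng.random((nt, nt)) < 0.3
            S[nd:, nd:] = np.triu(blk, 1) | np.triu(blk, 1).T
        else:
            blk = rng.random((nd, nt)) < 0.3
            S[:nd, nd:] = blk
            S[nd:, :nd] = blk.T
        relations[r] = S
    return HeterogeneousNetwork(
        tuple(f"d{i}" for i in range(nd)), tuple(f"t{i}" for i in range(nt)), relations
    )


def gcn_params(rng, d_in, d_out, scale=1.0) -> GcnLayerParams:
    return GcnLayerParams(
        {r: Tensor(scale * rng.normal(0, 1, (d_in, d_out)), requires_grad=True)
         for r in RELATIONS}
    )


def gat_params(rng, d_in, d_out, K=2, a_scale=1.0) -> GatLayerParams:
    return GatLayerParams(
        W=[Tensor(rng.normal(0, 1, (d_in, d_out))) for _ in range(K)],
        a_src=[Tensor(a_scale * rng.normal(0, 1, d_out)) for _ in range(K)],
        a_dst=[Tensor(a_scale * rng.normal(0, 1, d_out)) for _ in range(K)],
        beta=Tensor(rng.normal(0, 1, (K, len(RELATIONS)))),
    )


class TestGcnPropagate:
    def test_two_nodes_one_edge_worked_example(self):
        # S~ = [[1,1],[1,1]], degrees (2,2) -> normalized = all 0.5
        net = random_network(np.random.default_rng(0), 1, 1)
        for r in RELATIONS:
            net.relations[r][:] = False
        net.relations["drug_target_interaction"][0, 1] = True
        net.relations["drug_target_interaction"][1, 0] = True
        structure = GraphStructure(net)
        params = GcnLayerParams(
            {r: Tensor(np.eye(1) if r == "drug_target_interaction" else np.zeros((1, 1)))
             for r in RELATIONS}
        )
        out = gcn_propagate(np.array([[1.0], [0.0]]), structure, params)
        np.testing.assert_allclose(out.data, [[0.5], [0.5]])

    def test_single_isolated_node_identity(self):
        net = random_network(np.random.default_rng(0), 1, 1)
        for r in RELATIONS:
            net.relations[r][:] = False
        structure = GraphStructure(net)
        params = GcnLayerParams(
            {r: Tensor(np.eye(2) if r == RELATIONS[0] else np.zeros((2, 2)))
             for r in RELATIONS}
        )
        x = np.array([[0.3, 0.7], [0.1, 0.2]])
        np.testing.assert_allclose(gcn_propagate(x, structure, params).data, x,
                                   rtol=1e-6)

    def test_matches_per_node_loop_oracle(self):
        with ad.precision("float64"):
            for seed in range(20):
                rng = np.random.default_rng(seed)
                net = random_network(rng, 4, 6)
                structure = GraphStructure(net)
                params = gcn_params(rng, 3, 5)
                X = rng.normal(0, 1, (10, 3))
                got = gcn_propagate(X, structure, params).data
                expect = np.zeros((10, 5))
                for r in RELATIONS:  # per-node, per-relation loop oracle
                    A = normalized_adjacency(net.relations[r])
                    W = params.W[r].data
                    for i in range(10):
                        acc = np.zeros(3)
                        for j in range(10):
                            acc += A[i, j] * X[j]
                        expect[i] += np.maximum(acc @ W, 0.0)
                np.testing.assert_allclose(got, expect, rtol=1e-6, atol=1e-9)

    def test_additivity_over_relations(self):
        rng = np.random.default_rng(3)
        net = random_network(rng, 3, 3)
        structure = GraphStructure(net)
        params = gcn_params(rng, 2, 2)
        X = np.abs(rng.normal(0, 1, (6, 2)))
        full = gcn_propagate(X, structure, params).data
        zeroed = GcnLayerParams(dict(params.W))
        zeroed.W = {r: (Tensor(np.zeros((2, 2))) if r == "drug_drug_interaction" else t)
                    for r, t in params.W.items()}
        dropped = gcn_propagate(X, structure, zeroed).data
        only = GcnLayerParams(
            {r: (t if r == "drug_drug_interaction" else Tensor(np.zeros((2, 2))))
             for r, t in params.W.items()}
        )
        alone = gcn_propagate(X, structure, only).data
        np.testing.assert_allclose(full, dropped + alone, rtol=1e-5)


class TestGatAttention:
    def test_single_neighbor_coefficient_is_one(self):
        rng = np.random.default_rng(0)
        net = random_network(rng, 1, 1)
        for r in RELATIONS:
            net.relations[r][:] = False
        net.relations["drug_target_interaction"][0, 1] = True
        net.relations["drug_target_interaction"][1, 0] = True
        structure = GraphStructure(net)
        params = gat_params(rng, 2, 3, K=1)
        phi = gat_attention(rng.normal(0, 1, (2, 2)), structure, params,
                            "drug_target_interaction", 0).data
        assert phi[0, 1] == pytest.approx(1.0)
        assert phi[1, 0] == pytest.approx(1.0)

    def test_identical_neighbors_share_weight_equally(self):
        rng = np.random.default_rng(1)
        net = random_network(rng, 1, 2)
        for r in RELATIONS:
            net.relations[r][:] = False
        for j in (1, 2):  # star: drug 0 linked to both targets
            net.relations["drug_target_interaction"][0, j] = True
            net.relations["drug_target_interaction"][j, 0] = True
        structure = GraphStructure(net)
        params = gat_params(rng, 2, 3, K=1)
        X = np.array([[0.5, -0.2], [1.0, 2.0], [1.0, 2.0]])  # identical neighbors
        phi = gat_attention(X, structure, params, "drug_target_interaction", 0).data
        assert phi[0, 1] == pytest.approx(0.5, abs=1e-6)
        assert phi[0, 2] == pytest.approx(0.5, abs=1e-6)

    def test_three_node_star_matches_scalar_softmax_oracle(self):
        with ad.precision("float64"):
            rng = np.random.default_rng(2)
            net = random_network(rng, 1, 2)
            for r in RELATIONS:
                net.relations[r][:] = False
            for j in (1, 2):
                net.relations["drug_target_interaction"][0, j] = True
                net.relations["drug_target_interaction"][j, 0] = True
            structure = GraphStructure(net)
            params = gat_params(rng, 2, 3, K=1)
            X = rng.normal(0, 1, (3, 2))
            phi = gat_attention(X, structure, params,
                                "drug_target_interaction", 0).data
            # scalar enumeration oracle
            W, asrc, adst = params.W[0].data, params.a_src[0].data, params.a_dst[0].data
            beta = params.beta.data[0, RELATIONS.index("drug_target_interaction")]

            def logit(i, j):
                z = float(asrc @ (W.T @ X[i]) + adst @ (W.T @ X[j]) + beta)
                return z if z > 0 else 0.2 * z

            e1, e2 = np.exp(logit(0, 1)), np.exp(logit(0, 2))
            np.testing.assert_allclose(phi[0, 1], e1 / (e1 + e2), rtol=1e-6)
            np.testing.assert_allclose(phi[0, 2], e2 / (e1 + e2), rtol=1e-6)

    def test_rows_sum_to_one_wherever_defined(self):
        rng = np.random.default_rng(5)
        net = random_network(rng, 4, 5)
        structure = GraphStructure(net)
        params = gat_params(rng, 3, 4, K=3)
        X = rng.normal(0, 1, (9, 3))
        for r in RELATIONS:
            for k in range(3):
                phi = gat_attention(X, structure, params, r, k).data
                sums = phi.sum(axis=1)
                has_nb = net.relations[r].any(axis=1)
                np.testing.assert_allclose(sums[has_nb], 1.0, rtol=1e-5)
                np.testing.assert_allclose(sums[~has_nb], 0.0, atol=1e-12)


class TestGatPropagate:
    def test_uniform_attention_gives_neighbor_mean(self):
        with ad.precision("float64"):
            rng = np.random.default_rng(0)
            net = random_network(rng, 3, 3)
            for r in RELATIONS:
                if r != "drug_drug_interaction":
                    net.relations[r][:] = False
            structure = GraphStructure(net)
            d = 3
            params = GatLayerParams(
                W=[Tensor(np.eye(d))],
                a_src=[Tensor(np.zeros(d))],
                a_dst=[Tensor(np.zeros(d))],
                beta=Tensor(np.zeros((1, len(RELATIONS)))),
            )
            X = rng.normal(0, 1, (6, d))
            out = gat_propagate(X, structure, params).data
            S = net.relations["drug_drug_interaction"]
            for i in range(6):
                nbrs = np.flatnonzero(S[i])
                expect = np.maximum(X[nbrs].mean(axis=0), 0) if len(nbrs) else np.zeros(d)
                np.testing.assert_allclose(out[i], expect, rtol=1e-6, atol=1e-12)

    def test_isolated_node_gets_zero_vector(self):
        rng = np.random.default_rng(1)
        net = random_network(rng, 2, 2)
        for r in RELATIONS:
            net.relations[r][:] = False
        structure = GraphStructure(net)
        params = gat_params(rng, 2, 2, K=2)
        out = gat_propagate(rng.normal(0, 1, (4, 2)), structure, params).data
        np.testing.assert_allclose(out, 0.0)

    def test_heads_are_averaged(self):
        # two heads with identical parameters must equal the single head
        rng = np.random.default_rng(4)
        net = random_network(rng, 3, 3)
        structure = GraphStructure(net)
        one = gat_params(rng, 2, 3, K=1)
        two = GatLayerParams(
            W=[one.W[0], one.W[0]], a_src=[one.a_src[0], one.a_src[0]],
            a_dst=[one.a_dst[0], one.a_dst[0]],
            beta=Tensor(np.vstack([one.beta.data, one.beta.data])),
        )
        X = rng.normal(0, 1, (6, 2))
        np.testing.assert_allclose(
            gat_propagate(X, structure, one).data,
            gat_propagate(X, structure, two).data, rtol=1e-5,
        )


class TestEncodeNodes:
    def test_output_shapes(self):
        rng = np.random.default_rng(0)
        net = random_network(rng, 4, 7)
        structure = GraphStructure(net)
        params = init_encoder_params(5, EncoderConfig(d=8, n_heads=2), rng)
        X0 = rng.normal(0, 1, (11, 5))
        _, X_D, X_T = encode_nodes(X0, structure, params)
        assert X_D.shape == (4, 8) and X_T.shape == (7, 8)

    def test_fusion_uses_first_and_third_layer_only(self):
        rng = np.random.default_rng(1)
        net = random_network(rng, 3, 4)
        structure = GraphStructure(net)
        params = init_encoder_params(4, EncoderConfig(d=6, n_heads=2), rng)
        # zero the third layer -> X3 = 0 -> output depends only on X1
        for t in params.layers[2][1].tensors():
            t.data[:] = 0.0
        X0 = rng.normal(0, 1, (7, 4))
        base = encode_nodes(X0, structure, params)[0].data.copy()
        for t in params.layers[1][1].tensors():  # perturb the middle layer
            t.data += 1.0
        after = encode_nodes(X0, structure, params)[0].data
        np.testing.assert_allclose(base, after, atol=1e-6)

    def test_layer_order_is_configurable(self):
        rng = np.random.default_rng(2)
        params = init_encoder_params(
            4, EncoderConfig(d=6, n_heads=2, layer_order=("gat", "gat", "gcn")), rng
        )
        assert [k for k, _ in params.layers] == ["gat", "gat", "gcn"]

    def test_permutation_equivariance_within_kinds(self):
        with ad.precision("float64"):
            rng = np.random.default_rng(3)
            nd, nt = 4, 5
            net = random_network(rng, nd, nt)
            params = init_encoder_params(3, EncoderConfig(d=4, n_heads=2), rng)
            X0 = rng.normal(0, 1, (nd + nt, 3))
            base = encode_nodes(X0, GraphStructure(net), params)[0].data

            pd = rng.permutation(nd)
            pt = nd + rng.permutation(nt)
            perm = np.concatenate([pd, pt])
            pnet = HeterogeneousNetwork(
                tuple(net.drug_ids[i] for i in pd),
                tuple(net.node_ids[i] for i in pt),
                {r: S[np.ix_(perm, perm)] for r, S in net.relations.items()},
            )
            permuted = encode_nodes(X0[perm], GraphStructure(pnet), params)[0].data
            np.testing.assert_allclose(permuted, base[perm], rtol=1e-6, atol=1e-9)


class TestBceLoss:
    def test_perfect_prediction_loss_near_zero(self):
        u = Tensor(np.array([1.0, 0.0, 1.0]))
        y = np.array([1, 0, 1])
        assert float(bce_loss(u, y).data) < 1e-5

    def test_uninformative_half_gives_ln2(self):
        u = Tensor(np.full(10, 0.5))
        y = np.array([1, 0] * 5)
        assert float(bce_loss(u, y).data) == pytest.approx(np.log(2), rel=1e-5)

    def test_scalar_arithmetic_example(self):
        u = Tensor(np.array([0.9, 0.1]))
        y = np.array([1, 0])
        expect = -(np.log(0.9) + np.log(0.9)) / 2  # 0.10536
        assert float(bce_loss(u, y).data) == pytest.approx(expect, rel=1e-5)

    def test_matches_scalar_oracle_on_random_instances(self):
        with ad.precision("float64"):
            for seed in range(20):
                rng = np.random.default_rng(seed)
                u = rng.uniform(0.01, 0.99, 15)
                y = rng.integers(0, 2, 15)
                expect = -np.mean(y * np.log(u) + (1 - y) * np.log(1 - u))
                got = float(bce_loss(Tensor(u), y).data)
                assert got == pytest.approx(expect, rel=1e-9)


def micro_model(seed: int) -> tuple[JointRepresentationModel, np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    net = random_network(rng, 5, 6)
    source = RandomFeatureSource(5, 6, 4, rng)
    encoder = init_encoder_params(4, EncoderConfig(d=6, n_heads=2), rng)
    model = JointRepresentationModel(source, GraphStructure(net), encoder)
    pairs = np.stack(np.meshgrid(np.arange(5), np.arange(6), indexing="ij"),
                     axis=-1).reshape(-1, 2)
    labels = rng.integers(0, 2, len(pairs))
    return model, pairs, labels


class TestTrainEncoder:
    def test_same_seed_identical_loss_curves(self):
        logs = []
        for _ in range(2):
            model, pairs, labels = micro_model(7)
            log = train_encoder(model, pairs[:20], labels[:20], pairs[20:], labels[20:],
                                epochs=10, patience=10)
            logs.append([(e.train_loss, e.val_loss) for e in log])
        assert logs[0] == logs[1]

    def test_zero_learning_rate_leaves_parameters_unchanged(self):
        model, pairs, labels = micro_model(8)
        before = [p.data.copy() for p in model.parameters()]
        train_encoder(model, pairs[:20], labels[:20], pairs[20:], labels[20:],
                      lr=0.0, epochs=5, patience=5)
        for p, b in zip(model.parameters(), before):
            np.testing.assert_array_equal(p.data, b)

    def test_loss_decreases_on_trainable_instance(self):
        model, pairs, labels = micro_model(9)
        log = train_encoder(model, pairs, labels, pairs, labels,
                            epochs=60, patience=60)
        assert log[-1].train_loss < log[0].train_loss

    def test_pair_scores_are_probabilities(self):
        model, pairs, _ = micro_model(10)
        u = model.scores(pairs).data
        assert np.all((u > 0) & (u < 1))
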