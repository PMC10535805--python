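"""Relational GCN/GAT encoder over the heterogeneous network.

Per layer, features propagate independently along each of the five typed
relations and the per-relation results are summed:

* GCN layer:  X^{l+1} = sum_r ReLU( A_r^{-1/2} S~_r A_r^{-1/2} X^l W_r^l )
  with S~_r = I + S_r and A_r the degree matrix of S~_r.
* GAT layer:  multi-head attention per relation.  Head k scores neighbor
  j of node i with a LeakyReLU logit a_k^T [W_k x_i || W_k x_j || B_k r_ij],
  softmax-normalized over i's r-neighborhood; heads are averaged, then
  x_i^{l+1} = sum_r ReLU( (1/K) sum_k sum_j phi_r^{ijk} W_k x_j ).
  Because the edge-type term B_k r_ij is constant within one relation's
  neighborhood it cancels in the per-relation softmax; it becomes active
  under the optional "universal" softmax over all other nodes.

Three layers (default GCN-GAT-GCN) widen the receptive field; a fusion
layer combines the first and third layer outputs through a learned
window-1 convolution (a shared linear map on the concatenation) into the
final node representations, split into drug rows X_D and target rows X_T.
The preference matrix U = X_D X_T^T, squashed through a logistic, is
trained against known interaction labels with binary cross-entropy,
jointly with the sequence CNN that supplies the layer-0 features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .hetnet import RELATIONS, HeterogeneousNetwork, normalized_adjacency


@dataclass
class GcnLayerParams:
    """One trainable weight block per relation."""

    W: dict[str, Tensor]

    def tensors(self) -> list[Tensor]:
        return list(self.W.values())


@dataclass
class GatLayerParams:
    """K attention heads shared across relations, plus per-(head, relation)
    edge-type offsets (the B_k r_ij term of the attention logit)."""

    W: list[Tensor]  # per head, (d_in, d_out)
    a_src: list[Tensor]  # per head, (d_out,)
    a_dst: list[Tensor]  # per head, (d_out,)
    beta: Tensor  # (K, n_relations)
    slope: float = 0.2

    @property
    def n_heads(self) -> int:
        return len(self.W)

    def tensors(self) -> list[Tensor]:
        return [*self.W, *self.a_src, *self.a_dst, self.beta]


@dataclass
class FusionParams:
    W: Tensor  # (2d, d)
    b: Tensor  # (d,)

    def tensors(self) -> list[Tensor]:
        return [self.W, self.b]


@dataclass
class EncoderConfig:
    d: int = 128
    n_heads: int = 4
    layer_order: tuple[str, ...] = ("gcn", "gat", "gcn")
    leaky_slope: float = 0.2
    universal_softmax: bool = False  # softmax over all t != i instead of N_r(i)

    def __post_init__(self) -> None:
        bad = set(self.layer_order) - {"gcn", "gat"}
        if bad:
            raise ValueError(f"unknown layer kinds {bad}")
        if len(self.layer_order) != 3:
            raise ValueError("the encoder stacks exactly three graph layers")


@dataclass
class EncoderParams:
    layers: list[tuple[str, GcnLayerParams | GatLayerParams]]
    fusion: FusionParams
    config: EncoderConfig = field(default_factory=EncoderConfig)

    def tensors(self) -> list[Tensor]:
        out: list[Tensor] = []
        for _, p in self.layers:
            out += p.tensors()
        return out + self.fusion.tensors()


def init_encoder_params(
    d_in: int, config: EncoderConfig | None = None, rng: np.random.Generator | None = None
) -> EncoderParams:
    config = config or EncoderConfig()
    rng = rng or np.random.default_rng(0)
    d = config.d
    R = len(RELATIONS)

    # He-style scale, shrunk by the relation count (layer outputs sum over
    # R relations) so initial pair logits stay out of sigmoid saturation
    def w(shape, fan_in, scale=1.0):
        return Tensor(
            rng.normal(0, scale * np.sqrt(2.0 / fan_in), shape), requires_grad=True
        )

    layers: list[tuple[str, GcnLayerParams | GatLayerParams]] = []
    cur = d_in
    for kind in config.layer_order:
        if kind == "gcn":
            layers.append(
                ("gcn", GcnLayerParams({r: w((cur, d), cur, 1.0 / R) for r in RELATIONS}))
            )
        else:
            layers.append(
                (
                    "gat",
                    GatLayerParams(
                        W=[w((cur, d), cur, 1.0 / R) for _ in range(config.n_heads)],
                        a_src=[w((d,), d, 0.1) for _ in range(config.n_heads)],
                        a_dst=[w((d,), d, 0.1) for _ in range(config.n_heads)],
                        beta=Tensor(np.zeros((config.n_heads, len(RELATIONS))), requires_grad=True),
                        slope=config.leaky_slope,
                    ),
                )
            )
        cur = d
    fusion = FusionParams(
        W=w((2 * d, d), 2 * d, 0.5), b=Tensor(np.zeros(d), requires_grad=True)
    )
    return EncoderParams(layers, fusion, config)


class GraphStructure:
    """Pre-computed per-relation normalized adjacencies and neighbor masks."""

    def __init__(self, network: HeterogeneousNetwork):
        self.n = network.n_nodes
        self.n_drugs = network.n_drugs
        self.norm_adj = {
            r: normalized_adjacency(network.relations[r]) for r in RELATIONS
        }
        self.masks = {r: network.relations[r].copy() for r in RELATIONS}


def gcn_propagate(
    X: Tensor | np.ndarray, structure: GraphStructure, params: GcnLayerParams
) -> Tensor:
    """X^{l+1} = sum_r ReLU(A_r^{-1/2} S~_r A_r^{-1/2} X W_r)."""
    X = X if isinstance(X, Tensor) else Tensor(X)
    out = None
    for r in RELATIONS:
        term = ad.relu(Tensor(structure.norm_adj[r]) @ X @ params.W[r])
        out = term if out is None else out + term
    return out


def gat_attention(
    X: Tensor | np.ndarray,
    structure: GraphStructure,
    params: GatLayerParams,
    relation: str,
    head: int,
    universal_softmax: bool = False,
) -> Tensor:
    """Attention coefficient matrix phi for one relation and head.

    Row i holds softmax-normalized coefficients over i's r-neighbors
    (zero row where i has no neighbor under r).  The optional universal
    variant normalizes over all t != i but keeps weight only on neighbors.
    """
    X = X if isinstance(X, Tensor) else Tensor(X)
    H = X @ params.W[head]
    s_src = H @ params.a_src[head]  # (n,)
    s_dst = H @ params.a_dst[head]
    r_idx = RELATIONS.index(relation)
    beta_r = ad.gather_rows(_transpose(ad.gather_rows(params.beta, np.array([head]))),
                            np.array([r_idx]))  # (1, 1) scalar offset
    logits = ad.leaky_relu(_outer_sum(s_src, s_dst) + beta_r, params.slope)
    mask = structure.masks[relation]
    if universal_softmax:
        off_diag = ~np.eye(structure.n, dtype=bool)
        phi_all = ad.masked_softmax(logits, off_diag)
        return phi_all * Tensor(mask.astype(float))
    return ad.masked_softmax(logits, mask)


def _transpose(x: Tensor) -> Tensor:
    out = ad._node(x.data.T, (x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g.T)

    out._backward = bwd
    return out


def _outer_sum(a: Tensor, b: Tensor) -> Tensor:
    """logits[i, j] = a[i] + b[j]."""
    out = ad._node(a.data[:, None] + b.data[None, :], (a, b))

    def bwd(g):
        if a.requires_grad:
            a._accumulate(g.sum(axis=1))
        if b.requires_grad:
            b._accumulate(g.sum(axis=0))

    out._backward = bwd
    return out


def gat_propagate(
    X: Tensor | np.ndarray,
    structure: GraphStructure,
    params: GatLayerParams,
    universal_softmax: bool = False,
) -> Tensor:
    """x_i^{l+1} = sum_r ReLU((1/K) sum_k sum_j phi_r^{ijk} W_k x_j)."""
    X = X if isinstance(X, Tensor) else Tensor(X)
    K = params.n_heads
    out = None
    heads_H = [X @ params.W[k] for k in range(K)]
    for r in RELATIONS:
        acc = None
        for k in range(K):
            phi = gat_attention(X, structure, params, r, k, universal_softmax)
            term = phi @ heads_H[k]
            acc = term if acc is None else acc + term
        term_r = ad.relu(acc * (1.0 / K))
        out = term_r if out is None else out + term_r
    return out


def encode_nodes(
    X0: Tensor | np.ndarray, structure: GraphStructure, params: EncoderParams
) -> tuple[Tensor, Tensor, Tensor]:
    """Three graph layers + first/third-layer fusion -> (X, X_D, X_T)."""
    X = X0 if isinstance(X0, Tensor) else Tensor(X0)
    outputs = []
    for kind, p in params.layers:
        if kind == "gcn":
            X = gcn_propagate(X, structure, p)
        else:
            X = gat_propagate(X, structure, p, params.config.universal_softmax)
        outputs.append(X)
    fused = ad.concat([outputs[0], outputs[2]], axis=1) @ params.fusion.W + params.fusion.b
    nd = structure.n_drugs
    X_D = ad.gather_rows(fused, np.arange(nd))
    X_T = ad.gather_rows(fused, np.arange(nd, structure.n))
    return fused, X_D, X_T


def bce_loss(u: Tensor, y: np.ndarray, eps: float = 1e-7) -> Tensor:
    """Binary cross-entropy of predicted probabilities against 0/1 labels."""
    y = np.asarray(y, dtype=float)
    u = ad.clip(u, eps, 1.0 - eps)
    ll = Tensor(y) * ad.log(u) + Tensor(1.0 - y) * ad.log(1.0 - u)
    return ad.mean(ll) * (-1.0)


def pair_scores(X_D: Tensor, X_T: Tensor, pairs: np.ndarray) -> Tensor:
    """Logistic-squashed inner products u_ij for (drug_idx, target_idx) rows."""
    di = ad.gather_rows(X_D, pairs[:, 0])
    tj = ad.gather_rows(X_T, pairs[:, 1])
    return ad.sigmoid(ad.tsum(di * tj, axis=1))


class JointRepresentationModel:
    """Sequence CNN + graph encoder trained end-to-end.

    ``feature_source`` produces the layer-0 node features (drugs stacked
    above targets); it owns the CNN parameters, so swapping in a frozen
    random matrix gives the "random node features" ablation and swapping
    the encoder for an identity projection gives the "no graph" ablation.
    """

    def __init__(
        self,
        feature_source: "NodeFeatureSource",
        structure: GraphStructure | None,
        encoder: EncoderParams | None,
        projection: FusionParams | None = None,
    ):
        if (structure is None) != (encoder is None):
            raise ValueError("structure and encoder must be supplied together")
        if encoder is None and projection is None:
            raise ValueError("need a projection when the graph encoder is ablated")
        self.feature_source = feature_source
        self.structure = structure
        self.encoder = encoder
        self.projection = projection

    def parameters(self) -> list[Tensor]:
        out = self.feature_source.tensors()
        if self.encoder is not None:
            out += self.encoder.tensors()
        elif self.projection is not None:
            out += self.projection.tensors()
        return out

    def forward(self) -> tuple[Tensor, Tensor]:
        X0 = self.feature_source.forward()
        if self.encoder is not None:
            _, X_D, X_T = encode_nodes(X0, self.structure, self.encoder)
            return X_D, X_T
        proj = X0 @ self.projection.W + self.projection.b
        nd = self.feature_source.n_drugs
        return ad.gather_rows(proj, np.arange(nd)), ad.gather_rows(
            proj, np.arange(nd, proj.shape[0])
        )

    def scores(self, pairs: np.ndarray) -> Tensor:
        X_D, X_T = self.forward()
        return pair_scores(X_D, X_T, pairs)

    def embeddings(self) -> tuple[np.ndarray, np.ndarray]:
        X_D, X_T = self.forward()
        return X_D.data.copy(), X_T.data.copy()


class NodeFeatureSource:
    """Interface: layer-0 node feature producer (drugs first)."""

    n_drugs: int

    def forward(self) -> Tensor:  # pragma: no cover - interface
        raise NotImplementedError

    def tensors(self) -> list[Tensor]:  # pragma: no cover - interface
        raise NotImplementedError


@dataclass
class TrainLogEntry:
    epoch: int
    train_loss: float
    val_loss: float


def train_encoder(
    model: JointRepresentationModel,
    train_pairs: np.ndarray,
    train_labels: np.ndarray,
    val_pairs: np.ndarray,
    val_labels: np.ndarray,
    lr: float = 1e-3,
    epochs: int = 200,
    patience: int = 20,
    callback: Callable[[TrainLogEntry], None] | None = None,
) -> list[TrainLogEntry]:
    """Adam minimization of the pair BCE; early stop on validation loss.

    Returns the per-epoch training log.  Raises on divergence (NaN loss).
    Fully deterministic given the model's initial parameters.
    """
    opt = ad.Adam(model.parameters(), lr=lr)
    log: list[TrainLogEntry] = []
    best = np.inf
    best_params = None
    bad = 0
    for epoch in range(epochs):
        opt.zero_grad()
        loss = bce_loss(model.scores(train_pairs), train_labels)
        if not np.isfinite(loss.data):
            raise RuntimeError(f"training diverged at epoch {epoch} (loss={loss.data})")
        loss.backward()
        opt.step()
        val = float(bce_loss(model.scores(val_pairs), val_labels).data)
        entry = TrainLogEntry(epoch, float(loss.data), val)
        log.append(entry)
        if callback:
            callback(entry)
        if val < best - 1e-6:
            best = val
            best_params = [p.data.copy() for p in model.parameters()]
            bad = 0
        else:
            bad += 1
            if bad >= patience:
                break
    if best_params is not None:
        for p, d in zip(model.parameters(), best_params):
            p.data = d
    return log
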