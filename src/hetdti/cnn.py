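"""Convolutional feature extractor for one-hot sequence embeddings.

The stack maps a channel x length one-hot sequence to a fixed-length
feature vector:

1. a *region embedding* layer — N window-3 valid convolutions over the
   one-hot input, no nonlinearity, length L -> L-2;
2. two *refinement* layers — full cross-channel window-3 convolutions with
   a rectifier applied to the input channels, each shrinking the length by
   2, mixing every region with its left and right neighbors;
3. *aggregation blocks* — stride-2 max pooling plus a residual
   two-convolution map theta, X_{t+1} = P(X_t) + theta(P(X_t)), halving
   the length per block;
4. a global max over the remaining valid positions, giving a vector of
   dimension N independent of input length.

Padding is handled by strict validity propagation: an output position is
valid only if every input position under its receptive field is valid, and
the global max ranges over valid positions only, so appending padding
columns can never change the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .sequences import SequenceEmbedding


@dataclass
class RegionConvParams:
    """N window-3 kernels over the one-hot channels, linear (no sigma).

    ``W`` has shape (3, C, N): position-in-window x input channel x kernel.
    The bias is one scalar per kernel, broadcast along the length axis.
    """

    W: Tensor
    b: Tensor

    @property
    def n_kernels(self) -> int:
        return self.W.shape[2]

    @property
    def w_flat(self) -> Tensor:
        """(3C, N) view consistent with window-stacking order."""
        W = self.W
        out = ad._node(W.data.reshape(-1, W.shape[2]), (W,))

        def bwd(g):
            if W.requires_grad:
                W._accumulate(g.reshape(W.shape))

        out._backward = bwd
        return out


@dataclass
class RefineConvParams:
    """Full cross-channel window-3 convolution with ReLU pre-activation.

    ``W`` has shape (3*N_in, N_out); the rectifier is applied to the input
    channels before the convolution sums over channels and window.
    """

    W: Tensor
    b: Tensor


@dataclass
class AggregationBlockParams:
    """Stride-2 max pooling + residual two-convolution map theta.

    theta is two window-1 convolutions (channel-mixing linear maps) with a
    rectifier between them, so the block output P(X) + theta(P(X)) keeps
    the pooled length and channel count.
    """

    W1: Tensor
    b1: Tensor
    W2: Tensor
    b2: Tensor


@dataclass
class CnnConfig:
    n_kernels: int = 64
    n_refine_layers: int = 2
    n_blocks: int = 2
    depthwise_refine: bool = False  # depthwise reading of the refinement conv

    @property
    def min_valid_length(self) -> int:
        """Shortest valid token count that survives every layer."""
        return 2 * self.n_refine_layers + 2 + 2 ** self.n_blocks


@dataclass
class CnnParams:
    region: RegionConvParams
    refine: list[RefineConvParams]
    blocks: list[AggregationBlockParams]
    config: CnnConfig = field(default_factory=CnnConfig)

    def tensors(self) -> list[Tensor]:
        out = [self.region.W, self.region.b]
        for r in self.refine:
            out += [r.W, r.b]
        for blk in self.blocks:
            out += [blk.W1, blk.b1, blk.W2, blk.b2]
        return out


def init_cnn_params(
    n_channels: int, config: CnnConfig | None = None, rng: np.random.Generator | None = None
) -> CnnParams:
    """He-style initialization of all extractor parameters."""
    config = config or CnnConfig()
    rng = rng or np.random.default_rng(0)
    N = config.n_kernels

    def w(shape, fan_in):
        return Tensor(rng.normal(0.0, np.sqrt(2.0 / fan_in), shape), requires_grad=True)

    def zeros(shape):
        return Tensor(np.zeros(shape), requires_grad=True)

    region = RegionConvParams(W=w((3, n_channels, N), 3 * n_channels), b=zeros(N))
    refine = [
        RefineConvParams(W=w((3 * N, N), 3 * N), b=zeros(N))
        for _ in range(config.n_refine_layers)
    ]
    blocks = [
        AggregationBlockParams(
            W1=w((N, N), N), b1=zeros(N), W2=w((N, N), N), b2=zeros(N)
        )
        for _ in range(config.n_blocks)
    ]
    return CnnParams(region, refine, blocks, config)


# ---------------------------------------------------------------------------
# Single-sequence dense surfaces (numpy in / numpy out)
# ---------------------------------------------------------------------------

def region_embed(X: np.ndarray, params: RegionConvParams) -> np.ndarray:
    """Region-embedding convolution of a dense C x L one-hot matrix.

    Returns the (L-2) x N response matrix: column i is kernel i's window-3
    valid convolution of X (linear, bias added, no nonlinearity).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a C x L matrix")
    if X.shape[1] < 3:
        raise ValueError(f"sequence length {X.shape[1]} < window size 3")
    xt = Tensor(X.T[None])  # (1, L, C)
    out = ad.windows3(xt) @ params.w_flat + params.b
    return out.data[0]


def conv_refine(
    Xp: np.ndarray, params: RefineConvParams, depthwise: bool = False
) -> np.ndarray:
    """Refinement convolution of an L x N matrix -> (L-2) x N.

    The rectifier hits the input channels first; the convolution then sums
    across window positions and (unless ``depthwise``) across all input
    channels.
    """
    out = _refine_t(Tensor(np.asarray(Xp, dtype=float)[None]), params, depthwise)
    return out.data[0]


def _refine_t(x: Tensor, params: RefineConvParams, depthwise: bool) -> Tensor:
    h = ad.windows3(ad.relu(x))  # (B, L-2, 3N)
    if depthwise:
        # zero the cross-channel couplings, keeping only kernel i on channel i
        N = params.b.shape[0]
        eye = np.tile(np.eye(N), (3, 1))
        masked = params.W * Tensor(eye)
        return h @ masked + params.b
    return h @ params.W + params.b


def aggregate_block(Xt: np.ndarray, params: AggregationBlockParams) -> np.ndarray:
    """One pooling/residual block: floor(L/2) x N from L x N."""
    out = _block_t(Tensor(np.asarray(Xt, dtype=float)[None]), params)
    return out.data[0]


def _block_t(x: Tensor, params: AggregationBlockParams) -> Tensor:
    pooled = ad.maxpool2(x)
    theta = ad.relu(pooled @ params.W1 + params.b1) @ params.W2 + params.b2
    return pooled + theta


def extract_features(emb: SequenceEmbedding, params: CnnParams) -> np.ndarray:
    """Full extractor on one embedding -> feature vector of length N."""
    tokens = emb.indices[None, :]
    valid = np.array([emb.n_valid])
    return forward_batch(tokens, valid, params).data[0]


# ---------------------------------------------------------------------------
# Batched differentiable path (token indices in, Tensor out)
# ---------------------------------------------------------------------------

def forward_batch(
    tokens: np.ndarray, n_valid: np.ndarray, params: CnnParams
) -> Tensor:
    """Run the extractor on a batch of index-encoded sequences.

    ``tokens``: (B, L) int vocabulary indices (arbitrary at padded
    positions); ``n_valid``: (B,) count of leading valid positions.
    Returns a (B, N) Tensor differentiable w.r.t. all parameters.
    """
    tokens = np.asarray(tokens)
    n_valid = np.asarray(n_valid)
    cfg = params.config
    if int(n_valid.min()) < cfg.min_valid_length:
        short = int(np.argmin(n_valid))
        raise ValueError(
            f"sequence #{short} has {int(n_valid[short])} valid positions; "
            f"the configured stack needs at least {cfg.min_valid_length}"
        )
    x = ad.onehot_window_embed(tokens, params.region.W) + params.region.b
    valid = n_valid - 2
    mask = _prefix_mask(valid, x.shape[1])
    x = x * Tensor(mask[..., None].astype(float))
    for r in params.refine:
        x = _refine_t(x, r, cfg.depthwise_refine)
        valid = valid - 2
        mask = _prefix_mask(valid, x.shape[1])
        x = x * Tensor(mask[..., None].astype(float))
    for blk in params.blocks:
        x = _block_t(x, blk)
        valid = valid // 2
        mask = _prefix_mask(valid, x.shape[1])
        x = x * Tensor(mask[..., None].astype(float))
    return ad.masked_max(x, mask[..., None], axis=-2)


def _prefix_mask(n_valid: np.ndarray, L: int) -> np.ndarray:
    return np.arange(L)[None, :] < n_valid[:, None]
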