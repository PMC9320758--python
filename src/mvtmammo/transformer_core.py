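"""Transformer building blocks: scaled dot-product attention, multi-head
self-attention, the GELU MLP, and the pre-LN residual block.

Local blocks (applied per view) and global blocks (applied to the
concatenated four-view sequence) share exactly this design; only the
sequence they see differs.  All functions accept either numpy arrays or
autodiff :class:`~mvtmammo._tensor.Tensor`s and return the same kind they
were given, so the identical code path serves inference, unit oracles and
training.

Shapes are written (..., T, d): any number of leading batch axes is
allowed and attention always acts over the second-to-last axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._tensor import Tensor, gelu, layer_norm, softmax

__all__ = [
    "BlockParams",
    "scaled_dot_product_attention",
    "multi_head_self_attention",
    "mlp_forward",
    "transformer_block_forward",
]


def _wrap(x) -> tuple[Tensor, bool]:
    if isinstance(x, Tensor):
        return x, True
    return Tensor(np.asarray(x, dtype=np.float32)), False


@dataclass
class BlockParams:
    """Trainable parameters of one transformer block.

    The QKV projection is fused: w_qkv maps d_embed -> 3*d_embed (with
    bias), followed by a d_embed -> d_embed output projection.  The MLP is
    d_embed -> r*d_embed (GELU) -> d_embed.  Two layer norms, pre-LN.
    """

    w_qkv: Tensor
    b_qkv: Tensor
    w_out: Tensor
    b_out: Tensor
    ln1_g: Tensor
    ln1_b: Tensor
    ln2_g: Tensor
    ln2_b: Tensor
    w_fc1: Tensor
    b_fc1: Tensor
    w_fc2: Tensor
    b_fc2: Tensor
    n_heads: int

    @classmethod
    def initialize(cls, rng: np.random.Generator, d_embed: int, n_heads: int,
                   mlp_ratio: int = 4, init_std: float = 0.02) -> "BlockParams":
        if d_embed % n_heads != 0:
            raise ValueError(f"d_embed={d_embed} not divisible by n_heads={n_heads}")
        hidden = mlp_ratio * d_embed

        def w(*shape):
            return Tensor(rng.normal(0.0, init_std, shape).astype(np.float32),
                          requires_grad=True)

        def zeros(*shape):
            return Tensor(np.zeros(shape, dtype=np.float32), requires_grad=True)

        def ones(*shape):
            return Tensor(np.ones(shape, dtype=np.float32), requires_grad=True)

        return cls(
            w_qkv=w(d_embed, 3 * d_embed), b_qkv=zeros(3 * d_embed),
            w_out=w(d_embed, d_embed), b_out=zeros(d_embed),
            ln1_g=ones(d_embed), ln1_b=zeros(d_embed),
            ln2_g=ones(d_embed), ln2_b=zeros(d_embed),
            w_fc1=w(d_embed, hidden), b_fc1=zeros(hidden),
            w_fc2=w(hidden, d_embed), b_fc2=zeros(d_embed),
            n_heads=n_heads,
        )

    @property
    def d_embed(self) -> int:
        return self.w_qkv.shape[0]

    def tensors(self) -> dict[str, Tensor]:
        return {name: getattr(self, name) for name in
                ("w_qkv", "b_qkv", "w_out", "b_out", "ln1_g", "ln1_b",
                 "ln2_g", "ln2_b", "w_fc1", "b_fc1", "w_fc2", "b_fc2")}


def scaled_dot_product_attention(Q, K, V):
    """Softmax(Q K^T / sqrt(d_k)) V.

    Returns (output, weights); each row of `weights` sums to one.  The
    softmax subtracts the row maximum, so large-magnitude scores stay
    finite.
    """
    q, q_t = _wrap(Q)
    k, k_t = _wrap(K)
    v, v_t = _wrap(V)
    if q.shape[-1] != k.shape[-1]:
        raise ValueError(f"Q and K must share d_k, got {q.shape[-1]} vs {k.shape[-1]}")
    if k.shape[-2] != v.shape[-2]:
        raise ValueError(f"K and V must share their row count, got "
                         f"{k.shape[-2]} vs {v.shape[-2]}")
    d_k = q.shape[-1]
    scores = (q @ k.swap_last()) * (1.0 / math.sqrt(d_k))
    weights = softmax(scores, axis=-1)
    out = weights @ v
    if q_t or k_t or v_t:
        return out, weights
    return out.data, weights.data


def _split_heads(x: Tensor, h: int) -> Tensor:
    """(..., T, d) -> (..., h, T, d/h)."""
    *lead, T, d = x.shape
    x = x.reshape(*lead, T, h, d // h)
    n = x.ndim
    axes = tuple(range(n - 3)) + (n - 2, n - 3, n - 1)
    return x.transpose(axes)


def _merge_heads(x: Tensor) -> Tensor:
    """(..., h, T, d/h) -> (..., T, d)."""
    n = x.ndim
    axes = tuple(range(n - 3)) + (n - 2, n - 3, n - 1)
    x = x.transpose(axes)
    *lead, T, h, dk = x.shape
    return x.reshape(*lead, T, h * dk)


def multi_head_self_attention(seq, params: BlockParams, n_heads: int | None = None):
    """h parallel attention heads over subspace projections, concatenated
    and projected back to d_embed.  Output shape equals input shape."""
    x, was_tensor = _wrap(seq)
    h = params.n_heads if n_heads is None else n_heads
    d = x.shape[-1]
    if d % h != 0:
        raise ValueError(f"d_embed={d} not divisible by h={h}")
    qkv = x @ params.w_qkv + params.b_qkv
    q = _split_heads(qkv[..., :d], h)
    k = _split_heads(qkv[..., d:2 * d], h)
    v = _split_heads(qkv[..., 2 * d:], h)
    heads, _ = scaled_dot_product_attention(q, k, v)
    out = _merge_heads(heads) @ params.w_out + params.b_out
    return out if was_tensor else out.data


def mlp_forward(seq, params: BlockParams):
    """Two fully-connected layers with an exact-GELU non-linearity."""
    x, was_tensor = _wrap(seq)
    if x.shape[-1] != params.w_fc1.shape[0]:
        raise ValueError(f"input width {x.shape[-1]} != d_embed {params.w_fc1.shape[0]}")
    out = gelu(x @ params.w_fc1 + params.b_fc1) @ params.w_fc2 + params.b_fc2
    return out if was_tensor else out.data


def transformer_block_forward(seq, params: BlockParams):
    """Pre-LN residual block: x + MSA(LN(x)), then + MLP(LN(.))."""
    x, was_tensor = _wrap(seq)
    attn_in = layer_norm(x, params.ln1_g, params.ln1_b)
    x = x + multi_head_self_attention(attn_in, params)
    mlp_in = layer_norm(x, params.ln2_g, params.ln2_b)
    x = x + mlp_forward(mlp_in, params)
    return x if was_tensor else x.data
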