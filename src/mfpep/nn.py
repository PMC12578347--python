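"""Neural building blocks used by the peptide predictor.

Linear maps, masked multi-head self-attention, a masked BiLSTM, same-length
1-D convolutions, layer normalization, a path-graph attention layer and the
Adam optimizer, all built on :mod:`mfpep.autodiff` tensors.

Masking convention: a mask is a plain ``(batch, length)`` float array with 1
at valid residue positions and 0 at padding. Layers re-apply the mask to
their outputs so padded rows stay identically zero, which is what makes the
model's predictions invariant to whatever values are stored at padded
positions.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

NEG_INF = -1e9


def glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[-2] if len(shape) > 1 else shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class ParamStore:
    """Named registry of trainable tensors with deterministic creation order."""

    def __init__(self) -> None:
        self._params: dict[str, Tensor] = {}

    def add(self, name: str, value: np.ndarray) -> Tensor:
        if name in self._params:
            raise ValueError(f"duplicate parameter name {name!r}")
        t = Tensor(value, requires_grad=True, name=name)
        self._params[name] = t
        return t

    def __getitem__(self, name: str) -> Tensor:
        return self._params[name]

    def __contains__(self, name: str) -> bool:
        return name in self._params

    def items(self):
        return self._params.items()

    def tensors(self) -> list[Tensor]:
        return list(self._params.values())

    def zero_grad(self) -> None:
        for t in self._params.values():
            t.grad = None

    def n_parameters(self) -> int:
        return int(sum(t.data.size for t in self._params.values()))

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self._params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            self._params[k].data = np.asarray(v, dtype=np.float64)


def linear(x: Tensor, W: Tensor, b: Tensor | None = None) -> Tensor:
    y = x @ W
    if b is not None:
        y = y + b
    return y


def apply_mask(x: Tensor, mask: np.ndarray) -> Tensor:
    """Zero rows at padded positions; mask is (B, L), x is (B, L, D)."""
    return x * mask[..., None]


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = (var + eps) ** -0.5
    return xc * inv * gamma + beta


def dropout(x: Tensor, rate: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or rate <= 0.0:
        return x
    keep = (rng.random(x.shape) >= rate).astype(np.float64) / (1.0 - rate)
    return x * keep


def multi_head_self_attention(
    x: Tensor,
    mask: np.ndarray,
    Wq: Tensor,
    Wk: Tensor,
    Wv: Tensor,
    Wo: Tensor,
    n_heads: int,
) -> Tensor:
    """Masked multi-head self-attention over (B, L, d) inputs.

    Padded key positions receive an additive -1e9 score before the softmax;
    padded query rows are zeroed on output.
    """
    B, L, d = x.shape
    dh = d // n_heads

    def split(t: Tensor) -> Tensor:
        return t.reshape(B, L, n_heads, dh).transpose(0, 2, 1, 3)  # (B,H,L,dh)

    q, k, v = split(x @ Wq), split(x @ Wk), split(x @ Wv)
    scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
    key_bias = (1.0 - mask)[:, None, None, :] * NEG_INF  # (B,1,1,L)
    attn = ad.softmax(scores + key_bias, axis=-1)
    out = attn @ v  # (B,H,L,dh)
    out = out.transpose(0, 2, 1, 3).reshape(B, L, d) @ Wo
    return apply_mask(out, mask)


def lstm_direction(
    x: Tensor,
    mask: np.ndarray,
    Wx: Tensor,
    Wh: Tensor,
    b: Tensor,
    reverse: bool,
) -> Tensor:
    """One direction of a masked LSTM; returns (B, L, H).

    The state update is gated by the mask so padded steps carry the state
    through unchanged: the output at valid positions does not depend on how
    much padding surrounds them.
    """
    B, L, D = x.shape
    H = Wh.shape[0]
    xz = (x.reshape(B * L, D) @ Wx).reshape(B, L, 4 * H)  # input part, one matmul
    h = Tensor(np.zeros((B, H)))
    c = Tensor(np.zeros((B, H)))
    steps = range(L - 1, -1, -1) if reverse else range(L)
    outs: list[Tensor | None] = [None] * L
    for t in steps:
        z = xz[:, t, :] + h @ Wh + b
        i = ad.sigmoid(z[:, 0 * H : 1 * H])
        f = ad.sigmoid(z[:, 1 * H : 2 * H])
        g = ad.tanh(z[:, 2 * H : 3 * H])
        o = ad.sigmoid(z[:, 3 * H : 4 * H])
        c_new = f * c + i * g
        h_new = o * ad.tanh(c_new)
        m = mask[:, t : t + 1]
        h = h_new * m + h * (1.0 - m)
        c = c_new * m + c * (1.0 - m)
        outs[t] = h * m
    return ad.stack(outs, axis=1)  # type: ignore[arg-type]


def bilstm(x: Tensor, mask: np.ndarray, params: ParamStore, prefix: str) -> Tensor:
    fw = lstm_direction(x, mask, params[f"{prefix}.fw.Wx"], params[f"{prefix}.fw.Wh"], params[f"{prefix}.fw.b"], reverse=False)
    bw = lstm_direction(x, mask, params[f"{prefix}.bw.Wx"], params[f"{prefix}.bw.Wh"], params[f"{prefix}.bw.b"], reverse=True)
    return ad.concat([fw, bw], axis=-1)


def conv1d_same(x: Tensor, W: Tensor, b: Tensor) -> Tensor:
    """Same-length 1-D convolution over the position axis.

    x: (B, L, Cin); W: (K, Cin, Cout). Implemented as a sum of shifted
    matrix products, which keeps the tape short for small kernels.
    """
    B, L, Cin = x.shape
    K = W.shape[0]
    pad = K // 2
    padded = ad.concat(
        [Tensor(np.zeros((B, pad, Cin))), x, Tensor(np.zeros((B, pad, Cin)))], axis=1
    )
    out = None
    for k in range(K):
        term = padded[:, k : k + L, :] @ W[k]
        out = term if out is None else out + term
    return out + b


def masked_max_pool(x: Tensor, mask: np.ndarray) -> Tensor:
    """Max over positions, ignoring padded rows. x: (B, L, C) -> (B, C)."""
    bias = (1.0 - mask)[..., None] * NEG_INF
    return (x + bias).max(axis=1)


def path_gat(
    h: Tensor,
    mask: np.ndarray,
    params: ParamStore,
    prefix: str,
    n_heads: int,
    return_attention: bool = False,
):
    """Multi-head graph attention over the residue chain (path) graph.

    Each valid position attends over its sequence neighbors {i-1, i, i+1}
    (self-loop included); attention logits use the standard additive form
    LeakyReLU(a_src . W h_i + a_dst . W h_j), normalized per neighborhood.
    Heads are concatenated; padded rows are zeroed.
    """
    B, L, d = h.shape
    head_outs = []
    coeffs = []
    m = mask  # (B, L)
    # neighbor validity per offset
    valid = {0: m}
    left = np.zeros_like(m)
    left[:, 1:] = m[:, :-1]
    right = np.zeros_like(m)
    right[:, :-1] = m[:, 1:]
    valid[-1], valid[1] = left * m, right * m

    for head in range(n_heads):
        W = params[f"{prefix}.h{head}.W"]
        a_src = params[f"{prefix}.h{head}.a_src"]  # (dh, 1)
        a_dst = params[f"{prefix}.h{head}.a_dst"]
        wh = h @ W  # (B, L, dh)
        s_src = (wh @ a_src)[..., 0]  # (B, L)
        s_dst = (wh @ a_dst)[..., 0]

        def shifted(t: Tensor, off: int) -> Tensor:
            dhh = t.shape[-1] if t.ndim == 3 else None
            if off == 0:
                return t
            if t.ndim == 2:
                zero = Tensor(np.zeros((B, 1)))
                if off == -1:
                    return ad.concat([zero, t[:, :-1]], axis=1)
                return ad.concat([t[:, 1:], zero], axis=1)
            zero = Tensor(np.zeros((B, 1, dhh)))
            if off == -1:
                return ad.concat([zero, t[:, :-1, :]], axis=1)
            return ad.concat([t[:, 1:, :], zero], axis=1)

        logits = []
        for off in (-1, 0, 1):
            e = ad.leaky_relu(s_src + shifted(s_dst, off), 0.2)
            e = e + (1.0 - valid[off]) * NEG_INF
            logits.append(e)
        alpha = ad.softmax(ad.stack(logits, axis=-1), axis=-1)  # (B, L, 3)
        agg = None
        for j, off in enumerate((-1, 0, 1)):
            term = alpha[:, :, j : j + 1] * shifted(wh, off)
            agg = term if agg is None else agg + term
        head_outs.append(agg)
        coeffs.append(alpha)
    out = ad.elu(ad.concat(head_outs, axis=-1))
    out = apply_mask(out, mask)
    if return_attention:
        return out, [c.numpy() for c in coeffs]
    return out


class Adam:
    """Adam optimizer with decoupled weight decay and gradient clipping.

    The decay keeps logits from running away into sigmoid saturation,
    which matters for dice-style objectives whose gradients vanish on
    confidently wrong entries; clipping bounds the global gradient norm.
    """

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0, clip_norm: float | None = None):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        scale = 1.0
        if self.clip_norm is not None:
            total = np.sqrt(sum(
                float((p.grad ** 2).sum()) for p in self.params if p.grad is not None
            ))
            if total > self.clip_norm:
                scale = self.clip_norm / (total + 1e-12)
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad * scale
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / (1 - self.b1**self.t)
            vh = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * (
                mh / (np.sqrt(vh) + self.eps) + self.weight_decay * p.data
            )

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
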