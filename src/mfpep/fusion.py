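"""Gated fusion of the aligned feature streams.

Each stream i carries a learnable gate vector g_i in R^d. The effective
gate sigma(g_i) lies in (0,1) elementwise; the fused representation is the
average of the gated streams:

    fused = (1/N) * sum_i F_i * sigmoid(g_i)

Streams of different native dimensionality are first aligned to the shared
model dimension d by per-stream affine projections. Gates therefore shrink
but never amplify, and with all gates at zero the fusion is simply half the
plain stream average.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class FusionError(ValueError):
    pass


@dataclasses.dataclass
class GateState:
    """Unconstrained gate parameters, one row per stream."""

    G: Tensor  # (N_streams, d)
    stream_order: tuple[str, ...]

    @property
    def effective(self) -> np.ndarray:
        """sigmoid(G), the gates actually applied; each entry in (0,1)."""
        return 1.0 / (1.0 + np.exp(-self.G.data))

    def to_table(self) -> dict[str, np.ndarray]:
        """Stream name -> effective gate vector, for inspection."""
        eff = self.effective
        return {name: eff[i].copy() for i, name in enumerate(self.stream_order)}


def init_gates(
    n_streams: int,
    d: int,
    seed: int,
    stream_order: Sequence[str] | None = None,
    scale: float = 0.1,
) -> GateState:
    """Uniform[-scale, scale] gate initialization: effective gates near 0.5."""
    if n_streams < 1 or d < 1:
        raise FusionError("n_streams and d must be positive")
    rng = np.random.default_rng(seed)
    G = Tensor(rng.uniform(-scale, scale, size=(n_streams, d)), requires_grad=True)
    order = tuple(stream_order) if stream_order else tuple(
        f"stream_{i}" for i in range(n_streams)
    )
    if len(order) != n_streams:
        raise FusionError("stream_order length must equal n_streams")
    return GateState(G=G, stream_order=order)


def align_streams(
    streams: Sequence[Tensor | np.ndarray],
    projections: Sequence[tuple[Tensor, Tensor]],
    mask: np.ndarray,
) -> list[Tensor]:
    """Affine-project each stream to the shared dimension and re-mask.

    ``projections[i]`` is the (W, b) pair for stream i, W of shape
    (native_dim_i, d). All streams must share the (batch, length) layout of
    ``mask``.
    """
    if len(streams) != len(projections):
        raise FusionError("one projection per stream is required")
    aligned = []
    m = np.asarray(mask, dtype=float)[..., None]
    for s, (W, b) in zip(streams, projections):
        t = ad.as_tensor(s)
        if t.shape[:-1] != m.shape[:-1]:
            raise FusionError(
                f"stream shape {t.shape} inconsistent with mask shape {mask.shape}"
            )
        aligned.append((t @ W + b) * m)
    return aligned


def gate_fuse(aligned: Sequence[Tensor], gates: GateState) -> Tensor:
    """Average of sigmoid-gated streams; differentiable in G and streams."""
    n = len(aligned)
    if gates.G.shape[0] != n:
        raise FusionError(
            f"gate matrix has {gates.G.shape[0]} rows for {n} streams"
        )
    g = ad.sigmoid(gates.G)  # (N, d)
    total = None
    for i, F in enumerate(aligned):
        term = F * g[i]
        total = term if total is None else total + term
    return total * (1.0 / n)


def sum_fuse(aligned: Sequence[Tensor]) -> Tensor:
    """Ablation variant: plain mean of the aligned streams, no gates."""
    total = None
    for F in aligned:
        total = F if total is None else total + F
    return total * (1.0 / len(aligned))
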