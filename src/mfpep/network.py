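"""The trainable multi-stream peptide function predictor.

Eight feature streams (token embeddings, a masked multi-head self-attention
view, five fuzzified biological property encodings, and a graph-attention
view of the residue chain graph) are aligned by per-stream affine
projections, fused by learnable sigmoid gates, and passed through a masked
BiLSTM, parallel multi-width 1-D convolutions with max-pooling over valid
positions, a feed-forward block with residual connection and layer
normalization, and a sigmoid MLP classifier with one output per functional
category.

Every module and every stream can be ablated from the config: module
ablation removes the component (gate fusion degrades to a plain mean of
the aligned streams), stream ablation feeds zeros in place of the stream.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import expit

from . import autodiff as ad
from . import nn
from .autodiff import Tensor
from .encoders import (
    ChainGraph,
    PropertyTable,
    build_chain_graph,
    encode_aac,
    encode_property_batch,
    load_property_table,
    positional_encoding,
)
from .fusion import GateState, align_streams, gate_fuse, sum_fuse
from .sequence_io import PeptideRecord, tokenize_batch

STREAMS = (
    "embedding", "attention", "aaindex", "paac", "pc6", "blosum62", "aac", "graph",
)
MODULES = ("gatconv", "bilstm", "gmf", "gate_fusion", "cnn", "ffn")
BIO_STREAMS = ("aaindex", "paac", "pc6", "blosum62", "aac")


class BuildError(ValueError):
    pass


class InferenceError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters; defaults are CPU-scale."""

    d_model: int = 32
    attn_heads: int = 4
    lstm_hidden: int = 32
    lstm_layers: int = 1
    conv_kernels: tuple[int, ...] = (3, 5, 7)
    conv_channels: int = 32
    ffn_dim: int = 128
    gat_heads: int = 2
    dropout: float = 0.2
    n_classes: int = 21
    max_len: int = 50
    seed: int = 0
    ablate_modules: frozenset[str] = frozenset()
    ablate_streams: frozenset[str] = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "conv_kernels", tuple(self.conv_kernels))
        object.__setattr__(self, "ablate_modules", frozenset(self.ablate_modules))
        object.__setattr__(self, "ablate_streams", frozenset(self.ablate_streams))
        if min(
            self.d_model, self.attn_heads, self.lstm_hidden, self.lstm_layers,
            self.ffn_dim, self.gat_heads, self.n_classes, self.max_len,
        ) < 1:
            raise BuildError("all architecture counts must be >= 1")
        if not self.conv_kernels:
            raise BuildError("conv_kernels must be non-empty")
        if any(k % 2 == 0 or k < 1 for k in self.conv_kernels):
            raise BuildError("conv kernel widths must be odd and positive")
        if not (0.0 <= self.dropout < 1.0):
            raise BuildError("dropout must lie in [0, 1)")
        if self.d_model % self.attn_heads != 0:
            raise BuildError("d_model must be divisible by attn_heads")
        if self.d_model % self.gat_heads != 0:
            raise BuildError("d_model must be divisible by gat_heads")
        bad = self.ablate_modules - set(MODULES)
        if bad:
            raise BuildError(f"unknown module ablation target(s) {sorted(bad)}")
        bad = self.ablate_streams - set(STREAMS)
        if bad:
            raise BuildError(f"unknown stream ablation target(s) {sorted(bad)}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["conv_kernels"] = list(self.conv_kernels)
        d["ablate_modules"] = sorted(self.ablate_modules)
        d["ablate_streams"] = sorted(self.ablate_streams)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        for key in ("ablate_modules", "ablate_streams"):
            if key in d:
                d[key] = frozenset(d[key])
        if "conv_kernels" in d:
            d["conv_kernels"] = tuple(d["conv_kernels"])
        return cls(**d)


@dataclasses.dataclass(frozen=True)
class EncodedBatch:
    """Pre-computed deterministic inputs for a list of records."""

    tokens: np.ndarray            # (N, L) ints
    mask: np.ndarray              # (N, L) float 0/1
    bio: dict[str, np.ndarray]    # stream name -> (N, L, native_dim)


def _standardized_lookup(tokens, mask, table: PropertyTable) -> np.ndarray:
    """Row lookup, z-scored using the table's own 20-residue statistics."""
    X = encode_property_batch(tokens, mask, table)
    M = table.matrix()
    mu, sd = M.mean(axis=0), M.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return ((X - mu) / sd) * mask[..., None]


class MFTPModel:
    """Model state: parameters plus the deterministic encoding resources."""

    def __init__(self, config: ModelConfig, tables: dict[str, PropertyTable] | None = None):
        self.config = config
        self.tables = tables or {
            "aaindex": load_property_table("aaindex"),
            "paac": load_property_table("paac"),
            "pc6": load_property_table("pc6"),
            "blosum62": load_property_table("blosum62"),
        }
        self.params = nn.ParamStore()
        self._build(np.random.default_rng(config.seed))
        self.pe = positional_encoding(config.max_len, config.d_model)

    # -- construction -----------------------------------------------------
    def _native_dims(self) -> dict[str, int]:
        d = self.config.d_model
        return {
            "embedding": d,
            "attention": d,
            "aaindex": self.tables["aaindex"].dim,
            "paac": self.tables["paac"].dim,
            "pc6": self.tables["pc6"].dim,
            "blosum62": self.tables["blosum62"].dim,
            "aac": 20,
            "graph": d,
        }

    def _build(self, rng: np.random.Generator) -> None:
        cfg = self.config
        P = self.params
        d = cfg.d_model
        P.add("embedding.W", rng.normal(0.0, 0.1, size=(21, d)))
        for w in ("Wq", "Wk", "Wv", "Wo"):
            P.add(f"attn.{w}", nn.glorot(rng, (d, d)))
        dh = d // cfg.gat_heads
        for h in range(cfg.gat_heads):
            P.add(f"gat.h{h}.W", nn.glorot(rng, (d, dh)))
            P.add(f"gat.h{h}.a_src", nn.glorot(rng, (dh, 1)))
            P.add(f"gat.h{h}.a_dst", nn.glorot(rng, (dh, 1)))
        dims = self._native_dims()
        for name in BIO_STREAMS:
            nd = dims[name]
            P.add(f"fuzz.{name}.c", np.zeros(nd))
            P.add(f"fuzz.{name}.log_sigma", np.zeros(nd))
        for name in STREAMS:
            P.add(f"proj.{name}.W", nn.glorot(rng, (dims[name], d)))
            P.add(f"proj.{name}.b", np.zeros(d))
        P.add("gates.G", rng.uniform(-0.1, 0.1, size=(len(STREAMS), d)))
        H = cfg.lstm_hidden
        for layer in range(cfg.lstm_layers):
            din = d if layer == 0 else 2 * H
            for direction in ("fw", "bw"):
                P.add(f"lstm{layer}.{direction}.Wx", nn.glorot(rng, (din, 4 * H)))
                P.add(f"lstm{layer}.{direction}.Wh", nn.glorot(rng, (H, 4 * H)))
                P.add(f"lstm{layer}.{direction}.b", np.zeros(4 * H))
        trunk_dim = d if "bilstm" in cfg.ablate_modules else 2 * H
        for k in cfg.conv_kernels:
            P.add(f"conv{k}.W", nn.glorot(rng, (k, trunk_dim, cfg.conv_channels)))
            P.add(f"conv{k}.b", np.zeros(cfg.conv_channels))
        pooled = (
            trunk_dim
            if "cnn" in cfg.ablate_modules
            else len(cfg.conv_kernels) * cfg.conv_channels
        )
        P.add("ffn.W1", nn.glorot(rng, (pooled, cfg.ffn_dim)))
        P.add("ffn.b1", np.zeros(cfg.ffn_dim))
        P.add("ffn.W2", nn.glorot(rng, (cfg.ffn_dim, pooled)))
        P.add("ffn.b2", np.zeros(pooled))
        P.add("ffn.ln.gamma", np.ones(pooled))
        P.add("ffn.ln.beta", np.zeros(pooled))
        hidden = max(pooled // 2, cfg.n_classes)
        P.add("clf.W1", nn.glorot(rng, (pooled, hidden)))
        P.add("clf.b1", np.zeros(hidden))
        P.add("clf.W2", nn.glorot(rng, (hidden, cfg.n_classes)))
        P.add("clf.b2", np.zeros(cfg.n_classes))
        self._pooled_dim = pooled

    def n_parameters(self) -> int:
        return self.params.n_parameters()

    # -- encoding ---------------------------------------------------------
    def encode_records(self, records: Sequence[PeptideRecord]) -> EncodedBatch:
        tokens, mask = tokenize_batch(records, self.config.max_len)
        maskf = mask.astype(float)
        bio = {
            name: _standardized_lookup(tokens, maskf, self.tables[name])
            for name in ("aaindex", "paac", "pc6", "blosum62")
        }
        aac = np.stack([encode_aac(r) for r in records])  # (N, 20)
        bio["aac"] = aac[:, None, :] * maskf[..., None]   # tiled over positions
        return EncodedBatch(tokens=tokens, mask=maskf, bio=bio)

    # -- forward ----------------------------------------------------------
    def _fuzzify(self, name: str, x: np.ndarray, mask: np.ndarray) -> Tensor:
        c = self.params[f"fuzz.{name}.c"]
        sigma = ad.exp(self.params[f"fuzz.{name}.log_sigma"])
        z = (ad.as_tensor(x) - c) / sigma
        return ad.exp(z * z * -0.5) * mask[..., None]

    def _streams(self, batch: EncodedBatch, training: bool,
                 rng: np.random.Generator | None) -> list[Tensor]:
        cfg = self.config
        mask = batch.mask
        B, L = mask.shape
        emb = nn.apply_mask(
            ad.embedding_lookup(self.params["embedding.W"], batch.tokens), mask
        )
        x_pos = nn.apply_mask(emb + self.pe[None, :, :], mask)
        streams: dict[str, Tensor] = {"embedding": emb}
        streams["attention"] = nn.multi_head_self_attention(
            x_pos, mask, self.params["attn.Wq"], self.params["attn.Wk"],
            self.params["attn.Wv"], self.params["attn.Wo"], cfg.attn_heads,
        )
        for name in BIO_STREAMS:
            x = batch.bio[name]
            if "gmf" in cfg.ablate_modules:
                streams[name] = ad.as_tensor(x)
            else:
                streams[name] = self._fuzzify(name, x, mask)
        if "gatconv" in cfg.ablate_modules:
            streams["graph"] = emb
        else:
            streams["graph"] = nn.path_gat(emb, mask, self.params, "gat", cfg.gat_heads)
        ordered = []
        dims = self._native_dims()
        for name in STREAMS:
            if name in cfg.ablate_streams:
                ordered.append(Tensor(np.zeros((B, L, dims[name]))))
            else:
                ordered.append(streams[name])
        return ordered

    def forward(
        self,
        batch: EncodedBatch,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        """Logits of shape (batch, n_classes)."""
        cfg = self.config
        mask = batch.mask
        streams = self._streams(batch, training, rng)
        projections = [
            (self.params[f"proj.{n}.W"], self.params[f"proj.{n}.b"]) for n in STREAMS
        ]
        aligned = align_streams(streams, projections, mask)
        if "gate_fusion" in cfg.ablate_modules:
            fused = sum_fuse(aligned)
        else:
            gates = GateState(G=self.params["gates.G"], stream_order=STREAMS)
            fused = gate_fuse(aligned, gates)
        if training and rng is not None:
            fused = nn.dropout(fused, cfg.dropout, rng, training)
        h = fused
        if "bilstm" not in cfg.ablate_modules:
            for layer in range(cfg.lstm_layers):
                h = nn.bilstm(h, mask, self.params, f"lstm{layer}")
        if "cnn" in cfg.ablate_modules:
            pooled = nn.masked_max_pool(h, mask)
        else:
            pooled = ad.concat(
                [
                    nn.masked_max_pool(
                        ad.relu(
                            nn.conv1d_same(
                                h, self.params[f"conv{k}.W"], self.params[f"conv{k}.b"]
                            )
                        ),
                        mask,
                    )
                    for k in cfg.conv_kernels
                ],
                axis=-1,
            )
        if "ffn" not in cfg.ablate_modules:
            inner = ad.relu(pooled @ self.params["ffn.W1"] + self.params["ffn.b1"])
            if training and rng is not None:
                inner = nn.dropout(inner, cfg.dropout, rng, training)
            pooled = nn.layer_norm(
                pooled + (inner @ self.params["ffn.W2"] + self.params["ffn.b2"]),
                self.params["ffn.ln.gamma"], self.params["ffn.ln.beta"],
            )
        hcls = ad.relu(pooled @ self.params["clf.W1"] + self.params["clf.b1"])
        return hcls @ self.params["clf.W2"] + self.params["clf.b2"]

    # -- inference --------------------------------------------------------
    def predict_proba(self, records: Sequence[PeptideRecord], batch_size: int = 256) -> np.ndarray:
        out = []
        for i in range(0, len(records), batch_size):
            batch = self.encode_records(records[i : i + batch_size])
            logits = self.forward(batch, training=False)
            out.append(expit(logits.numpy()))
        return np.vstack(out)

    def graph_stream(
        self,
        graph: ChainGraph,
        node_features: np.ndarray,
        return_attention: bool = False,
    ):
        """Graph-attention output for one chain graph, re-padded to max_len.

        ``node_features`` has one row per valid position (n_nodes, d_model).
        """
        if graph.n_nodes == 0:
            raise InferenceError("cannot run the graph stream on an empty graph")
        L = self.config.max_len
        if node_features.shape != (graph.n_nodes, self.config.d_model):
            raise InferenceError(
                f"node features must be (n_nodes, d_model), got {node_features.shape}"
            )
        feats = np.zeros((1, L, self.config.d_model))
        feats[0, : graph.n_nodes] = node_features
        mask = np.zeros((1, L))
        mask[0, : graph.n_nodes] = 1.0
        result = nn.path_gat(
            Tensor(feats), mask, self.params, "gat", self.config.gat_heads,
            return_attention=return_attention,
        )
        if return_attention:
            out, coeffs = result
            return out.numpy()[0], [c[0] for c in coeffs]
        return result.numpy()[0]

    # -- persistence ------------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(
            path,
            __config__=json.dumps(self.config.to_dict()),
            **self.params.state_dict(),
        )

    @classmethod
    def load(cls, path: str | Path) -> "MFTPModel":
        with np.load(path, allow_pickle=False) as data:
            config = ModelConfig.from_dict(json.loads(str(data["__config__"])))
            model = cls(config)
            model.params.load_state_dict(
                {k: data[k] for k in data.files if k != "__config__"}
            )
        return model


def predict_labels(
    logits: np.ndarray | Tensor,
    threshold: float = 0.5,
    names: Sequence[str] | None = None,
) -> list[set]:
    """Label subsets from logits: class c assigned iff sigmoid(logit) > t.

    With the default threshold 0.5 this is the strict sign rule logit > 0.
    """
    if not (0.0 < threshold < 1.0):
        raise InferenceError("threshold must lie in (0, 1)")
    z = logits.numpy() if isinstance(logits, Tensor) else np.asarray(logits)
    p = expit(z)
    out = []
    for row in np.atleast_2d(p):
        idx = np.nonzero(row > threshold)[0]
        out.append({names[i] for i in idx} if names else set(idx.tolist()))
    return out
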