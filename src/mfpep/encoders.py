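"""Per-sequence feature streams for peptide sequences.

Eight streams feed the predictor: learned token embeddings, a multi-head
self-attention view of the position-encoded embeddings, five biological
property encodings (AAindex-style, PAAC, PC6, BLOSUM62 rows, amino-acid
composition) passed through Gaussian fuzzification, and a graph-attention
view of the residue chain graph. This module provides the deterministic
parts: property tables, positional encodings, composition, fuzzification
and the chain graph itself; the learned streams live in
:mod:`mfpep.network`.

Property tables are plain TSV resources (one row per residue). The PAAC,
PC6 and AAindex-style tables are column-standardized (z-scored over the 20
residues) at load time so the Gaussian membership functions start from
comparable scales; BLOSUM62 rows are the canonical log-odds scores taken
verbatim from the substitution matrix shipped with Biopython.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np

from .sequence_io import AMINO_ACIDS, PeptideRecord, TokenizedSequence, ValidationError

BLOSUM62_DIM = 23  # 20 standard residues + B, Z, X columns


class EncodingError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class PropertyTable:
    """Map from each standard residue to a fixed-length property vector."""

    name: str
    columns: tuple[str, ...]
    rows: dict[str, np.ndarray]

    def __post_init__(self):
        if set(self.rows) != set(AMINO_ACIDS):
            missing = set(AMINO_ACIDS) - set(self.rows)
            raise EncodingError(f"table {self.name!r} missing residues {sorted(missing)}")
        for aa, v in self.rows.items():
            if v.shape != (len(self.columns),) or not np.all(np.isfinite(v)):
                raise EncodingError(f"table {self.name!r}: bad row for {aa!r}")

    @property
    def dim(self) -> int:
        return len(self.columns)

    def matrix(self) -> np.ndarray:
        """(20, dim) matrix in alphabetical residue order."""
        return np.stack([self.rows[aa] for aa in AMINO_ACIDS])


def _load_tsv_table(name: str, path: Path | None, standardize: bool) -> PropertyTable:
    if path is None:
        ref = resources.files("mfpep.data").joinpath(f"{name}.tsv")
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    lines = [l for l in text.splitlines() if l.strip() and not l.startswith("#")]
    header = lines[0].split("\t")
    columns = tuple(header[1:])
    rows: dict[str, np.ndarray] = {}
    for line in lines[1:]:
        parts = line.split("\t")
        rows[parts[0]] = np.array([float(x) for x in parts[1:]], dtype=float)
    if standardize:
        M = np.stack([rows[aa] for aa in AMINO_ACIDS])
        mu, sd = M.mean(axis=0), M.std(axis=0)
        sd[sd == 0] = 1.0
        rows = {aa: (rows[aa] - mu) / sd for aa in AMINO_ACIDS}
    return PropertyTable(name=name, columns=columns, rows=rows)


def _blosum62_table() -> PropertyTable:
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load("BLOSUM62")
    cols = [c for c in mat.alphabet if c != "*"]
    assert len(cols) == BLOSUM62_DIM
    rows = {
        aa: np.array([float(mat[aa, c]) for c in cols], dtype=float)
        for aa in AMINO_ACIDS
    }
    return PropertyTable(name="blosum62", columns=tuple(cols), rows=rows)


def load_property_table(
    name: str, path: str | Path | None = None, standardize: bool | None = None
) -> PropertyTable:
    """Load one of the named property tables.

    ``aaindex``, ``paac`` and ``pc6`` come from TSV resources (or a
    user-supplied ``path`` with the same layout) and are z-scored per
    column by default; ``blosum62`` comes from Biopython and is never
    standardized.
    """
    name = name.lower()
    if name == "blosum62":
        if standardize:
            raise EncodingError("BLOSUM62 rows are used verbatim")
        return _blosum62_table()
    fname = {"aaindex": "aaindex_reduced", "paac": "paac", "pc6": "pc6"}.get(name)
    if fname is None:
        raise EncodingError(f"unknown property table {name!r}")
    return _load_tsv_table(fname, Path(path) if path else None, True if standardize is None else standardize)


def positional_encoding(max_len: int, d_model: int) -> np.ndarray:
    """Sinusoidal positional encoding matrix of shape (max_len, d_model).

    Entry (pos, 2i) = sin(pos / 10000^(2i/d_model)) and entry (pos, 2i+1)
    = cos(pos / 10000^(2i/d_model)).
    """
    if max_len < 1:
        raise EncodingError("max_len must be >= 1")
    if d_model < 2 or d_model % 2 != 0:
        raise EncodingError(f"d_model must be even and >= 2, got {d_model}")
    pos = np.arange(max_len)[:, None]
    i = np.arange(d_model // 2)[None, :]
    angle = pos / np.power(10000.0, 2 * i / d_model)
    pe = np.zeros((max_len, d_model))
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle)
    return pe


def encode_property_stream(
    tokens: TokenizedSequence, table: PropertyTable
) -> np.ndarray:
    """Per-position lookup of table rows; zero rows at padded positions."""
    out = np.zeros((tokens.tokens.shape[0], table.dim))
    for j, (tok, valid) in enumerate(zip(tokens.tokens, tokens.mask)):
        if not valid:
            continue
        aa = AMINO_ACIDS[tok - 1]
        out[j] = table.rows[aa]
    return out


def encode_property_batch(
    tokens: np.ndarray, mask: np.ndarray, table: PropertyTable
) -> np.ndarray:
    """(N, L) token/mask arrays -> (N, L, dim) lookup, vectorized."""
    M = np.vstack([np.zeros((1, table.dim)), table.matrix()])  # row 0 = padding
    return M[tokens] * mask[..., None]


def encode_aac(record: PeptideRecord | str) -> np.ndarray:
    """Amino-acid composition: 20 residue frequencies, alphabetical order."""
    seq = record.sequence if isinstance(record, PeptideRecord) else record
    if len(seq) == 0:
        raise ValidationError("empty sequence has no composition")
    counts = np.zeros(20)
    for aa in seq.upper():
        idx = AMINO_ACIDS.find(aa)
        if idx < 0:
            raise EncodingError(f"non-standard residue {aa!r} in composition")
        counts[idx] += 1
    return counts / counts.sum()


@dataclasses.dataclass(frozen=True)
class FuzzifierParams:
    """Centers and widths of per-dimension Gaussian membership functions."""

    centers: np.ndarray
    widths: np.ndarray
    trainable: bool = True

    def __post_init__(self):
        c = np.atleast_1d(np.asarray(self.centers, dtype=float))
        s = np.atleast_1d(np.asarray(self.widths, dtype=float))
        if c.shape != s.shape:
            raise EncodingError("centers and widths must have equal length")
        if np.any(s <= 0):
            raise EncodingError("fuzzifier widths must be strictly positive")
        object.__setattr__(self, "centers", c)
        object.__setattr__(self, "widths", s)


def gmf_fuzzify(
    values: np.ndarray, params: FuzzifierParams, mask: np.ndarray | None = None
) -> np.ndarray:
    """Gaussian membership f(x) = exp(-(x-c)^2 / (2 sigma^2)) per dimension.

    Outputs lie in (0, 1]; rows at masked positions are reset to zero.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[-1] != params.centers.shape[0]:
        raise EncodingError(
            f"fuzzifier dimension {params.centers.shape[0]} does not match "
            f"feature dimension {values.shape[-1]}"
        )
    z = (values - params.centers) / params.widths
    out = np.exp(-0.5 * z * z)
    if mask is not None:
        out = out * np.asarray(mask, dtype=float)[..., None]
    return out


@dataclasses.dataclass(frozen=True)
class ChainGraph:
    """Path graph over the valid residues of a tokenized sequence."""

    n_nodes: int
    edges: tuple[tuple[int, int], ...]

    def adjacency_matrix(self) -> np.ndarray:
        A = np.zeros((self.n_nodes, self.n_nodes), dtype=int)
        for u, v in self.edges:
            A[u, v] = 1
        return A


def build_chain_graph(tokens: TokenizedSequence) -> ChainGraph:
    """Bidirectional edges between consecutive valid residues."""
    n = tokens.length
    if n == 0:
        raise EncodingError("cannot build a chain graph with zero valid positions")
    edges: list[tuple[int, int]] = []
    for j in range(n - 1):
        edges.append((j, j + 1))
        edges.append((j + 1, j))
    return ChainGraph(n_nodes=n, edges=tuple(edges))
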