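"""Reading, writing and tokenizing multi-label peptide data.

The on-disk format is a multi-label FASTA dialect: the header line carries
an identifier and an optional comma-separated label list after a single
``|``, e.g. ``>pep1|AMP,ACP``. Sequences use the 20 standard amino acids.
An empty label field (``>pep1|`` or no ``|`` at all) is only accepted in
prediction mode, where labels are what the model is asked to produce.

Tokenization assigns each residue its alphabetical rank among the standard
amino acids (A=1, C=2, ..., Y=20), pads with zeros to a fixed length, and
keeps a boolean mask so downstream layers can ignore padding.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

# Alphabetical order of the 20 standard amino acids; rank = index + 1.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
TOKEN_OF = {aa: i + 1 for i, aa in enumerate(AMINO_ACIDS)}
NON_STANDARD = set("BJOUXZ")

#: The 21 functional categories of the therapeutic-peptide benchmark.
DEFAULT_LABELS = (
    "AMP", "ABP", "ACP", "ACVP", "ADP", "AEP", "AFP", "AHIVP", "AHP", "AIP",
    "AMRSAP", "APP", "ATP", "AVP", "BBP", "BIP", "CPP", "DPPIP", "QSP",
    "SBP", "THP",
)

ResiduePolicy = Literal["strict", "mask"]


class ParseError(ValueError):
    """Malformed input file; carries the offending line number."""


class ValidationError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class LabelSpace:
    """Ordered, fixed label vocabulary for one run."""

    names: tuple[str, ...] = DEFAULT_LABELS

    def __post_init__(self):
        if len(self.names) < 1:
            raise ValidationError("label space must contain at least one name")
        if len(set(self.names)) != len(self.names):
            raise ValidationError("label names must be unique")
        object.__setattr__(self, "names", tuple(self.names))

    @property
    def size(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def to_matrix(self, records: Sequence["PeptideRecord"]) -> np.ndarray:
        """Binary (N, M) label matrix in label-space order."""
        idx = {n: i for i, n in enumerate(self.names)}
        Y = np.zeros((len(records), self.size), dtype=np.int8)
        for r, rec in enumerate(records):
            for lab in rec.labels:
                Y[r, idx[lab]] = 1
        return Y


@dataclasses.dataclass(frozen=True)
class PeptideRecord:
    """One peptide sequence with its identifier and label subset."""

    id: str
    sequence: str
    labels: frozenset[str] = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "labels", frozenset(self.labels))


@dataclasses.dataclass(frozen=True)
class TokenizedSequence:
    tokens: np.ndarray  # (max_len,) ints in 0..20; 0 = padding
    mask: np.ndarray    # (max_len,) bool; True at valid positions

    @property
    def length(self) -> int:
        return int(self.mask.sum())


def validate_record(
    record: PeptideRecord,
    label_space: LabelSpace,
    *,
    min_len: int = 5,
    max_len: int = 50,
    policy: ResiduePolicy = "strict",
    allow_unlabeled: bool = False,
) -> None:
    """Raise ValidationError when a record violates the data contract."""
    n = len(record.sequence)
    if not (min_len <= n <= max_len):
        raise ValidationError(
            f"record {record.id!r}: length {n} outside [{min_len}, {max_len}]"
        )
    for j, aa in enumerate(record.sequence):
        if aa in TOKEN_OF:
            continue
        if policy == "strict" or aa not in NON_STANDARD:
            raise ValidationError(
                f"record {record.id!r}: non-standard residue {aa!r} at position {j + 1}"
            )
    unknown = set(record.labels) - set(label_space.names)
    if unknown:
        raise ValidationError(
            f"record {record.id!r}: unknown label(s) {sorted(unknown)}"
        )
    if not record.labels and not allow_unlabeled:
        raise ValidationError(
            f"record {record.id!r}: empty label set outside prediction mode"
        )


def read_labeled_fasta(
    path: str | Path,
    label_space: LabelSpace | None = None,
    *,
    policy: ResiduePolicy = "strict",
    prediction_mode: bool = False,
    min_len: int = 5,
    max_len: int = 50,
) -> list[PeptideRecord]:
    """Read the multi-label FASTA dialect.

    Headers look like ``>id|LAB1,LAB2``; the label field may be empty (or
    the ``|`` absent) only when ``prediction_mode`` is true. Records that
    violate the residue policy or length bounds are rejected with their
    line numbers.
    """
    label_space = label_space or LabelSpace()
    records: list[PeptideRecord] = []
    header: tuple[str, frozenset[str], int] | None = None
    seq_parts: list[str] = []

    def flush() -> None:
        if header is None:
            return
        rid, labels, lineno = header
        seq = "".join(seq_parts).upper()
        rec = PeptideRecord(rid, seq, labels)
        try:
            validate_record(
                rec, label_space, min_len=min_len, max_len=max_len,
                policy=policy, allow_unlabeled=prediction_mode,
            )
        except ValidationError as exc:
            raise ValidationError(f"line {lineno}: {exc}") from None
        records.append(rec)

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                seq_parts = []
                body = line[1:].strip()
                if not body:
                    raise ParseError(f"line {lineno}: empty FASTA header")
                if "|" in body:
                    rid, _, labfield = body.partition("|")
                    rid = rid.strip()
                    labels = frozenset(
                        s.strip() for s in labfield.split(",") if s.strip()
                    )
                else:
                    rid, labels = body.strip(), frozenset()
                if not rid:
                    raise ParseError(f"line {lineno}: header without identifier")
                if not labels and not prediction_mode:
                    raise ParseError(
                        f"line {lineno}: header {rid!r} has no labels outside "
                        "prediction mode"
                    )
                header = (rid, labels, lineno)
            else:
                if header is None:
                    raise ParseError(f"line {lineno}: sequence before any header")
                seq_parts.append(line)
    flush()
    return records


def infer_label_space(path: str | Path) -> LabelSpace:
    """Label space from the labels actually present in a file's headers.

    Falls back to the default 21-category space when the file carries no
    labels (e.g. prediction inputs).
    """
    labels: set[str] = set()
    with open(path) as fh:
        for line in fh:
            if line.startswith(">") and "|" in line:
                _, _, labfield = line[1:].strip().partition("|")
                labels.update(s.strip() for s in labfield.split(",") if s.strip())
    return LabelSpace(tuple(sorted(labels))) if labels else LabelSpace()


def write_labeled_fasta(path: str | Path, records: Iterable[PeptideRecord]) -> None:
    with open(path, "w") as fh:
        for rec in records:
            labels = ",".join(sorted(rec.labels))
            fh.write(f">{rec.id}|{labels}\n{rec.sequence}\n")


def tokenize(
    record: PeptideRecord | str,
    max_len: int = 50,
    *,
    policy: ResiduePolicy = "strict",
    on_long: Literal["reject", "truncate"] = "reject",
) -> TokenizedSequence:
    """Map a sequence to integer tokens (alphabetical rank) plus a mask."""
    seq = record.sequence if isinstance(record, PeptideRecord) else record
    seq = seq.upper()
    if len(seq) == 0:
        raise ValidationError("empty sequence cannot be tokenized")
    if len(seq) > max_len:
        if on_long == "reject":
            raise ValidationError(
                f"sequence length {len(seq)} exceeds max_len={max_len}"
            )
        import warnings

        warnings.warn(f"truncating sequence of length {len(seq)} to {max_len}")
        seq = seq[:max_len]
    tokens = np.zeros(max_len, dtype=np.int64)
    mask = np.zeros(max_len, dtype=bool)
    for j, aa in enumerate(seq):
        tok = TOKEN_OF.get(aa)
        if tok is None:
            if policy == "mask" and aa in NON_STANDARD:
                continue  # token 0, mask False
            raise ValidationError(f"non-standard residue {aa!r} at position {j + 1}")
        tokens[j] = tok
        mask[j] = True
    return TokenizedSequence(tokens=tokens, mask=mask)


def tokenize_batch(
    records: Sequence[PeptideRecord], max_len: int = 50, **kw
) -> tuple[np.ndarray, np.ndarray]:
    """Stack tokenized records into (N, max_len) token and mask arrays."""
    toks = [tokenize(r, max_len, **kw) for r in records]
    return (
        np.stack([t.tokens for t in toks]),
        np.stack([t.mask for t in toks]),
    )


def split_dataset(
    records: Sequence[PeptideRecord], fraction: float, seed: int
) -> tuple[list[PeptideRecord], list[PeptideRecord]]:
    """Seeded random split into train (floor(fraction*N)) and test lists."""
    if not records:
        raise ValidationError("cannot split an empty record list")
    if not (0.0 < fraction < 1.0):
        raise ValidationError(f"fraction must lie in (0, 1), got {fraction}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    n_train = int(np.floor(fraction * len(records)))
    train = [records[i] for i in order[:n_train]]
    test = [records[i] for i in order[n_train:]]
    return train, test


def write_predictions(
    path: str | Path,
    records: Sequence[PeptideRecord],
    probabilities: np.ndarray,
    label_space: LabelSpace,
    threshold: float = 0.5,
) -> None:
    """Tab-separated prediction table: id, per-class probability, binary call."""
    probabilities = np.asarray(probabilities)
    with open(path, "w") as fh:
        header = ["id"] + [f"p_{n}" for n in label_space.names] + [
            f"call_{n}" for n in label_space.names
        ]
        fh.write("\t".join(header) + "\n")
        for rec, p in zip(records, probabilities):
            calls = (p > threshold).astype(int)
            row = [rec.id] + [f"{x:.6f}" for x in p] + [str(c) for c in calls]
            fh.write("\t".join(row) + "\n")
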