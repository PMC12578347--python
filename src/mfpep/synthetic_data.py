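"""Synthetic motif-labeled peptide datasets.

Each functional class is tied to a distinct short sequence motif; a record
carries label c exactly when its sequence contains motif c (before
optional label-flip noise). This gives a known ground truth so that
end-to-end label-recovery experiments are meaningful, while emulating the
structural features of real therapeutic-peptide benchmarks: lengths 5-50,
strong per-class imbalance, and a minority of multi-label records.

Label placement uses exact per-class counts (``round(prevalence_c * n)``
records get motif c), followed by a donor-swap repair pass that moves one
motif from a multi-label record to each unlabeled record whenever the
total number of label slots is at least n. Because the default prevalence
ladder is normalized to sum to ``1 + multi_label_rate``, the repaired
dataset ends up with every record labeled and a multi-label fraction close
to the requested rate. When the user supplies prevalences summing to less
than 1 (e.g. a two-class imbalance study), unlabeled records remain and
are emitted as valid all-negative examples.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .sequence_io import AMINO_ACIDS, LabelSpace, PeptideRecord


class SyntheticConfigError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class SyntheticConfig:
    n_sequences: int = 2000
    n_classes: int = 8
    motif_length: int = 4
    length_range: tuple[int, int] = (5, 50)
    prevalence: tuple[float, ...] | None = None  # default: geometric ladder
    multi_label_rate: float = 0.15
    label_noise: float = 0.0
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.length_range
        if not (5 <= lo <= hi <= 50):
            raise SyntheticConfigError("length_range must lie within [5, 50]")
        if self.n_classes < 1 or self.n_sequences < 1:
            raise SyntheticConfigError("counts must be positive")
        if self.motif_length < 1 or self.motif_length > lo:
            raise SyntheticConfigError("motif_length must fit the shortest sequence")
        if not (0.0 <= self.multi_label_rate < 1.0):
            raise SyntheticConfigError("multi_label_rate must lie in [0, 1)")
        if not (0.0 <= self.label_noise < 1.0):
            raise SyntheticConfigError("label_noise must lie in [0, 1)")
        if self.prevalence is not None:
            p = tuple(float(x) for x in self.prevalence)
            if len(p) != self.n_classes:
                raise SyntheticConfigError("one prevalence per class is required")
            if any(not (0.0 < x < 1.0) for x in p):
                raise SyntheticConfigError("prevalences must lie in (0, 1)")
            object.__setattr__(self, "prevalence", p)

    def resolved_prevalence(self) -> np.ndarray:
        """Explicit prevalences, or an imbalanced geometric ladder.

        The default ladder spans about a 20:1 majority:minority ratio and
        is normalized so that total label slots average 1 + multi_label_rate
        per record, which makes the post-repair multi-label fraction land
        near the requested rate.
        """
        if self.prevalence is not None:
            return np.asarray(self.prevalence, dtype=float)
        ladder = np.geomspace(1.0, 1.0 / 20.0, self.n_classes)
        ladder *= (1.0 + self.multi_label_rate) / ladder.sum()
        return np.minimum(ladder, 0.95)


def _draw_motifs(rng: np.random.Generator, n: int, length: int) -> list[str]:
    """Distinct motifs, none a substring of another."""
    for _attempt in range(100):
        motifs = [
            "".join(rng.choice(list(AMINO_ACIDS), size=length)) for _ in range(n)
        ]
        ok = all(
            motifs[i] not in motifs[j]
            for i in range(n)
            for j in range(n)
            if i != j
        )
        if ok:
            return motifs
    raise SyntheticConfigError(
        "could not draw substring-free motifs after 100 attempts; "
        "increase motif_length or reduce n_classes"
    )


def _place_motifs(
    rng: np.random.Generator, length: int, motifs: Sequence[str]
) -> str | None:
    """Uniform background sequence with the given motifs embedded,
    non-overlapping; None when they do not fit after a few tries."""
    seq = rng.choice(list(AMINO_ACIDS), size=length)
    taken: list[tuple[int, int]] = []
    for motif in motifs:
        m = len(motif)
        placed = False
        for _try in range(50):
            start = int(rng.integers(0, length - m + 1))
            if all(start + m <= s or start >= e for s, e in taken):
                seq[start : start + m] = list(motif)
                taken.append((start, start + m))
                placed = True
                break
        if not placed:
            return None
    return "".join(seq)


def generate_dataset(
    config: SyntheticConfig, label_space: LabelSpace | None = None
) -> tuple[list[PeptideRecord], dict[str, str]]:
    """Generate motif-labeled peptides; returns (records, motif table).

    Deterministic under ``config.seed``. The motif table maps each class
    name to its defining motif.
    """
    rng = np.random.default_rng(config.seed)
    n, C = config.n_sequences, config.n_classes
    if label_space is None:
        names = tuple(f"C{i + 1:02d}" for i in range(C))
        label_space = LabelSpace(names)
    else:
        if label_space.size != C:
            raise SyntheticConfigError("label space size must equal n_classes")
        names = label_space.names
    motifs = _draw_motifs(rng, C, config.motif_length)
    motif_of = dict(zip(names, motifs))

    prevalence = config.resolved_prevalence()
    planned = [set() for _ in range(n)]
    for c in range(C):
        t_c = max(1, int(round(prevalence[c] * n)))
        for r in rng.choice(n, size=min(t_c, n), replace=False):
            planned[r].add(c)

    # Repair pass: hand one motif from the most-labeled records to each
    # unlabeled record while any donor with >= 2 labels exists.
    empty = [int(r) for r in rng.permutation([r for r in range(n) if not planned[r]])]
    donors = sorted(
        (r for r in range(n) if len(planned[r]) >= 2),
        key=lambda r: -len(planned[r]),
    )
    di = 0
    for r in empty:
        while di < len(donors) and len(planned[donors[di]]) < 2:
            di += 1
        if di >= len(donors):
            break  # prevalences sum below 1: all-negative records remain
        donor = donors[di]
        c = min(planned[donor], key=lambda cc: prevalence[cc])
        planned[donor].discard(c)
        planned[r].add(c)

    lo, hi = config.length_range
    records: list[PeptideRecord] = []
    for r in range(n):
        classes = sorted(planned[r])
        need = max(lo, len(classes) * config.motif_length)
        length = int(rng.integers(need, hi + 1))
        seq = None
        while seq is None:
            seq = _place_motifs(rng, length, [motifs[c] for c in classes])
        # Labels are defined by motif containment, so rare accidental
        # occurrences of other motifs are labeled consistently.
        labels = {names[c] for c in range(C) if motifs[c] in seq}
        if config.label_noise > 0:
            flips = rng.random(C) < config.label_noise
            for c in range(C):
                if flips[c]:
                    labels ^= {names[c]}
        records.append(PeptideRecord(id=f"syn{r + 1:05d}", sequence=seq, labels=labels))
    return records, motif_of


@dataclasses.dataclass(frozen=True)
class ImbalanceSummary:
    counts: dict[str, int]
    ratio: float | None        # max count / min nonzero count
    multi_label_fraction: float
    n_records: int
    n_unlabeled: int


def summarize_imbalance(
    records: Sequence[PeptideRecord], label_space: LabelSpace
) -> ImbalanceSummary:
    """Per-class counts (every annotated function counts), majority:minority
    ratio over classes with at least one record, and multi-label fraction."""
    counts = {name: 0 for name in label_space.names}
    multi = 0
    unlabeled = 0
    for rec in records:
        if len(rec.labels) >= 2:
            multi += 1
        if not rec.labels:
            unlabeled += 1
        for lab in rec.labels:
            counts[lab] += 1
    nonzero = [v for v in counts.values() if v > 0]
    ratio = max(nonzero) / min(nonzero) if nonzero else None
    return ImbalanceSummary(
        counts=counts,
        ratio=ratio,
        multi_label_fraction=multi / len(records) if records else 0.0,
        n_records=len(records),
        n_unlabeled=unlabeled,
    )
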