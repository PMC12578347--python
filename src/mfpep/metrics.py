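"""Multi-label evaluation metrics for peptide function prediction.

Five set-based metrics over true/predicted label subsets (precision,
coverage, accuracy, absolute true, absolute false), micro-averaged F1 and
MCC over label-instance pairs, and per-class ROC AUC in the concordance
(Mann-Whitney) formulation with ties counted as half.

Empty-set conventions: a per-sample term whose denominator is an empty set
contributes 0, except in the intersection-over-union family when both the
true and predicted sets are empty, which counts as exact agreement (1).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.stats import rankdata


class MetricError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class MetricReport:
    """The seven multi-label metrics plus per-class AUC."""

    precision: float
    coverage: float
    accuracy: float
    absolute_true: float
    absolute_false: float
    f1: float
    mcc: float
    auc: np.ndarray | None = None  # per-class; nan where undefined

    def to_dict(self) -> dict:
        d = {
            "precision": self.precision,
            "coverage": self.coverage,
            "accuracy": self.accuracy,
            "absolute_true": self.absolute_true,
            "absolute_false": self.absolute_false,
            "f1": self.f1,
            "mcc": self.mcc,
        }
        if self.auc is not None:
            d["auc"] = [None if np.isnan(a) else float(a) for a in self.auc]
        return d


def set_based_metrics(
    true_sets: Sequence[set], pred_sets: Sequence[set], M: int
) -> tuple[float, float, float, float, float]:
    """Precision, coverage, accuracy, absolute true, absolute false.

    For each sample i with true set L and predicted set L*:
    precision averages |L∩L*|/|L*|, coverage |L∩L*|/|L|, accuracy the
    Jaccard index |L∩L*|/|L∪L*|; absolute true is the exact-match rate;
    absolute false averages (|L∪L*|-|L∩L*|)/M, the symmetric set
    difference normalized by the label-space size M.
    """
    if len(true_sets) != len(pred_sets):
        raise MetricError("true and predicted lists must have equal length")
    if len(true_sets) == 0:
        raise MetricError("cannot evaluate an empty set of samples")
    prec = cov = acc = atrue = afalse = 0.0
    for L, Lp in zip(true_sets, pred_sets):
        L, Lp = set(L), set(Lp)
        union = L | Lp
        if len(union) > M:
            raise MetricError(f"label union of size {len(union)} exceeds M={M}")
        inter = len(L & Lp)
        # zero-denominator terms contribute 0, except exact agreement of
        # two empty sets, which counts as 1 across the ratio family
        prec += inter / len(Lp) if Lp else (1.0 if not L else 0.0)
        cov += inter / len(L) if L else (1.0 if not Lp else 0.0)
        acc += inter / len(union) if union else 1.0
        atrue += 1.0 if L == Lp else 0.0
        afalse += (len(union) - inter) / M
    n = len(true_sets)
    return prec / n, cov / n, acc / n, atrue / n, afalse / n


def confusion_metrics(
    true_matrix: np.ndarray, pred_matrix: np.ndarray
) -> tuple[float, float]:
    """Micro-averaged F1 and MCC over all N x M label-instance pairs."""
    Y = np.asarray(true_matrix)
    P = np.asarray(pred_matrix)
    if Y.shape != P.shape:
        raise MetricError("shape mismatch between true and predicted matrices")
    for A in (Y, P):
        if not np.isin(A, (0, 1)).all():
            raise MetricError("matrices must be binary")
    tp = float(np.sum((Y == 1) & (P == 1)))
    fp = float(np.sum((Y == 0) & (P == 1)))
    fn = float(np.sum((Y == 1) & (P == 0)))
    tn = float(np.sum((Y == 0) & (P == 0)))
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom > 0 else 0.0
    return f1, float(mcc)


def roc_auc_per_class(
    true_matrix: np.ndarray, score_matrix: np.ndarray
) -> np.ndarray:
    """Per-class AUC as P(random positive outscores random negative).

    Ties count one half (Mann-Whitney form). Classes with no positives or
    no negatives are reported as nan rather than raising.
    """
    Y = np.asarray(true_matrix)
    S = np.asarray(score_matrix, dtype=float)
    if Y.shape != S.shape:
        raise MetricError("shape mismatch between labels and scores")
    if not np.all(np.isfinite(S)):
        raise MetricError("scores must be finite")
    N, M = Y.shape
    out = np.full(M, np.nan)
    for c in range(M):
        y = Y[:, c]
        n_pos = int(y.sum())
        n_neg = N - n_pos
        if n_pos == 0 or n_neg == 0:
            continue
        r = rankdata(S[:, c])  # average ranks handle ties as 1/2
        out[c] = (r[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    return out


def sets_from_matrix(matrix: np.ndarray, names: Sequence[str] | None = None) -> list[set]:
    """Binary (N, M) matrix -> list of label(-index) sets per row."""
    matrix = np.asarray(matrix)
    result = []
    for row in matrix:
        idx = np.nonzero(row)[0]
        result.append({names[i] for i in idx} if names else set(idx.tolist()))
    return result


def evaluate_predictions(
    true_matrix: np.ndarray,
    score_matrix: np.ndarray,
    threshold: float = 0.5,
) -> MetricReport:
    """Full metric report from a binary truth matrix and score matrix."""
    if not (0.0 < threshold < 1.0):
        raise MetricError("threshold must lie in (0, 1)")
    Y = np.asarray(true_matrix)
    S = np.asarray(score_matrix, dtype=float)
    P = (S > threshold).astype(int)
    prec, cov, acc, atrue, afalse = set_based_metrics(
        sets_from_matrix(Y), sets_from_matrix(P), M=Y.shape[1]
    )
    f1, mcc = confusion_metrics(Y, P)
    auc = roc_auc_per_class(Y, S)
    return MetricReport(
        precision=prec, coverage=cov, accuracy=acc, absolute_true=atrue,
        absolute_false=afalse, f1=f1, mcc=mcc, auc=auc,
    )
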