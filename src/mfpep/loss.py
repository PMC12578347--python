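"""Marginal focal dice loss (MFDL) and reference losses for comparison.

MFDL targets heavily imbalanced multi-label problems. For every class c
(treated as its own binary sub-problem over the batch):

1.  *Margin adjustment* — logits are shifted by a count-dependent margin
    before the sigmoid, in the spirit of label-distribution-aware margins:
    the minority side of the class receives the full margin ``m_max``, the
    majority side the smaller ``m_max * w_maj / w_min`` where ``w = n^(-1/2)``
    is the inverse-square-root count weight. Shifting positives (usually
    the minority) down by more forces the model to learn a wider margin
    for them.
2.  *Clipped focal probabilities* — ``p_pos = min(p + clip_pos, 1) * p``
    for positives and the mirrored form for negatives; the clip keeps
    easy examples from saturating and the product discounts uncertain
    predictions.
3.  *Dice components* — a soft dice loss per class and side,
    ``L_pos = 1 - 2 * sum(p_pos * y) / sum(p_pos^e_pos + y)``, aggregated
    over the batch; sides with no instances in the batch are skipped.
4.  *Composition* — ``alpha * L_pos + (1 - alpha) * L_neg``, weighted per
    class by ``w_c = m_max * n_c^(-1/2) / max_c' n_c'^(-1/2)`` (or 1 when
    class weighting is off) and reduced over classes (mean, sum or none).

Everything is differentiable with respect to the logits via
:mod:`mfpep.autodiff`, so the same code path serves training and the
finite-difference gradient checks.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Literal

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

EPS = 1e-8


class LossConfigError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class MFDLConfig:
    """Hyperparameters of the marginal focal dice loss."""

    alpha: float = 0.5           # positive/negative mixing weight
    m_max: float = 0.5           # maximum margin (and class-weight scale)
    p_pos: float = 2.0           # focal exponent, positive dice denominator
    p_neg: float = 2.0           # focal exponent, negative dice denominator
    clip_pos: float = 0.05       # probability clip increment, positives
    clip_neg: float = 0.05       # probability clip increment, negatives
    use_class_weights: bool = True
    reduction: Literal["mean", "sum", "none"] = "mean"

    def __post_init__(self):
        if not (0.0 <= self.alpha <= 1.0):
            raise LossConfigError("alpha must lie in [0, 1]")
        if self.m_max < 0:
            raise LossConfigError("m_max must be >= 0")
        if self.p_pos <= 0 or self.p_neg <= 0:
            raise LossConfigError("focal exponents must be > 0")
        if self.clip_pos < 0 or self.clip_neg < 0:
            raise LossConfigError("clips must be >= 0")
        if self.reduction not in ("mean", "sum", "none"):
            raise LossConfigError(f"unknown reduction {self.reduction!r}")


@dataclasses.dataclass(frozen=True)
class ClassStats:
    """Per-class counts, inverse-sqrt weights and logit margins."""

    n_pos: np.ndarray
    n_neg: np.ndarray
    w_pos: np.ndarray       # n_pos^(-1/2), smoothed
    w_neg: np.ndarray       # n_neg^(-1/2), smoothed
    w_class: np.ndarray     # Eq-6-style class weights (1 when disabled)
    margin_pos: np.ndarray  # margin subtracted from logits where y = 1
    margin_neg: np.ndarray  # margin subtracted from logits where y = 0


def compute_class_stats(label_matrix: np.ndarray, config: MFDLConfig) -> ClassStats:
    """Derive counts, weights and margins from a binary (N, C) label matrix."""
    Y = np.asarray(label_matrix)
    if Y.ndim != 2 or not np.isin(Y, (0, 1)).all():
        raise LossConfigError("label matrix must be binary with shape (N, C)")
    N, C = Y.shape
    n_pos = Y.sum(axis=0).astype(float)
    n_neg = N - n_pos
    if n_pos.sum() == 0:
        raise LossConfigError("at least one positive instance is required")
    for side, n in (("positives", n_pos), ("negatives", n_neg)):
        if (n == 0).any():
            warnings.warn(
                f"class(es) {np.where(n == 0)[0].tolist()} have no {side}; "
                "using a smoothing count of 1 for their weights"
            )
    sp = np.maximum(n_pos, 1.0)
    sn = np.maximum(n_neg, 1.0)
    w_pos = sp ** -0.5
    w_neg = sn ** -0.5
    if config.use_class_weights:
        w = sp ** -0.5
        w_class = config.m_max * w / w.max()
    else:
        w_class = np.ones(C)
    # Minority side of each class receives the full margin; the majority
    # side is scaled down by the weight ratio (<= 1).
    w_min_side = np.maximum(w_pos, w_neg)
    w_maj_side = np.minimum(w_pos, w_neg)
    ratio = w_maj_side / w_min_side
    pos_is_minority = n_pos <= n_neg
    margin_pos = np.where(pos_is_minority, config.m_max, config.m_max * ratio)
    margin_neg = np.where(pos_is_minority, config.m_max * ratio, config.m_max)
    return ClassStats(
        n_pos=n_pos, n_neg=n_neg, w_pos=w_pos, w_neg=w_neg,
        w_class=w_class, margin_pos=margin_pos, margin_neg=margin_neg,
    )


def mfdl_loss(
    logits: Tensor | np.ndarray,
    labels: np.ndarray,
    stats: ClassStats,
    config: MFDLConfig,
    apply_margin: bool = True,
    return_components: bool = False,
):
    """Marginal focal dice loss over an (N, C) batch of logits.

    Returns an autodiff :class:`Tensor` (scalar for mean/sum reduction, a
    per-class vector for ``reduction='none'``). With ``return_components``
    the per-class positive/negative dice components are also returned as
    plain arrays for inspection.
    """
    Y = np.asarray(labels, dtype=float)
    if Y.ndim != 2 or not np.isin(Y, (0.0, 1.0)).all():
        raise LossConfigError("labels must be a binary (N, C) matrix")
    z = ad.as_tensor(logits)
    if z.shape != Y.shape:
        raise LossConfigError(f"logits shape {z.shape} != labels shape {Y.shape}")

    if apply_margin:
        m = np.where(Y == 1, stats.margin_pos, stats.margin_neg)
        z = z - m
    p = ad.sigmoid(z)

    # positive side
    p_pos = (p + config.clip_pos).clip_max(1.0) * p * Y
    num_pos = (p_pos * Y).sum(axis=0)                       # (C,)
    den_pos = (p_pos ** config.p_pos + Y).sum(axis=0)
    l_pos = 1.0 - (num_pos * 2.0) / (den_pos + EPS)

    # negative side
    Yn = 1.0 - Y
    q = 1.0 - p
    p_neg = (q + config.clip_neg).clip_max(1.0) * q * Yn
    num_neg = (p_neg * Yn).sum(axis=0)
    den_neg = (p_neg ** config.p_neg + Yn).sum(axis=0)
    l_neg = 1.0 - (num_neg * 2.0) / (den_neg + EPS)

    has_pos = (Y.sum(axis=0) > 0).astype(float)
    has_neg = (Yn.sum(axis=0) > 0).astype(float)
    per_class = l_pos * (config.alpha * has_pos) + l_neg * ((1.0 - config.alpha) * has_neg)
    weighted = per_class * stats.w_class

    if config.reduction == "mean":
        out = weighted.mean()
    elif config.reduction == "sum":
        out = weighted.sum()
    else:
        out = weighted
    if return_components:
        components = {
            "l_pos": l_pos.numpy().copy(),
            "l_neg": l_neg.numpy().copy(),
            "has_pos": has_pos,
            "has_neg": has_neg,
            "per_class": per_class.numpy().copy(),
        }
        return out, components
    return out


def _abs(z: Tensor) -> Tensor:
    return ad.relu(z) + ad.relu(-z)


def _bce_with_logits(z: Tensor, Y: np.ndarray) -> Tensor:
    """Numerically stable elementwise binary cross-entropy, mean-reduced."""
    softplus = ad.log(ad.exp(-_abs(z)) + 1.0)
    per = ad.relu(z) - z * Y + softplus
    return per.mean()


def reference_losses(
    logits: Tensor | np.ndarray,
    labels: np.ndarray,
    variant: str,
    stats: ClassStats | None = None,
    config: MFDLConfig | None = None,
    focal_gamma: float = 2.0,
    asl_gamma_pos: float = 1.0,
    asl_gamma_neg: float = 4.0,
    asl_clip: float = 0.05,
) -> Tensor:
    """Comparator losses: bce, focal, mlfdl, ldam_margin, asymmetric.

    ``mlfdl`` is the margin-free, unweighted configuration of the focal
    dice loss; ``ldam_margin`` is binary cross-entropy on margin-adjusted
    logits (margins from ``stats``); ``asymmetric`` is the standard
    asymmetric loss with probability shifting on the negative side.
    """
    Y = np.asarray(labels, dtype=float)
    z = ad.as_tensor(logits)
    config = config or MFDLConfig()

    if variant == "bce":
        return _bce_with_logits(z, Y)
    if variant == "focal":
        p = ad.sigmoid(z)
        pt = p * Y + (1.0 - p) * (1.0 - Y)
        mod = (1.0 - pt) ** focal_gamma
        per = mod * (-ad.log(pt + 1e-12))
        return per.mean()
    if variant == "mlfdl":
        # margin-free, unweighted focal dice: stats reduce to the identity
        cfg = dataclasses.replace(config, m_max=0.0, use_class_weights=False)
        C = Y.shape[1]
        st = ClassStats(
            n_pos=Y.sum(axis=0), n_neg=(1 - Y).sum(axis=0),
            w_pos=np.ones(C), w_neg=np.ones(C), w_class=np.ones(C),
            margin_pos=np.zeros(C), margin_neg=np.zeros(C),
        )
        return mfdl_loss(z, Y, st, cfg, apply_margin=True)
    if variant == "ldam_margin":
        if stats is None:
            raise LossConfigError("ldam_margin requires class stats")
        m = np.where(Y == 1, stats.margin_pos, stats.margin_neg)
        return _bce_with_logits(z - m, Y)
    if variant == "asymmetric":
        p = ad.sigmoid(z)
        pm = ad.relu(p - asl_clip)  # shifted negative probability
        loss_pos = ((1.0 - p) ** asl_gamma_pos) * (-ad.log(p + 1e-12)) * Y
        loss_neg = (pm ** asl_gamma_neg) * (-ad.log((1.0 - pm) + 1e-12)) * (1.0 - Y)
        return (loss_pos + loss_neg).mean()
    raise LossConfigError(f"unknown loss variant {variant!r}")


def make_loss_fn(name: str, stats: ClassStats, config: MFDLConfig):
    """Closure (logits, labels) -> Tensor for the named training loss."""
    name = name.lower()
    if name == "mfdl":
        return lambda z, y: mfdl_loss(z, y, stats, config)
    if name in ("bce", "focal", "mlfdl", "ldam_margin", "asymmetric"):
        return lambda z, y: reference_losses(z, y, name, stats=stats, config=config)
    raise LossConfigError(f"unknown loss {name!r}")
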