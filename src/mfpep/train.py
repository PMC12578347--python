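"""Training loop, cross-validation, ablation and loss-comparison harnesses.

Class statistics for the marginal focal dice loss are computed once from
the full training fold (margins and weights are dataset-level quantities),
then held fixed across batches. Training is deterministic under the config
seed on a single device: the fold partition, batch order and dropout masks
all derive from it.
"""

from __future__ import annotations

import dataclasses
import time
from typing import Sequence

import numpy as np

from . import nn
from .loss import ClassStats, MFDLConfig, compute_class_stats, make_loss_fn
from .metrics import MetricReport, evaluate_predictions
from .network import MODULES, STREAMS, MFTPModel, ModelConfig
from .sequence_io import LabelSpace, PeptideRecord


class TrainConfigError(ValueError):
    pass


class DivergenceError(RuntimeError):
    pass


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    epochs: int = 20
    batch_size: int = 64
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    weight_decay: float = 1e-3
    clip_norm: float = 5.0
    prior_bias_init: bool = True
    lr_schedule: str = "constant"  # or "cosine"
    loss: str = "mfdl"
    mfdl: MFDLConfig = MFDLConfig()
    model: ModelConfig = ModelConfig()
    threshold: float = 0.5
    folds: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise TrainConfigError("epochs must be >= 1")
        if self.batch_size < 1:
            raise TrainConfigError("batch_size must be >= 1")
        if not (0.0 < self.threshold < 1.0):
            raise TrainConfigError("threshold must lie in (0, 1)")
        if self.folds < 2:
            raise TrainConfigError("folds must be >= 2 for cross-validation")
        if self.optimizer.lower() != "adam":
            raise TrainConfigError(f"unknown optimizer {self.optimizer!r}")
        if self.lr_schedule not in ("cosine", "constant"):
            raise TrainConfigError(f"unknown lr schedule {self.lr_schedule!r}")

    def to_dict(self) -> dict:
        return {
            "epochs": self.epochs,
            "batch_size": self.batch_size,
            "learning_rate": self.learning_rate,
            "optimizer": self.optimizer,
            "weight_decay": self.weight_decay,
            "clip_norm": self.clip_norm,
            "prior_bias_init": self.prior_bias_init,
            "lr_schedule": self.lr_schedule,
            "loss": self.loss,
            "mfdl": dataclasses.asdict(self.mfdl),
            "model": self.model.to_dict(),
            "threshold": self.threshold,
            "folds": self.folds,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        if "mfdl" in d:
            d["mfdl"] = MFDLConfig(**d["mfdl"])
        if "model" in d:
            d["model"] = ModelConfig.from_dict(d["model"])
        return cls(**d)


@dataclasses.dataclass
class RunReport:
    """Result of one training run or cross-validation study."""

    loss_curve: list[float]
    final_metrics: MetricReport | None
    fold_metrics: list[MetricReport]
    config: dict
    seed: int

    def summary_table(self) -> str:
        """Mean +/- sd per metric over folds, in benchmark-table style."""
        reports = self.fold_metrics or ([self.final_metrics] if self.final_metrics else [])
        keys = ("precision", "coverage", "accuracy", "absolute_true",
                "absolute_false", "f1", "mcc")
        lines = []
        for k in keys:
            vals = np.array([getattr(r, k) for r in reports], dtype=float)
            lines.append(f"{k}\t{vals.mean():.3f}±{vals.std(ddof=0):.3f}")
        return "\n".join(lines)

    def mean_metrics(self) -> dict[str, float]:
        reports = self.fold_metrics or ([self.final_metrics] if self.final_metrics else [])
        keys = ("precision", "coverage", "accuracy", "absolute_true",
                "absolute_false", "f1", "mcc")
        return {k: float(np.mean([getattr(r, k) for r in reports])) for k in keys}


def _label_space_for(records: Sequence[PeptideRecord], n_classes: int) -> LabelSpace:
    names = sorted({lab for r in records for lab in r.labels})
    if len(names) > n_classes:
        raise TrainConfigError(
            f"records carry {len(names)} labels but the model has {n_classes} outputs"
        )
    # pad the space with unused names so the matrix width matches the model
    extra = [f"_unused{i}" for i in range(n_classes - len(names))]
    return LabelSpace(tuple(names + extra))


def train(
    train_records: Sequence[PeptideRecord],
    valid_records: Sequence[PeptideRecord] | None,
    config: TrainConfig,
    label_space: LabelSpace | None = None,
    early_stop: dict[str, float] | None = None,
    verbose: bool = False,
) -> tuple[MFTPModel, RunReport]:
    """Train a model; returns the model and a report with the loss curve.

    ``early_stop`` maps metric names to target values; when every target is
    met on the validation set at an epoch boundary, training stops early.
    """
    if not train_records:
        raise TrainConfigError("training set is empty")
    label_space = label_space or _label_space_for(
        list(train_records) + list(valid_records or []), config.model.n_classes
    )
    model = MFTPModel(dataclasses.replace(config.model, seed=config.seed))
    Y = label_space.to_matrix(train_records).astype(float)
    stats = compute_class_stats(Y.astype(int), config.mfdl)
    if config.prior_bias_init:
        # start the classifier at the empirical class priors; shortens the
        # flat warm-up phase that sigmoid outputs otherwise spend drifting
        # from p=0.5 to the base rates
        prior = np.clip(stats.n_pos / (stats.n_pos + stats.n_neg), 1e-3, 1 - 1e-3)
        model.params["clf.b2"].data = np.log(prior / (1 - prior))
    loss_fn = make_loss_fn(config.loss, stats, config.mfdl)
    opt = nn.Adam(
        model.params.tensors(), lr=config.learning_rate,
        weight_decay=config.weight_decay, clip_norm=config.clip_norm,
    )
    rng = np.random.default_rng(config.seed + 1)

    batch = model.encode_records(train_records)
    n = len(train_records)
    curve: list[float] = []
    final_metrics = None
    for epoch in range(config.epochs):
        if config.lr_schedule == "cosine":
            opt.lr = config.learning_rate * 0.5 * (
                1.0 + np.cos(np.pi * epoch / max(config.epochs, 1))
            )
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            sub = dataclasses.replace(
                batch,
                tokens=batch.tokens[idx],
                mask=batch.mask[idx],
                bio={k: v[idx] for k, v in batch.bio.items()},
            )
            logits = model.forward(sub, training=True, rng=rng)
            loss = loss_fn(logits, Y[idx])
            value = float(loss.numpy())
            if not np.isfinite(value):
                raise DivergenceError(
                    f"non-finite training loss {value} at epoch {epoch + 1}"
                )
            model.params.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += value
            n_batches += 1
        curve.append(epoch_loss / n_batches)
        if verbose:
            print(f"epoch {epoch + 1}: loss {curve[-1]:.4f}")
        if valid_records and early_stop:
            final_metrics = evaluate(model, valid_records, label_space, config.threshold)
            if all(
                getattr(final_metrics, k) >= v for k, v in early_stop.items()
            ):
                break
            final_metrics = None
    if valid_records and final_metrics is None:
        final_metrics = evaluate(model, valid_records, label_space, config.threshold)
    report = RunReport(
        loss_curve=curve,
        final_metrics=final_metrics,
        fold_metrics=[],
        config=config.to_dict(),
        seed=config.seed,
    )
    return model, report


def evaluate(
    model: MFTPModel,
    records: Sequence[PeptideRecord],
    label_space: LabelSpace,
    threshold: float = 0.5,
) -> MetricReport:
    """Metric report for a labeled record list."""
    Y = label_space.to_matrix(records)
    scores = model.predict_proba(records)
    return evaluate_predictions(Y, scores, threshold)


def cross_validate(
    records: Sequence[PeptideRecord],
    config: TrainConfig,
    label_space: LabelSpace | None = None,
    verbose: bool = False,
) -> RunReport:
    """Seeded k-fold cross-validation; reports per-fold metrics."""
    n = len(records)
    if config.folds > n:
        raise TrainConfigError(f"folds={config.folds} exceeds {n} records")
    label_space = label_space or _label_space_for(records, config.model.n_classes)
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(n)
    fold_of = np.zeros(n, dtype=int)
    for pos, i in enumerate(order):
        fold_of[i] = pos % config.folds
    fold_metrics = []
    curves = []
    for fold in range(config.folds):
        tr = [records[i] for i in range(n) if fold_of[i] != fold]
        te = [records[i] for i in range(n) if fold_of[i] == fold]
        model, rep = train(tr, te, config, label_space=label_space, verbose=verbose)
        fold_metrics.append(rep.final_metrics)
        curves.append(rep.loss_curve)
    return RunReport(
        loss_curve=[float(np.mean(c)) for c in zip(*curves)],
        final_metrics=None,
        fold_metrics=fold_metrics,
        config=config.to_dict(),
        seed=config.seed,
    )


ABLATION_TARGETS = tuple(MODULES) + tuple(STREAMS)


def run_ablation(
    records: Sequence[PeptideRecord],
    config: TrainConfig,
    targets: Sequence[str] = (),
    use_cv: bool = False,
    verbose: bool = False,
) -> dict[str, RunReport]:
    """One run per ablation target, plus the unmodified baseline.

    Module targets remove the component (gate fusion degrades to a plain
    mean over aligned streams); stream targets zero that feature. All other
    hyperparameters are held fixed.
    """
    for t in targets:
        if t not in ABLATION_TARGETS:
            raise TrainConfigError(f"unknown ablation target {t!r}")
    out: dict[str, RunReport] = {}

    def one(cfg: TrainConfig) -> RunReport:
        if use_cv:
            return cross_validate(records, cfg, verbose=verbose)
        tr, te = _holdout(records, cfg.seed)
        _, rep = train(tr, te, cfg, verbose=verbose)
        return rep

    out["baseline"] = one(config)
    for t in targets:
        if t in MODULES:
            mc = dataclasses.replace(
                config.model, ablate_modules=config.model.ablate_modules | {t}
            )
        else:
            mc = dataclasses.replace(
                config.model, ablate_streams=config.model.ablate_streams | {t}
            )
        out[t] = one(dataclasses.replace(config, model=mc))
    return out


def _holdout(records: Sequence[PeptideRecord], seed: int, fraction: float = 0.8):
    from .sequence_io import split_dataset

    return split_dataset(records, fraction, seed)


def compare_losses(
    records: Sequence[PeptideRecord],
    config: TrainConfig,
    variants: Sequence[str] = ("mfdl", "bce", "focal", "mlfdl", "ldam_margin", "asymmetric"),
    use_cv: bool = False,
    verbose: bool = False,
) -> dict[str, RunReport]:
    """Train the same architecture under each loss; returns reports by name."""
    out = {}
    for v in variants:
        cfg = dataclasses.replace(config, loss=v)
        if use_cv:
            out[v] = cross_validate(records, cfg, verbose=verbose)
        else:
            tr, te = _holdout(records, cfg.seed)
            _, rep = train(tr, te, cfg, verbose=verbose)
            out[v] = rep
    return out
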