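"""Training protocol: configs, early stopping, scheduling, multi-seed runs.

The training loop itself lives in
:meth:`recgobd.model.RecGOBDClassifier.fit`; this module holds its
reusable pieces and the evaluation protocol that averages test-set metrics
over several random seeds on one fixed data split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .metrics import LossConfig, MetricsReport, evaluate_predictions
from .sequence_io import DatasetSplit, ProteinRecord

__all__ = [
    "TrainConfig",
    "TrainLog",
    "EarlyStopping",
    "step_lr",
    "step_scheduler",
    "train",
    "multi_seed_evaluate",
    "MultiSeedReport",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings (architecture sizes live on the estimator)."""

    learning_rate: float = 1e-3
    scheduler: str = "none"  # "none" | "step"
    scheduler_step_size: int = 10
    scheduler_gamma: float = 0.5
    loss: LossConfig = field(default_factory=LossConfig)
    patience: int = 5
    min_delta: float = 0.0
    max_epochs: int = 100
    batch_size: int = 32
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4)

    def __post_init__(self):
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not self.seeds:
            raise ValueError("at least one seed is required")


@dataclass
class TrainLog:
    """Per-epoch losses and the early-stopping outcome of one run."""

    train_losses: list[float]
    val_losses: list[float]
    best_epoch: int  # 1-based epoch with the lowest validation loss
    stopped_early: bool
    seed: int


class EarlyStopping:
    """Stop when the validation loss has not improved for ``patience`` epochs.

    "Improved" means strictly below the best loss so far minus ``min_delta``.
    The parameters of the best epoch are what training ultimately returns.
    """

    def __init__(self, patience: int = 5, min_delta: float = 0.0):
        if patience < 1:
            raise ValueError("patience must be >= 1")
        self.patience = patience
        self.min_delta = min_delta
        self.best_loss = np.inf
        self.best_epoch = 0
        self.stale = 0
        self.stopped = False

    def update(self, epoch: int, val_loss: float) -> tuple[bool, bool]:
        """Record an epoch's validation loss; returns (improved, stop_now)."""
        if val_loss < self.best_loss - self.min_delta:
            self.best_loss = val_loss
            self.best_epoch = epoch
            self.stale = 0
            return True, False
        self.stale += 1
        if self.stale >= self.patience:
            self.stopped = True
        return False, self.stopped


def step_lr(lr: float, epoch: int, scheduler: str = "step",
            step_size: int = 10, gamma: float = 0.5) -> float:
    """Stepwise decay ``lr * gamma ** floor(epoch / step_size)`` (0-based epoch)."""
    if scheduler == "none":
        return lr
    if scheduler != "step":
        raise ValueError(f"unknown scheduler {scheduler!r}")
    if step_size <= 0:
        raise ValueError("scheduler step_size must be positive")
    return lr * gamma ** (epoch // step_size)


def step_scheduler(lr: float, epoch: int, config: TrainConfig) -> float:
    """The learning rate at ``epoch`` under a TrainConfig's scheduler."""
    return step_lr(lr, epoch, config.scheduler, config.scheduler_step_size,
                   config.scheduler_gamma)


def _subset(records: list[ProteinRecord], labels: dict[str, np.ndarray],
            ids: tuple[str, ...]):
    by_id = {r.id: r for r in records}
    missing = [i for i in ids if i not in by_id]
    if missing:
        raise KeyError(f"split references unknown ids, e.g. {missing[:3]}")
    recs = [by_id[i] for i in ids]
    y = np.stack([labels[i] for i in ids])
    return recs, y


def train(records: list[ProteinRecord], labels: dict[str, np.ndarray],
          split: DatasetSplit, train_config: TrainConfig | None = None,
          embedder=None, seed: int = 0, **model_kwargs):
    """Fit a classifier on a split's train partition, early-stopped on val.

    Returns the fitted :class:`~recgobd.model.RecGOBDClassifier`; its
    ``train_log_`` attribute is the :class:`TrainLog`.
    """
    from .model import RecGOBDClassifier

    cfg = train_config or TrainConfig()
    X_tr, y_tr = _subset(records, labels, split.train_ids)
    X_val, y_val = _subset(records, labels, split.val_ids)
    clf = RecGOBDClassifier(
        embedder=embedder,
        loss=cfg.loss.kind, alpha=cfg.loss.alpha, gamma=cfg.loss.gamma,
        learning_rate=cfg.learning_rate, scheduler=cfg.scheduler,
        scheduler_step_size=cfg.scheduler_step_size,
        scheduler_gamma=cfg.scheduler_gamma,
        batch_size=cfg.batch_size, max_epochs=cfg.max_epochs,
        patience=cfg.patience, min_delta=cfg.min_delta,
        random_state=seed, **model_kwargs,
    )
    clf.fit(X_tr, y_tr, validation_data=(X_val, y_val))
    return clf


@dataclass
class MultiSeedReport:
    """Seed-averaged test metrics with per-seed detail."""

    mean_auroc: float
    mean_aupr: float
    mean_fmax: float
    std_auroc: float
    std_aupr: float
    std_fmax: float
    per_seed: list[MetricsReport]
    seeds: tuple[int, ...]

    def to_dict(self) -> dict:
        return {
            "mean_auroc": self.mean_auroc, "mean_aupr": self.mean_aupr,
            "mean_fmax": self.mean_fmax, "std_auroc": self.std_auroc,
            "std_aupr": self.std_aupr, "std_fmax": self.std_fmax,
            "seeds": list(self.seeds),
            "per_seed": [r.to_dict() for r in self.per_seed],
        }


def multi_seed_evaluate(records, labels, split: DatasetSplit,
                        train_config: TrainConfig | None = None,
                        embedder_factory=None, return_models: bool = False,
                        **model_kwargs):
    """Train and test once per seed on a fixed split; average the metrics.

    ``embedder_factory(seed)`` may build a fresh embedder per run; the
    default estimator embedder is used otherwise.  A failing seed aborts the
    whole evaluation with the seed identified.
    """
    cfg = train_config or TrainConfig()
    X_te, y_te = _subset(records, labels, split.test_ids)
    reports, models = [], []
    for seed in cfg.seeds:
        try:
            emb = embedder_factory(seed) if embedder_factory is not None else None
            clf = train(records, labels, split, cfg, embedder=emb, seed=seed,
                        **model_kwargs)
            reports.append(evaluate_predictions(clf.predict_proba(X_te), y_te))
            models.append(clf)
        except Exception as exc:
            raise RuntimeError(f"evaluation failed for seed {seed}: {exc}") from exc
    aur = np.array([r.auroc for r in reports])
    apr = np.array([r.aupr for r in reports])
    fmx = np.array([r.fmax for r in reports])
    report = MultiSeedReport(
        mean_auroc=float(aur.mean()), mean_aupr=float(apr.mean()),
        mean_fmax=float(fmx.mean()), std_auroc=float(aur.std()),
        std_aupr=float(apr.std()), std_fmax=float(fmx.std()),
        per_seed=reports, seeds=tuple(cfg.seeds),
    )
    if return_models:
        return report, models
    return report
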