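"""Training losses and protein-centric evaluation metrics.

Losses operate on predicted probabilities against binary truth: plain binary
cross-entropy, and focal loss

    FL = -alpha (1-p)^gamma log p        for positives,
         -(1-alpha) p^gamma log(1-p)     for negatives,

which down-weights easy examples.  Evaluation reports macro AUROC and AUPR
over the 10 GO terms plus the CAFA-style protein-centric Fmax: precision is
averaged over proteins predicted to have at least one term, recall over all
proteins, on a threshold grid of step 0.01, and Fmax is the maximum harmonic
mean across the grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = [
    "LossConfig",
    "FmaxResult",
    "MetricsReport",
    "bce_loss",
    "bce_loss_grad_logits",
    "focal_loss",
    "focal_loss_grad_logits",
    "auroc_macro",
    "aupr_macro",
    "fmax",
    "evaluate_predictions",
]

_EPS = 1e-7  # probability clipping before logs


@dataclass(frozen=True)
class LossConfig:
    """Choice of training loss with focal-loss hyperparameters."""

    kind: str = "bce"  # "bce" | "focal"
    alpha: float = 0.25
    gamma: float = 2.0

    def __post_init__(self):
        if self.kind not in ("bce", "focal"):
            raise ValueError(f"unknown loss kind {self.kind!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.gamma < 0.0:
            raise ValueError("gamma must be non-negative")


def _check(p, y):
    p = np.asarray(p, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: predictions {p.shape} vs labels {y.shape}")
    return p, y


def bce_loss(p, y) -> float:
    """Mean binary cross-entropy over all (protein, label) entries."""
    p, y = _check(p, y)
    pc = np.clip(p, _EPS, 1.0 - _EPS)
    return float(-(y * np.log(pc) + (1.0 - y) * np.log(1.0 - pc)).mean())


def focal_loss(p, y, config: LossConfig = LossConfig(kind="focal")) -> float:
    """Mean focal loss with weighting ``alpha`` and focusing ``gamma``."""
    p, y = _check(p, y)
    if config.gamma < 0:
        raise ValueError("gamma must be non-negative")
    pc = np.clip(p, _EPS, 1.0 - _EPS)
    pos = -config.alpha * (1.0 - pc) ** config.gamma * np.log(pc)
    neg = -(1.0 - config.alpha) * pc**config.gamma * np.log(1.0 - pc)
    return float(np.where(y == 1, pos, neg).mean())


def bce_loss_grad_logits(p, y) -> np.ndarray:
    """d(mean BCE)/d(logit) for sigmoid outputs: (p - y) / N (exact)."""
    p, y = _check(p, y)
    return (p - y) / p.size


def focal_loss_grad_logits(p, y, config: LossConfig) -> np.ndarray:
    """d(mean focal)/d(logit) for sigmoid outputs (chain rule through p)."""
    p, y = _check(p, y)
    a, g = config.alpha, config.gamma
    pc = np.clip(p, _EPS, 1.0 - _EPS)
    # dL/dp, then * dp/dz = p(1-p)
    dpos = a * ((1.0 - pc) ** g * (-1.0 / pc) + g * (1.0 - pc) ** (g - 1.0) * np.log(pc))
    dneg = (1.0 - a) * (pc**g / (1.0 - pc) - g * pc ** (g - 1.0) * np.log(1.0 - pc))
    dLdp = np.where(y == 1, dpos, dneg)
    return dLdp * pc * (1.0 - pc) / p.size


# ---------------------------------------------------------------------------
# ranking metrics


def _per_term(P, T, scorer):
    P = np.asarray(P, dtype=np.float64)
    T = np.asarray(T)
    if P.shape != T.shape or P.ndim != 2:
        raise ValueError("P and T must be equal-shape 2-D arrays")
    vals = np.full(P.shape[1], np.nan)
    for j in range(P.shape[1]):
        col = T[:, j]
        if 0 < col.sum() < col.size:  # needs both classes; else undefined
            vals[j] = scorer(col, P[:, j])
    return vals


def auroc_macro(P, T, micro: bool = False) -> tuple[float, np.ndarray]:
    """Macro-averaged ROC area over GO terms (midrank tie handling).

    Terms with a single class are excluded from the mean and returned as NaN
    in the per-term vector.  ``micro=True`` instead pools all entries.
    """
    if micro:
        val = float(roc_auc_score(np.asarray(T).ravel(), np.asarray(P).ravel()))
        return val, np.full(np.asarray(P).shape[1], np.nan)
    per_term = _per_term(P, T, roc_auc_score)
    if np.isnan(per_term).all():
        raise ValueError("no GO term has both a positive and a negative example")
    return float(np.nanmean(per_term)), per_term


def aupr_macro(P, T, micro: bool = False) -> tuple[float, np.ndarray]:
    """Macro-averaged precision-recall area (step interpolation) over terms."""
    if micro:
        val = float(average_precision_score(np.asarray(T).ravel(), np.asarray(P).ravel()))
        return val, np.full(np.asarray(P).shape[1], np.nan)
    per_term = _per_term(P, T, average_precision_score)
    if np.isnan(per_term).all():
        raise ValueError("no GO term has both a positive and a negative example")
    return float(np.nanmean(per_term)), per_term


# ---------------------------------------------------------------------------
# protein-centric Fmax


@dataclass(frozen=True)
class FmaxResult:
    fmax: float
    threshold: float
    avg_pr: np.ndarray  # per grid threshold
    avg_rc: np.ndarray
    thresholds: np.ndarray


def fmax(P, T, step: float = 0.01) -> FmaxResult:
    """Protein-centric maximum F-measure over a threshold grid.

    At each threshold t the predicted set of protein i is every term scoring
    >= t.  Precision is averaged over the m(t) proteins with a non-empty
    predicted set; recall over all n proteins (empty truth sets contribute
    recall 0).  Thresholds where m(t) = 0 or precision + recall = 0
    contribute F = 0.
    """
    P = np.asarray(P, dtype=np.float64)
    T = np.asarray(T)
    if P.ndim != 2 or P.shape != T.shape:
        raise ValueError("P and T must be equal-shape 2-D arrays")
    n = P.shape[0]
    if n == 0:
        raise ValueError("need at least one protein")
    n_steps = int(round(1.0 / step)) + 1
    thresholds = np.linspace(0.0, 1.0, n_steps)
    n_true = T.sum(axis=1)

    # (thresholds, proteins) counts in one vectorized sweep
    pred = P[None, :, :] >= thresholds[:, None, None]
    tp = (pred & (T[None, :, :] == 1)).sum(axis=2)
    n_pred = pred.sum(axis=2)

    with np.errstate(invalid="ignore", divide="ignore"):
        pr = np.where(n_pred > 0, tp / np.maximum(n_pred, 1), 0.0)
        rc = np.where(n_true[None, :] > 0, tp / np.maximum(n_true[None, :], 1), 0.0)
    m = (n_pred > 0).sum(axis=1)
    avg_pr = np.where(m > 0, pr.sum(axis=1) / np.maximum(m, 1), 0.0)
    avg_rc = rc.sum(axis=1) / n
    denom = avg_pr + avg_rc
    f = np.where(denom > 0, 2.0 * avg_pr * avg_rc / np.maximum(denom, _EPS), 0.0)
    best = int(np.argmax(f))
    return FmaxResult(
        fmax=float(f[best]),
        threshold=float(thresholds[best]),
        avg_pr=avg_pr,
        avg_rc=avg_rc,
        thresholds=thresholds,
    )


@dataclass
class MetricsReport:
    """AUROC / AUPR / Fmax summary with per-term values and threshold traces."""

    auroc: float
    aupr: float
    fmax: float
    fmax_threshold: float
    per_term_auroc: np.ndarray
    per_term_aupr: np.ndarray
    avg_pr_trace: np.ndarray
    avg_rc_trace: np.ndarray

    def to_dict(self) -> dict:
        return {
            "auroc": self.auroc,
            "aupr": self.aupr,
            "fmax": self.fmax,
            "fmax_threshold": self.fmax_threshold,
            "per_term_auroc": [None if np.isnan(v) else float(v) for v in self.per_term_auroc],
            "per_term_aupr": [None if np.isnan(v) else float(v) for v in self.per_term_aupr],
            "avg_pr_trace": [float(v) for v in self.avg_pr_trace],
            "avg_rc_trace": [float(v) for v in self.avg_rc_trace],
        }


def evaluate_predictions(P, T, step: float = 0.01) -> MetricsReport:
    """All three metrics on a probability matrix against binary truth."""
    auroc, per_roc = auroc_macro(P, T)
    aupr, per_pr = aupr_macro(P, T)
    fm = fmax(P, T, step=step)
    return MetricsReport(
        auroc=auroc,
        aupr=aupr,
        fmax=fm.fmax,
        fmax_threshold=fm.threshold,
        per_term_auroc=per_roc,
        per_term_aupr=per_pr,
        avg_pr_trace=fm.avg_pr,
        avg_rc_trace=fm.avg_rc,
    )
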