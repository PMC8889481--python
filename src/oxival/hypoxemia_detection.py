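"""Hypoxemia-detection analysis: error matrix, ROC/AUROC, optimal cut-off.

The condition is reference hypoxemia, SaO2 < 90%; a device predicts positive
when its windowed-median SpO2 is strictly below the cut-off.  The ROC sweep
runs over every distinct observed score plus a sentinel above the maximum, so
the optimal operating value is always an achievable threshold; AUROC is the
trapezoidal area, which coincides with the Mann-Whitney concordance
probability that a random hypoxemic window scores below a random normoxic
one (ties counted half).

Bootstrap confidence intervals resample pairs stratified by true class,
preserving prevalence.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy import stats

from .errors import DegenerateDataError
from .windowing import MatchedPair

logger = logging.getLogger(__name__)

HYPOXEMIA_THRESHOLD = 90.0
RATE_NAMES = ("sensitivity", "specificity", "ppv", "npv", "accuracy")


@dataclass(frozen=True)
class ErrorMatrix:
    """2x2 confusion counts; real-valued to support rate-derived reconstruction."""

    tp: float
    fp: float
    tn: float
    fn: float

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise DegenerateDataError(f"{name} must be >= 0")

    @property
    def positives(self) -> float:
        return self.tp + self.fn

    @property
    def negatives(self) -> float:
        return self.tn + self.fp

    @property
    def total(self) -> float:
        return self.tp + self.fp + self.tn + self.fn


def error_matrix(spo2, sao2, cutoff: float) -> ErrorMatrix:
    """Tabulate detection outcomes: condition SaO2 < 90, predicted SpO2 < cutoff."""
    spo2 = np.asarray(spo2, dtype=float)
    sao2 = np.asarray(sao2, dtype=float)
    if len(spo2) == 0 or spo2.shape != sao2.shape:
        raise DegenerateDataError("need non-empty aligned spo2/sao2 arrays")
    condition = sao2 < HYPOXEMIA_THRESHOLD
    predicted = spo2 < cutoff
    return ErrorMatrix(
        tp=float(np.sum(condition & predicted)),
        fp=float(np.sum(~condition & predicted)),
        tn=float(np.sum(~condition & ~predicted)),
        fn=float(np.sum(condition & ~predicted)),
    )


def classifier_metrics(m: ErrorMatrix) -> dict[str, float | None]:
    """Standard rates from an error matrix; undefined rates are None, not 0."""
    def ratio(num: float, den: float, name: str) -> float | None:
        if den == 0:
            logger.warning("%s undefined: zero denominator", name)
            return None
        return num / den

    return {
        "sensitivity": ratio(m.tp, m.tp + m.fn, "sensitivity"),
        "specificity": ratio(m.tn, m.tn + m.fp, "specificity"),
        "ppv": ratio(m.tp, m.tp + m.fp, "ppv"),
        "npv": ratio(m.tn, m.tn + m.fn, "npv"),
        "accuracy": ratio(m.tp + m.tn, m.total, "accuracy"),
    }


def metrics_from_rates(
    sensitivity: float, specificity: float, positives: float, negatives: float
) -> tuple[float | None, float | None, float | None]:
    """Reconstruct (ppv, npv, accuracy) from printed rates and class counts.

    Rebuilds tp = sensitivity * P, tn = specificity * N (and their
    complements) and applies the standard definitions — the identity used to
    cross-check published detection tables.
    """
    for name, rate in (("sensitivity", sensitivity), ("specificity", specificity)):
        if not 0.0 <= rate <= 1.0:
            raise DegenerateDataError(f"{name} must be in [0, 1]")
    if positives <= 0 or negatives <= 0:
        raise DegenerateDataError("class counts must be > 0")
    m = ErrorMatrix(
        tp=sensitivity * positives,
        fn=(1.0 - sensitivity) * positives,
        tn=specificity * negatives,
        fp=(1.0 - specificity) * negatives,
    )
    rates = classifier_metrics(m)
    return rates["ppv"], rates["npv"], rates["accuracy"]


@dataclass(frozen=True)
class ROCPoint:
    threshold: float
    fpr: float
    tpr: float


def _scores_labels(spo2, sao2) -> tuple[np.ndarray, np.ndarray]:
    spo2 = np.asarray(spo2, dtype=float)
    sao2 = np.asarray(sao2, dtype=float)
    if len(spo2) == 0 or spo2.shape != sao2.shape:
        raise DegenerateDataError("need non-empty aligned spo2/sao2 arrays")
    labels = sao2 < HYPOXEMIA_THRESHOLD
    if labels.all() or not labels.any():
        raise DegenerateDataError("both classes (hypoxemic and normoxic) must be present")
    return spo2, labels


def roc_curve(spo2, sao2) -> tuple[ROCPoint, ...]:
    """One ROC point per distinct score threshold plus an all-positive sentinel."""
    scores, labels = _scores_labels(spo2, sao2)
    pos = scores[labels]
    neg = scores[~labels]
    thresholds = np.append(np.unique(scores), scores.max() + 1.0)
    points = [
        ROCPoint(
            threshold=float(c),
            fpr=float(np.mean(neg < c)),
            tpr=float(np.mean(pos < c)),
        )
        for c in thresholds
    ]
    return tuple(points)


def auroc(points: Iterable[ROCPoint]) -> float:
    """Trapezoidal area under the ROC curve."""
    pts = sorted(points, key=lambda p: (p.fpr, p.tpr))
    fpr = np.array([0.0] + [p.fpr for p in pts] + [1.0])
    tpr = np.array([0.0] + [p.tpr for p in pts] + [1.0])
    return float(np.trapezoid(tpr, fpr))


def _auroc_rank(spo2, sao2) -> float:
    """Rank-based AUROC (probability hypoxemic < normoxic, ties half)."""
    scores, labels = _scores_labels(spo2, sao2)
    ranks = stats.rankdata(scores)
    n_pos = int(labels.sum())
    n_neg = len(scores) - n_pos
    # Sum of ranks of the positive (hypoxemic) class; low ranks = low scores.
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(1.0 - u / (n_pos * n_neg))


def optimal_cutoff(spo2, sao2, *, criterion: str = "youden") -> float:
    """Cut-off maximizing the sensitivity/specificity compromise.

    ``'youden'`` maximizes J = sensitivity + specificity - 1;
    ``'closest'`` minimizes distance to the (0, 1) ROC corner.  Ties are
    broken toward the higher cut-off (the clinically conservative,
    higher-sensitivity side).  If the optimum is the all-positive sentinel the
    sweep is degenerate and a warning is issued.
    """
    points = roc_curve(spo2, sao2)
    if criterion == "youden":
        objective = np.array([p.tpr - p.fpr for p in points])
    elif criterion == "closest":
        objective = -np.array([np.hypot(p.fpr, 1.0 - p.tpr) for p in points])
    else:
        raise DegenerateDataError(f"unknown criterion {criterion!r}")
    best = objective.max()
    best_idx = int(np.flatnonzero(objective >= best - 1e-12)[-1])
    cutoff = points[best_idx].threshold
    if best_idx == len(points) - 1:
        warnings.warn(
            "optimal cut-off is the all-positive sweep sentinel; classes are not separable",
            stacklevel=2,
        )
    return float(cutoff)


@dataclass(frozen=True)
class DetectionResult:
    """Detection metrics at one cut-off, each with a bootstrap CI."""

    cutoff: float
    cutoff_kind: str  # "fixed" | "optimal"
    n_positive: int
    n_negative: int
    metrics: dict[str, tuple[float | None, float, float]]
    auroc: tuple[float, float, float]
    roc_points: tuple[ROCPoint, ...]


def detection_report(
    spo2,
    sao2,
    *,
    cutoff: float = HYPOXEMIA_THRESHOLD,
    include_optimal: bool = True,
    reps: int = 10_000,
    seed: int | np.random.SeedSequence | None = None,
    level: float = 0.95,
) -> tuple[DetectionResult, ...]:
    """Full detection table rows for one device: fixed cut-off and (optionally)
    the Youden-optimal cut-off, with class-stratified percentile-bootstrap CIs
    for every rate and for the AUROC.  Deterministic given ``seed``.
    """
    scores, labels = _scores_labels(spo2, sao2)
    sao2 = np.asarray(sao2, dtype=float)
    rng = np.random.default_rng(seed)
    pos_idx = np.flatnonzero(labels)
    neg_idx = np.flatnonzero(~labels)
    points = roc_curve(scores, sao2)
    auc = auroc(points)

    cutoffs = [(float(cutoff), "fixed")]
    if include_optimal:
        cutoffs.append((optimal_cutoff(scores, sao2), "optimal"))

    # One shared set of stratified resamples for all cut-offs and the AUROC.
    boot_idx = [
        np.concatenate((rng.choice(pos_idx, len(pos_idx)), rng.choice(neg_idx, len(neg_idx))))
        for _ in range(reps)
    ]
    auc_boot = np.array([_auroc_rank(scores[idx], sao2[idx]) for idx in boot_idx])
    alpha = (1.0 - level) / 2.0
    q = [100 * alpha, 100 * (1 - alpha)]
    auc_ci = np.percentile(auc_boot, q)

    results = []
    for c, kind in cutoffs:
        point = classifier_metrics(error_matrix(scores, sao2, c))
        boot = {name: np.full(reps, np.nan) for name in RATE_NAMES}
        for i, idx in enumerate(boot_idx):
            rates = classifier_metrics(error_matrix(scores[idx], sao2[idx], c))
            for name in RATE_NAMES:
                if rates[name] is not None:
                    boot[name][i] = rates[name]
        metrics = {}
        for name in RATE_NAMES:
            values = boot[name][~np.isnan(boot[name])]
            if len(values):
                lo, hi = np.percentile(values, q)
            else:
                lo = hi = np.nan
            metrics[name] = (point[name], float(lo), float(hi))
        results.append(
            DetectionResult(
                cutoff=c,
                cutoff_kind=kind,
                n_positive=len(pos_idx),
                n_negative=len(neg_idx),
                metrics=metrics,
                auroc=(auc, float(auc_ci[0]), float(auc_ci[1])),
                roc_points=points,
            )
        )
    return tuple(results)


def detection_report_pairs(pairs: Iterable[MatchedPair], **kwargs) -> tuple[DetectionResult, ...]:
    """Convenience wrapper taking matched pairs instead of raw arrays."""
    pairs = list(pairs)
    spo2 = np.asarray([p.spo2_median for p in pairs])
    sao2 = np.asarray([p.sao2 for p in pairs])
    return detection_report(spo2, sao2, **kwargs)
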