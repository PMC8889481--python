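"""ISO-style accuracy statistics over matched SpO2/SaO2 pairs.

Implements the accuracy root-mean-square error (often written A_RMS), mean
bias, mean absolute bias, precision as the SD of residuals around the least
squares line of SpO2 on SaO2, percentile-bootstrap confidence intervals,
Bland-Altman limits of agreement, and the two numeric compliance checks from
ISO 80601-2-61 quoted in pulse-oximeter validation work: RMSE <= 4% with
bootstrap CI upper bound <= 8%, backed by a sample of >= 200 points from
>= 10 subjects balanced over the 70-100% SaO2 range.

All statistic functions take aligned ``spo2`` / ``sao2`` arrays; use
:func:`pair_arrays` to extract them from :class:`~oxival.windowing.MatchedPair`
sequences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

from .errors import DegenerateDataError
from .windowing import MatchedPair

logger = logging.getLogger(__name__)

ISO_RMSE_LIMIT = 4.0
ISO_RMSE_CI_LIMIT = 8.0
ISO_MIN_POINTS = 200
ISO_MIN_SUBJECTS = 10
ISO_BIN_WIDTH = 5.0
ISO_MAX_BIN_FRACTION = 0.40


def pair_arrays(pairs: Iterable[MatchedPair]) -> tuple[np.ndarray, np.ndarray]:
    """Extract aligned (spo2, sao2) arrays from matched pairs."""
    pairs = list(pairs)
    spo2 = np.asarray([p.spo2_median for p in pairs], dtype=float)
    sao2 = np.asarray([p.sao2 for p in pairs], dtype=float)
    return spo2, sao2


def _check(spo2, sao2, n_min: int = 1) -> tuple[np.ndarray, np.ndarray]:
    spo2 = np.asarray(spo2, dtype=float)
    sao2 = np.asarray(sao2, dtype=float)
    if spo2.shape != sao2.shape or spo2.ndim != 1:
        raise DegenerateDataError(f"spo2/sao2 must be equal-length 1-D arrays, got {spo2.shape}/{sao2.shape}")
    if len(spo2) < n_min:
        raise DegenerateDataError(f"need at least {n_min} pairs, got {len(spo2)}")
    return spo2, sao2


def rmse(spo2, sao2) -> float:
    """Root-mean-square error sqrt(sum((spo2_i - sao2_i)^2) / n)."""
    spo2, sao2 = _check(spo2, sao2, 1)
    return float(np.sqrt(np.mean((spo2 - sao2) ** 2)))


def mean_bias(spo2, sao2) -> float:
    """Mean of spo2_i - sao2_i (negative = device underestimates)."""
    spo2, sao2 = _check(spo2, sao2, 1)
    return float(np.mean(spo2 - sao2))


def mean_abs_bias(spo2, sao2) -> float:
    """Mean of |spo2_i - sao2_i|."""
    spo2, sao2 = _check(spo2, sao2, 1)
    return float(np.mean(np.abs(spo2 - sao2)))


def precision_residual_sd(spo2, sao2, *, ddof: int = 2) -> float:
    """SD of residuals around the least-squares fit of SpO2 on SaO2.

    Parameters
    ----------
    ddof:
        Residual degrees-of-freedom correction.  The default 2 matches the
        regression degrees of freedom (slope + intercept); pass 1 for the
        plain n-1 convention.

    Raises
    ------
    DegenerateDataError
        For fewer than 3 pairs or constant SaO2 (no regression possible).
    """
    spo2, sao2 = _check(spo2, sao2, 3)
    if np.ptp(sao2) == 0.0:
        raise DegenerateDataError("constant SaO2: residual-SD regression is degenerate")
    coeffs = np.polynomial.polynomial.polyfit(sao2, spo2, 1)
    residuals = spo2 - np.polynomial.polynomial.polyval(sao2, coeffs)
    return float(np.sqrt(np.sum(residuals**2) / (len(spo2) - ddof)))


def bootstrap_ci(
    statistic: Callable[[np.ndarray, np.ndarray], float],
    spo2,
    sao2,
    *,
    reps: int = 10_000,
    seed: int | np.random.SeedSequence | np.random.Generator | None = None,
    level: float = 0.95,
    clusters: Sequence | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap interval for ``statistic`` over resampled pairs.

    Pairs are resampled with replacement (``reps`` times).  When ``clusters``
    is given (e.g. session ids), whole clusters are resampled instead — a
    sensitivity option for within-participant correlation.  Deterministic for
    a fixed ``seed``.
    """
    spo2, sao2 = _check(spo2, sao2, 2)
    if reps < 1:
        raise DegenerateDataError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(spo2)
    values = np.empty(reps)
    if clusters is None:
        idx = rng.integers(0, n, size=(reps, n))
        for i in range(reps):
            values[i] = statistic(spo2[idx[i]], sao2[idx[i]])
    else:
        clusters = np.asarray(clusters)
        if len(clusters) != n:
            raise DegenerateDataError("clusters must align with pairs")
        unique = np.unique(clusters)
        members = {c: np.flatnonzero(clusters == c) for c in unique}
        for i in range(reps):
            chosen = rng.choice(unique, size=len(unique), replace=True)
            idx = np.concatenate([members[c] for c in chosen])
            values[i] = statistic(spo2[idx], sao2[idx])
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(values, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)


@dataclass(frozen=True)
class BlandAltman:
    mean_bias: float
    loa_lo: float
    loa_hi: float


def bland_altman(spo2, sao2) -> BlandAltman:
    """Mean difference and limits of agreement (bias +/- 1.96 SD, n-1 SD)."""
    spo2, sao2 = _check(spo2, sao2, 2)
    diffs = spo2 - sao2
    bias = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1))
    return BlandAltman(mean_bias=bias, loa_lo=bias - 1.96 * sd, loa_hi=bias + 1.96 * sd)


@dataclass(frozen=True)
class AccuracyReport:
    """One stratum's row of an accuracy table."""

    stratum: str
    n: int
    rmse: float
    rmse_ci: tuple[float, float]
    mean_bias: float
    mean_abs_bias: float
    precision: float | None


def compute_report(
    spo2,
    sao2,
    *,
    stratum: str = "overall",
    reps: int = 10_000,
    seed: int | np.random.SeedSequence | None = None,
    level: float = 0.95,
    precision_ddof: int = 2,
) -> AccuracyReport:
    """Assemble the full accuracy row for one stratum.

    The bootstrap CI covers the RMSE (the statistic the compliance check
    needs).  A degenerate precision regression (constant SaO2 within the
    stratum) is reported as missing with a warning rather than aborting the
    whole table.
    """
    spo2, sao2 = _check(spo2, sao2, 1)
    ci = bootstrap_ci(rmse, spo2, sao2, reps=reps, seed=seed, level=level) if len(spo2) >= 2 else (
        rmse(spo2, sao2),
        rmse(spo2, sao2),
    )
    try:
        precision = precision_residual_sd(spo2, sao2, ddof=precision_ddof)
    except DegenerateDataError as exc:
        logger.warning("stratum %r: precision unavailable (%s)", stratum, exc)
        precision = None
    return AccuracyReport(
        stratum=stratum,
        n=len(spo2),
        rmse=rmse(spo2, sao2),
        rmse_ci=ci,
        mean_bias=mean_bias(spo2, sao2),
        mean_abs_bias=mean_abs_bias(spo2, sao2),
        precision=precision,
    )


def iso_compliance(report: AccuracyReport) -> tuple[bool, list[str]]:
    """RMSE <= 4% and bootstrap CI upper bound <= 8% (both inclusive)."""
    reasons = []
    if report.rmse > ISO_RMSE_LIMIT:
        reasons.append(f"RMSE {report.rmse:.2f}% exceeds {ISO_RMSE_LIMIT}%")
    if report.rmse_ci[1] > ISO_RMSE_CI_LIMIT:
        reasons.append(f"RMSE CI upper bound {report.rmse_ci[1]:.2f}% exceeds {ISO_RMSE_CI_LIMIT}%")
    return (not reasons), reasons


def iso_sample_check(sao2, subjects) -> tuple[bool, list[str]]:
    """Sample-size/balance check: n >= 200, >= 10 subjects, balanced 70-100%.

    The balance proxy requires that no 5%-wide SaO2 bin in [70, 100] holds
    more than 40% of the points.
    """
    sao2 = np.asarray(sao2, dtype=float)
    subjects = np.asarray(subjects)
    if len(sao2) != len(subjects):
        raise DegenerateDataError("sao2 and subjects must align")
    reasons = []
    n = len(sao2)
    if n < ISO_MIN_POINTS:
        reasons.append(f"{n} points < {ISO_MIN_POINTS}")
    n_subjects = len(np.unique(subjects))
    if n_subjects < ISO_MIN_SUBJECTS:
        reasons.append(f"{n_subjects} subjects < {ISO_MIN_SUBJECTS}")
    if n:
        edges = np.arange(70.0, 100.0 + ISO_BIN_WIDTH, ISO_BIN_WIDTH)
        hist, _ = np.histogram(np.clip(sao2, 70.0, 100.0), bins=edges)
        worst = hist.max() / n
        if worst > ISO_MAX_BIN_FRACTION:
            reasons.append(
                f"{100 * worst:.0f}% of points in one {ISO_BIN_WIDTH:.0f}%-wide SaO2 bin "
                f"(limit {100 * ISO_MAX_BIN_FRACTION:.0f}%)"
            )
    return (not reasons), reasons
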