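"""Between-stratum test battery: ANOVA, Tukey-Kramer, Levene, paired Wilcoxon.

ANOVA and Levene wrap SciPy; Tukey-Kramer uses the studentized-range
procedure with unequal-n standard errors (SciPy's ``tukey_hsd``).  The paired
Wilcoxon signed-rank test is implemented here because the exact path must
handle tied absolute differences: the null distribution of W+ is built by
subset-sum dynamic programming over the (doubled, hence integral) average
ranks for n <= 25 nonzero differences, with the usual tie-corrected normal
approximation (continuity-corrected) above.

All tests are two-sided; significance defaults to alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateDataError

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class ComparisonResult:
    test: str
    statistic: float | None
    p_value: float | None
    significant_pairs: frozenset[frozenset] = field(default_factory=frozenset)
    alpha: float = DEFAULT_ALPHA
    pairwise_p: Mapping[tuple[str, str], float] | None = None


def _validated_groups(groups: Mapping[str, Sequence[float]], min_n: int = 2) -> dict[str, np.ndarray]:
    if len(groups) < 2:
        raise DegenerateDataError(f"need at least 2 groups, got {len(groups)}")
    out = {}
    for label, values in groups.items():
        arr = np.asarray(values, dtype=float)
        if arr.ndim != 1 or len(arr) < min_n:
            raise DegenerateDataError(f"group {label!r}: need at least {min_n} values")
        out[str(label)] = arr
    return out


def one_way_anova(groups: Mapping[str, Sequence[float]], *, alpha: float = DEFAULT_ALPHA) -> ComparisonResult:
    """One-way ANOVA F test on the group values.

    Raises :class:`DegenerateDataError` when the pooled within-group variance
    is zero (F undefined).
    """
    data = _validated_groups(groups)
    values = list(data.values())
    if all(np.ptp(v) == 0.0 for v in values):
        raise DegenerateDataError("zero within-group variance: ANOVA F is undefined")
    f_stat, p = stats.f_oneway(*values)
    return ComparisonResult(test="one-way-anova", statistic=float(f_stat), p_value=float(p), alpha=alpha)


def tukey_kramer(groups: Mapping[str, Sequence[float]], *, alpha: float = DEFAULT_ALPHA) -> ComparisonResult:
    """All pairwise comparisons via the Tukey-Kramer studentized-range test.

    Returns the set of significantly different group pairs (the superscript
    structure of a results table) and the full pairwise p-value map.
    """
    data = _validated_groups(groups)
    values = list(data.values())
    if all(np.ptp(v) == 0.0 for v in values):
        raise DegenerateDataError("zero within-group variance: Tukey-Kramer is undefined")
    labels = list(data)
    result = stats.tukey_hsd(*values)
    pairwise = {}
    significant = set()
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if j <= i:
                continue
            p = float(result.pvalue[i, j])
            pairwise[(a, b)] = p
            if p < alpha:
                significant.add(frozenset((a, b)))
    return ComparisonResult(
        test="tukey-kramer",
        statistic=None,
        p_value=None,
        significant_pairs=frozenset(significant),
        alpha=alpha,
        pairwise_p=pairwise,
    )


def levene(
    groups: Mapping[str, Sequence[float]], *, center: str = "mean", alpha: float = DEFAULT_ALPHA
) -> ComparisonResult:
    """Levene's test for equal spread: ANOVA on |deviations from group center|.

    ``center='mean'`` is the classic form; ``center='median'`` gives the
    Brown-Forsythe variant.
    """
    data = _validated_groups(groups)
    stat, p = stats.levene(*data.values(), center=center)
    if not np.isfinite(stat):
        raise DegenerateDataError("degenerate groups: Levene statistic undefined")
    return ComparisonResult(test=f"levene-{center}", statistic=float(stat), p_value=float(p), alpha=alpha)


# ---------------------------------------------------------------------------
# Paired Wilcoxon signed-rank
# ---------------------------------------------------------------------------

EXACT_MAX_N = 25


def _signed_rank_exact_p(w_plus: float, ranks: np.ndarray) -> float:
    """Two-sided exact p for W+ given the (possibly tied) ranks of |d|.

    Doubling average ranks makes them integral, so the 2^n equiprobable sign
    patterns induce a subset-sum distribution computed by dense DP.
    """
    ranks2 = np.rint(2.0 * ranks).astype(int)
    total = int(ranks2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    n_patterns = 2.0 ** len(ranks2)
    w2 = int(round(2.0 * w_plus))
    p_le = counts[: w2 + 1].sum() / n_patterns
    p_ge = counts[w2:].sum() / n_patterns
    return min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_paired(
    x: Sequence[float],
    y: Sequence[float],
    *,
    zero_method: str = "wilcox",
    alpha: float = DEFAULT_ALPHA,
) -> ComparisonResult:
    """Two-sided paired Wilcoxon signed-rank test on ``x - y``.

    Zero differences are dropped (``zero_method='wilcox'``, the convention) or
    handled per Pratt (``'pratt'``: ranked with the rest, then discarded from
    W+ — approximate path only).  Exact enumeration (tie-aware) is used for up
    to 25 nonzero differences; beyond that, the tie-corrected normal
    approximation with continuity correction.

    The reported statistic is W+, the sum of ranks of positive differences.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 1:
        raise DegenerateDataError("x and y must be equal-length 1-D arrays with n >= 1")
    d = x - y
    if np.all(d == 0.0):
        raise DegenerateDataError("all paired differences are zero")
    if zero_method not in ("wilcox", "pratt"):
        raise DegenerateDataError(f"unknown zero_method {zero_method!r}")

    if zero_method == "wilcox":
        d = d[d != 0.0]
        ranks = stats.rankdata(np.abs(d))
        w_plus = float(ranks[d > 0].sum())
        n = len(d)
        if n <= EXACT_MAX_N:
            p = _signed_rank_exact_p(w_plus, ranks)
            return ComparisonResult(test="wilcoxon-signed-rank", statistic=w_plus, p_value=p, alpha=alpha)
        mu = n * (n + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(tie_counts**3 - tie_counts) / 48.0
    else:  # pratt: rank zeros with the rest, drop them from W+, adjust moments
        n = len(d)
        ranks = stats.rankdata(np.abs(d))
        w_plus = float(ranks[d > 0].sum())
        n_zero = int(np.sum(d == 0.0))
        mu = (n * (n + 1) - n_zero * (n_zero + 1)) / 4.0
        _, tie_counts = np.unique(ranks[d != 0.0], return_counts=True)
        sigma2 = (
            n * (n + 1) * (2 * n + 1) - n_zero * (n_zero + 1) * (2 * n_zero + 1)
        ) / 24.0 - np.sum(tie_counts**3 - tie_counts) / 48.0

    if sigma2 <= 0:
        raise DegenerateDataError("degenerate signed-rank variance")
    correction = 0.5 * np.sign(w_plus - mu)
    z = (w_plus - mu - correction) / np.sqrt(sigma2)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return ComparisonResult(test="wilcoxon-signed-rank", statistic=w_plus, p_value=min(1.0, p), alpha=alpha)
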