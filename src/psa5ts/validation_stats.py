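"""Statistical machinery for the convergent/discriminant validity analyses.

Covers descriptive summaries (with an exact order-statistic confidence
interval for the median), Spearman rank correlations with the interpretation
bands used in clinimetric work, ROC analysis against a binary external
criterion (AUC via the tie-corrected Mann-Whitney statistic, Hanley-McNeil
standard errors, exact-binomial-shaped confidence intervals), DeLong's paired
test for correlated AUCs, and nonparametric group comparisons.

Hypothesis tests (Shapiro-Wilk, skewness/kurtosis, Mann-Whitney,
Kruskal-Wallis, chi-square, Spearman's p) delegate to :mod:`scipy.stats`;
the ROC/AUC machinery, the Hanley-McNeil and DeLong variances and the median
interval are implemented here.

All p-values are two-sided; significance is conventionally read at 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConstantInputError",
    "SingleClassError",
    "CorrelationCell",
    "RocResult",
    "DescriptiveSummary",
    "spearman",
    "interpret_rho",
    "correlation_matrix",
    "roc",
    "auc_band",
    "compare_aucs",
    "group_compare",
    "chi_square",
    "describe",
    "median_ci_ranks",
    "hanley_mcneil_se",
]


class ConstantInputError(ValueError):
    """Rank correlation is undefined for a constant sample."""


class SingleClassError(ValueError):
    """A discriminant analysis needs both criterion classes to be present."""


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------

#: |rho| interpretation bands.  The published cut points (<=0.25 little,
#: 0.26-0.49 low, 0.50-0.69 moderate, 0.70-0.89 high, >0.90 very high) leave
#: slivers between bands; they are closed into half-open intervals
#: [0, 0.26) / [0.26, 0.50) / [0.50, 0.70) / [0.70, 0.90] / (0.90, 1].
_RHO_BANDS = (
    (0.26, "little-to-none"),
    (0.50, "low"),
    (0.70, "moderate"),
)


def interpret_rho(rho: float) -> str:
    if not -1 <= rho <= 1:
        raise ValueError(f"rho must be in [-1, 1], got {rho}")
    a = abs(rho)
    for bound, label in _RHO_BANDS:
        if a < bound:
            return label
    return "high" if a <= 0.90 else "very high"


@dataclass(frozen=True)
class CorrelationCell:
    rho: float
    p: float
    band: str
    n: int


def spearman(x: Sequence, y: Sequence) -> CorrelationCell:
    """Spearman rank correlation with midrank tie handling; p from the
    t approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D samples")
    if x.size < 3:
        raise ValueError("Spearman correlation needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("correlation undefined for a constant sample")
    res = stats.spearmanr(x, y)
    rho = float(res.statistic)
    return CorrelationCell(rho=rho, p=float(res.pvalue), band=interpret_rho(rho), n=x.size)


def correlation_matrix(scores: pd.DataFrame) -> pd.DataFrame:
    """Upper-triangular matrix of :class:`CorrelationCell` for every
    instrument pair (symmetric semantics; the lower triangle is left empty)."""
    cols = list(scores.columns)
    if len(cols) < 2:
        raise ValueError("correlation matrix needs at least two instruments")
    out = pd.DataFrame(index=cols, columns=cols, dtype=object)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            out.loc[a, b] = spearman(scores[a], scores[b])
    return out


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    """Hanley & McNeil standard error of a trapezoidal AUC.

    Uses the exponential approximation Q1 = A/(2-A), Q2 = 2A^2/(1+A).
    Exactly 0 at AUC = 1 and shrinks as either class grows.
    """
    a = auc
    q1 = a / (2 - a)
    q2 = 2 * a * a / (1 + a)
    var = (a * (1 - a) + (n_pos - 1) * (q1 - a * a) + (n_neg - 1) * (q2 - a * a)) / (
        n_pos * n_neg
    )
    return math.sqrt(max(var, 0.0))


def _exact_binomial_ci(auc: float, se: float, n_pos: int, n_neg: int,
                       level: float = 0.95) -> tuple:
    """Clopper-Pearson-shaped interval for the AUC.

    The interval treats the AUC as a binomial proportion with the effective
    sample size implied by the Hanley-McNeil variance,
    ``n_eff = A(1-A)/SE^2``, so it keeps that variance while respecting the
    [0, 1] bounds.  At degenerate AUCs (0 or 1, SE = 0) the effective size
    falls back to ``min(n_pos, n_neg)``.
    """
    alpha = 1 - level
    if se > 0 and 0 < auc < 1:
        n_eff = auc * (1 - auc) / (se * se)
    else:
        n_eff = float(min(n_pos, n_neg))
    x = auc * n_eff
    lo = 0.0 if x <= 0 else float(stats.beta.ppf(alpha / 2, x, n_eff - x + 1))
    hi = 1.0 if x >= n_eff else float(stats.beta.ppf(1 - alpha / 2, x + 1, n_eff - x))
    return (lo, hi)


@dataclass(frozen=True)
class RocResult:
    """ROC analysis of one score against a binary criterion."""

    auc: float
    se: float
    ci95: tuple
    n_pos: int
    n_neg: int
    curve: tuple = field(repr=False)  # ((fpr, tpr) per threshold, descending)


def _midrank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC = (U statistic)/(n_pos * n_neg) via midranks (ties count 1/2)."""
    n_pos = int(labels.sum())
    ranks = stats.rankdata(scores)  # midranks
    r_pos = ranks[labels].sum()
    u = r_pos - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * (scores.size - n_pos)))


def roc(scores: Sequence, labels: Sequence) -> RocResult:
    """ROC of ``scores`` against binary ``labels`` (True = the positive,
    "active" class; higher score should predict it).

    The AUC equals the probability that a random positive outscores a random
    negative (ties counting one half).  The curve is evaluated at every
    observed score plus sentinels, so it runs from (0, 0) to (1, 1).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    n_pos = int(labels.sum())
    n_neg = int(scores.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise SingleClassError("both criterion classes must be non-empty")
    a = _midrank_auc(scores, labels)
    se = hanley_mcneil_se(a, n_pos, n_neg)
    thresholds = np.concatenate(([np.inf], np.unique(scores)[::-1], [-np.inf]))
    pos_scores = scores[labels]
    neg_scores = scores[~labels]
    curve = tuple(
        (float((neg_scores >= t).mean()), float((pos_scores >= t).mean()))
        for t in thresholds
    )
    return RocResult(
        auc=a,
        se=se,
        ci95=_exact_binomial_ci(a, se, n_pos, n_neg),
        n_pos=n_pos,
        n_neg=n_neg,
        curve=curve,
    )


def auc_band(auc: float) -> str:
    """'poor' ([0.5, 0.70)), 'useful' ([0.70, 0.90)) or 'high' (>= 0.90)."""
    if not 0.5 <= auc <= 1:
        raise ValueError(f"AUC must be in [0.5, 1], got {auc}")
    if auc < 0.70:
        return "poor"
    if auc < 0.90:
        return "useful"
    return "high"


# ---------------------------------------------------------------------------
# DeLong paired AUC comparison
# ---------------------------------------------------------------------------

def _placements(scores: np.ndarray, labels: np.ndarray) -> tuple:
    """DeLong placement values (V10 for positives, V01 for negatives)."""
    pos = scores[labels]
    neg = scores[~labels]
    m, n = pos.size, neg.size
    all_ranks = stats.rankdata(np.concatenate([pos, neg]))
    pos_ranks = stats.rankdata(pos)
    neg_ranks = stats.rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    return v10, v01


def compare_aucs(scores_a: Sequence, scores_b: Sequence, labels: Sequence) -> dict:
    """DeLong's paired test for two correlated AUCs measured on the same
    cases against the same binary criterion.

    Returns ``{'auc_a', 'auc_b', 'difference', 'se', 'z', 'p'}``.  Identical
    score columns (or any order-preserving transform of one another) give a
    zero difference with p = 1.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if not (scores_a.shape == scores_b.shape == labels.shape):
        raise ValueError("paired AUC comparison requires identical case sets")
    if labels.all() or not labels.any():
        raise SingleClassError("both criterion classes must be non-empty")
    v10a, v01a = _placements(scores_a, labels)
    v10b, v01b = _placements(scores_b, labels)
    auc_a, auc_b = float(v10a.mean()), float(v10b.mean())
    m, n = v10a.size, v01a.size
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1) if n > 1 else np.zeros((2, 2))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    diff = auc_a - auc_b
    if var <= 0:
        z = 0.0 if diff == 0 else math.inf * math.copysign(1, diff)
        p = 1.0 if diff == 0 else 0.0
    else:
        z = diff / math.sqrt(var)
        p = 2 * float(stats.norm.sf(abs(z)))
    return {
        "auc_a": auc_a,
        "auc_b": auc_b,
        "difference": diff,
        "se": math.sqrt(max(var, 0.0)),
        "z": z,
        "p": p,
    }


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------

def group_compare(values: Sequence, groups: Sequence, *, force: Optional[str] = None) -> dict:
    """Nonparametric comparison of a continuous variable across groups.

    Two groups use the Mann-Whitney U test, more use Kruskal-Wallis (both
    tie-corrected, two-sided).  ``force='kruskal'`` applies Kruskal-Wallis
    regardless of k (its chi-square p at k = 2 is the asymptotic equivalent
    of the Mann-Whitney normal approximation).
    Returns ``{'test', 'statistic', 'p', 'k'}``.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must be equal length")
    levels = pd.unique(groups)
    samples = [values[groups == g] for g in levels]
    if len(samples) < 2 or any(s.size == 0 for s in samples):
        raise ValueError("need at least two non-empty groups")
    if force not in (None, "kruskal"):
        raise ValueError(f"unknown force option {force!r}")
    if len(samples) == 2 and force is None:
        stat, p = stats.mannwhitneyu(samples[0], samples[1], alternative="two-sided")
        name = "mann-whitney"
    else:
        stat, p = stats.kruskal(*samples)
        name = "kruskal-wallis"
    return {"test": name, "statistic": float(stat), "p": float(p), "k": len(samples)}


def chi_square(table) -> dict:
    """Pearson chi-square test of independence on a contingency table."""
    res = stats.chi2_contingency(np.asarray(table), correction=False)
    return {"test": "chi-square", "statistic": float(res.statistic),
            "p": float(res.pvalue), "dof": int(res.dof)}


# ---------------------------------------------------------------------------
# Descriptive summaries
# ---------------------------------------------------------------------------

def median_ci_ranks(n: int, level: float = 0.95) -> tuple:
    """1-indexed order-statistic ranks (l, u) of a conservative exact
    binomial confidence interval for the median.

    l is the largest rank with ``P(Bin(n, 1/2) <= l-1) <= alpha/2`` and
    ``u = n + 1 - l``, so ``P(X_(l) <= median <= X_(u)) >= level``.
    """
    if n < 1:
        raise ValueError("n must be positive")
    alpha = 1 - level
    l = 0
    while stats.binom.cdf(l, n, 0.5) <= alpha / 2:
        l += 1
    # cdf(l-1) <= alpha/2 fails at current l, so the largest valid count is l
    return (max(l, 1), n + 1 - max(l, 1))


@dataclass
class DescriptiveSummary:
    """The descriptive panel reported for each index.

    Fields that cannot be computed for the sample at hand (e.g. normality
    tests on constant data) are ``None``.
    """

    n: int
    lowest: float
    highest: float
    mean: float
    mean_ci95: tuple
    median: float
    median_ci95: Optional[tuple]
    variance: float
    sd: float
    relative_sd: Optional[float]
    sem: float
    skewness: Optional[float]
    skewness_p: Optional[float]
    kurtosis: Optional[float]
    kurtosis_p: Optional[float]
    shapiro_w: Optional[float]
    shapiro_p: Optional[float]
    normal: Optional[bool]  # Shapiro-Wilk decision at alpha = 0.05
    iqr: tuple


def describe(values: Sequence) -> DescriptiveSummary:
    """All descriptive statistics for one score column (n >= 3)."""
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 3:
        raise ValueError("describe needs n >= 3")
    mean = float(x.mean())
    var = float(x.var(ddof=1))
    sd = math.sqrt(var)
    sem = sd / math.sqrt(n)
    t_crit = float(stats.t.ppf(0.975, n - 1))
    l, u = median_ci_ranks(n)
    constant = np.ptp(x) == 0

    skew = skew_p = kurt = kurt_p = None
    if not constant and n >= 8:  # skewtest's minimum sample size
        skew = float(stats.skew(x, bias=False))
        skew_p = float(stats.skewtest(x).pvalue)
    if not constant and n >= 20:  # kurtosistest's validity floor
        kurt = float(stats.kurtosis(x, bias=False))
        kurt_p = float(stats.kurtosistest(x).pvalue)
    sw_w = sw_p = normal = None
    if not constant:
        sw = stats.shapiro(x)
        sw_w, sw_p = float(sw.statistic), float(sw.pvalue)
        normal = sw_p >= 0.05

    return DescriptiveSummary(
        n=n,
        lowest=float(x[0]),
        highest=float(x[-1]),
        mean=mean,
        mean_ci95=(mean - t_crit * sem, mean + t_crit * sem),
        median=float(np.median(x)),
        median_ci95=(float(x[l - 1]), float(x[u - 1])),
        variance=var,
        sd=sd,
        relative_sd=(sd / mean) if mean > 0 else None,
        sem=sem,
        skewness=skew,
        skewness_p=skew_p,
        kurtosis=kurt,
        kurtosis_p=kurt_p,
        shapiro_w=sw_w,
        shapiro_p=sw_p,
        normal=normal,
        iqr=(float(np.percentile(x, 25)), float(np.percentile(x, 75))),
    )
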