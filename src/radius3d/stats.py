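"""Statistical workflow for cohort measurement tables.

Covers rater reliability (two-way ICC), normality screening (Shapiro-Wilk),
repeated-measures comparison of displacement magnitudes (Friedman with a
Scheffe-type rank post-hoc), paired pre/post comparison (Wilcoxon
signed-rank) and 2D-3D correlation (Pearson).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "StatResult",
    "PairwiseResult",
    "icc_two_way",
    "shapiro_wilk",
    "friedman",
    "scheffe_posthoc",
    "wilcoxon_signed_rank",
    "pearson_r",
]


@dataclass(frozen=True)
class StatResult:
    statistic: float
    p_value: float
    method: str
    df: Optional[float] = None
    n: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value out of [0, 1]: {self.p_value}")

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "p_value": self.p_value,
            "method": self.method,
            "df": self.df,
            "n": self.n,
        }


@dataclass(frozen=True)
class PairwiseResult:
    pair: tuple
    statistic: float
    p_value: float
    significant: bool

    def to_dict(self) -> dict:
        return {
            "pair": list(self.pair),
            "statistic": self.statistic,
            "p_value": self.p_value,
            "significant": self.significant,
        }


def _as_table(table, min_rows: int, min_cols: int, name: str) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.ndim != 2:
        raise ValueError(f"{name} must be 2-dimensional, got shape {t.shape}")
    n, k = t.shape
    if n < min_rows or k < min_cols:
        raise ValueError(f"{name} must be at least {min_rows}x{min_cols}, got {n}x{k}")
    if np.isnan(t).any():
        raise ValueError(f"{name} contains missing cells")
    return t


# ---------------------------------------------------------------------------
# reliability


def icc_two_way(table, form: Literal["ICC2_1", "ICC3_1"] = "ICC2_1") -> StatResult:
    """Intraclass correlation from a subjects x raters table.

    ``ICC2_1`` is the two-way random-effects, absolute-agreement, single
    measurement coefficient

        (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    and ``ICC3_1`` the two-way mixed, consistency form
    ``(MSR - MSE) / (MSR + (k-1) MSE)``, both from the two-way ANOVA mean
    squares (MSR rows/subjects, MSC columns/raters, MSE residual).  The
    p-value is from the F test ``MSR / MSE``.
    """
    t = _as_table(table, min_rows=3, min_cols=2, name="rater table")
    n, k = t.shape
    grand = t.mean()
    ss_total = float(((t - grand) ** 2).sum())
    if ss_total < 1e-15:
        raise ValueError("table has zero total variance; ICC undefined")

    row_means = t.mean(axis=1)
    col_means = t.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols

    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    if form == "ICC2_1":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    elif form == "ICC3_1":
        denom = msr + (k - 1) * mse
    else:
        raise ValueError(f"unknown ICC form {form!r}")
    if abs(denom) < 1e-15:
        raise ValueError("ICC denominator is zero; no usable variance")
    icc = (msr - mse) / denom

    if mse <= 1e-300:
        p = 0.0 if msr > mse else 1.0
    else:
        f = msr / mse
        p = float(sps.f.sf(f, n - 1, (n - 1) * (k - 1)))
    return StatResult(statistic=float(icc), p_value=p, method=form, df=float(n - 1), n=n)


# ---------------------------------------------------------------------------
# normality


def shapiro_wilk(sample) -> StatResult:
    """Shapiro-Wilk normality test (delegates to scipy)."""
    x = np.asarray(sample, dtype=float).ravel()
    if not 3 <= len(x) <= 5000:
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 5000, got n={len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("sample is constant; normality test undefined")
    w, p = sps.shapiro(x)
    return StatResult(statistic=float(w), p_value=float(p), method="shapiro_wilk", n=len(x))


# ---------------------------------------------------------------------------
# Friedman and post hoc


def _block_ranks(matrix: np.ndarray) -> np.ndarray:
    """Mid-ranks within each row (block)."""
    return np.apply_along_axis(sps.rankdata, 1, matrix)


def _friedman_statistic_from_ranks(ranks: np.ndarray) -> float:
    """Tie-corrected Friedman chi-square from a blocks x treatments rank table.

    Uses the general form
        chi2 = (k-1) * (sum_j R_j^2 - n^2 k (k+1)^2 / 4)
               / (sum_ij r_ij^2 - n k (k+1)^2 / 4)
    which reduces to the classic 12/(nk(k+1)) sum R_j^2 - 3n(k+1) formula
    when there are no ties.  A fully tied table yields 0 by convention.
    """
    n, k = ranks.shape
    col_sums = ranks.sum(axis=0)
    num = (k - 1) * (float((col_sums**2).sum()) - n**2 * k * (k + 1) ** 2 / 4.0)
    den = float((ranks**2).sum()) - n * k * (k + 1) ** 2 / 4.0
    if den <= 1e-12:
        return 0.0
    return num / den


def friedman(matrix, p_method: Literal["auto", "asymptotic", "exact"] = "auto") -> StatResult:
    """Friedman rank test for blocks x treatments data.

    Mid-ranks are used within blocks and the statistic carries the standard
    tie correction.  The p-value comes from the chi-square(k-1) reference
    distribution, or from exhaustive within-block permutation enumeration
    (``exact``; chosen automatically when k!^n <= 100000).  With every
    treatment tied in every block the statistic is 0 and p is 1.
    """
    m = _as_table(matrix, min_rows=2, min_cols=2, name="friedman matrix")
    n, k = m.shape
    ranks = _block_ranks(m)
    stat = _friedman_statistic_from_ranks(ranks)

    n_perms = math.factorial(k) ** n
    if p_method == "auto":
        p_method = "exact" if n_perms <= 100_000 else "asymptotic"
    if p_method == "exact":
        if n_perms > 2_000_000:
            raise ValueError(f"exact enumeration infeasible: k!^n = {n_perms}")
        p = _friedman_exact_p(ranks, stat)
        method = "friedman_exact"
    else:
        p = float(sps.chi2.sf(stat, k - 1)) if stat > 0 else 1.0
        method = "friedman_chi2"
    return StatResult(statistic=stat, p_value=p, method=method, df=float(k - 1), n=n)


def _friedman_exact_p(ranks: np.ndarray, observed: float) -> float:
    """P(chi2_perm >= observed) under all within-block rank permutations."""
    n, k = ranks.shape
    perms = list(itertools.permutations(range(k)))
    # all orderings of each block's rank vector; tie patterns are preserved
    block_perms = [np.array([ranks[i, list(p)] for p in perms]) for i in range(n)]
    count = 0
    total = 0
    for combo in itertools.product(*[range(len(perms))] * n):
        table = np.array([block_perms[i][j] for i, j in enumerate(combo)])
        if _friedman_statistic_from_ranks(table) >= observed - 1e-12:
            count += 1
        total += 1
    return count / total


def scheffe_posthoc(matrix, alpha: float = 0.05, labels: Optional[Sequence] = None) -> list[PairwiseResult]:
    """Scheffe-type pairwise rank comparisons after a Friedman test.

    For each treatment pair the statistic (R_i - R_j)^2 / (n k (k+1) / 6)
    (R = within-block rank sums) is referred to the chi-square(k-1)
    distribution; pairs with p < ``alpha`` are flagged.
    """
    m = _as_table(matrix, min_rows=2, min_cols=2, name="friedman matrix")
    n, k = m.shape
    if labels is None:
        labels = list(range(k))
    elif len(labels) != k:
        raise ValueError("labels length must match the number of treatments")
    ranks = _block_ranks(m)
    col_sums = ranks.sum(axis=0)
    scale = n * k * (k + 1) / 6.0
    results = []
    for i, j in itertools.combinations(range(k), 2):
        stat = float((col_sums[i] - col_sums[j]) ** 2 / scale)
        p = float(sps.chi2.sf(stat, k - 1))
        results.append(
            PairwiseResult(pair=(labels[i], labels[j]), statistic=stat, p_value=p, significant=p < alpha)
        )
    return results


# ---------------------------------------------------------------------------
# paired and correlation tests


def wilcoxon_signed_rank(
    pre_values,
    post_values,
    alternative: Literal["two-sided", "greater", "less"] = "two-sided",
) -> StatResult:
    """Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped; |differences| are mid-ranked.  The null
    distribution is exact for n <= 25 without ties and a normal
    approximation otherwise.  ``alternative`` refers to post - pre.
    """
    pre = np.asarray(pre_values, dtype=float).ravel()
    post = np.asarray(post_values, dtype=float).ravel()
    if pre.shape != post.shape:
        raise ValueError("paired samples must have equal length")
    if len(pre) < 5:
        raise ValueError(f"need at least 5 pairs, got {len(pre)}")
    d = post - pre
    d = d[d != 0]
    if len(d) == 0:
        raise ValueError("all paired differences are zero; test undefined")
    # exact enumeration for small n (mid-ranks are used when |d| ties occur)
    method = "approx" if len(d) > 25 else "exact"
    res = sps.wilcoxon(d, zero_method="wilcox", alternative=alternative, method=method)
    return StatResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method=f"wilcoxon_{method}",
        n=len(d),
    )


def pearson_r(x_values, y_values) -> StatResult:
    """Pearson correlation with two-sided p from the t transform."""
    x = np.asarray(x_values, dtype=float).ravel()
    y = np.asarray(y_values, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError(f"need at least 3 pairs, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input; correlation undefined")
    r, p = sps.pearsonr(x, y)
    return StatResult(statistic=float(r), p_value=float(p), method="pearson", df=float(len(x) - 2), n=len(x))
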