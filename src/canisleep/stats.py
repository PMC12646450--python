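"""Nonparametric group tests shared by all comparison stages.

Paired Wilcoxon signed-rank for within-subject contrasts (wakefulness and
drowsiness, and all hypnogram metrics), Mann-Whitney U where sessions
lacking a state break the pairing (NREM, REM), a Kolmogorov-Smirnov
normality diagnostic (reported, never used to gate the nonparametric
tests), and Kruskal-Wallis with Dunn's post-hoc z-tests for across-state
comparisons. Significance level alpha = 0.05 throughout unless a stage
states otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    n_used: int
    paired: bool
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError("p-value outside [0, 1]")


def paired_wilcoxon(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided paired Wilcoxon signed-rank test.

    Incomplete pairs (NaN in either member) are dropped; zero differences
    are dropped (Wilcoxon's original rule). The exact null distribution is
    used for n <= 25 (ties handled through the permutation distribution),
    the tie-corrected normal approximation with continuity correction
    otherwise. All-zero differences give a degenerate result with p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n_used = int(x.size)
    if n_used < 2:
        raise ValueError("need at least 2 complete pairs")
    d = x - y
    if np.all(d == 0):
        return TestResult(0.0, 1.0, "wilcoxon", n_used, True, degenerate=True)
    method = "exact" if n_used <= 25 else "approx"
    res = sstats.wilcoxon(x, y, zero_method="wilcox", alternative="two-sided",
                          correction=(method == "approx"), method=method)
    return TestResult(float(res.statistic), float(min(res.pvalue, 1.0)),
                      "wilcoxon", n_used, True)


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U (unpaired Wilcoxon rank-sum) test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        return TestResult(float(x.size * y.size / 2), 1.0, "mann-whitney",
                          int(x.size + y.size), False, degenerate=True)
    method = "exact" if max(x.size, y.size) <= 25 else "asymptotic"
    res = sstats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(float(res.statistic), float(min(res.pvalue, 1.0)),
                      "mann-whitney", int(x.size + y.size), False)


def ks_normality(x: Sequence[float]) -> TestResult:
    """One-sample KS test against a normal with the sample mean and SD.

    Diagnostic only: the pipeline's tests are nonparametric regardless.
    """
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 3:
        raise ValueError("need at least 3 values")
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        raise ValueError("degenerate sample (zero standard deviation)")
    res = sstats.kstest(x, "norm", args=(float(np.mean(x)), sd))
    return TestResult(float(res.statistic), float(res.pvalue),
                      "ks-normality", int(x.size), False)


def kruskal_dunn(groups: Mapping[str, Sequence[float]],
                 p_adjust: str = "holm",
                 ) -> tuple[TestResult, pd.DataFrame]:
    """Kruskal-Wallis omnibus test plus Dunn's pairwise post-hoc z-tests.

    Dunn's z compares mean ranks of the pooled sample,
    ``z = (R_i - R_j) / sqrt((N(N+1)/12 - T)(1/n_i + 1/n_j))`` with the tie
    correction ``T = sum(t^3 - t) / (12 (N - 1))``. Pairwise two-sided
    p-values are adjusted over the family (``holm`` default; ``bonferroni``
    or ``none`` available) and returned as a symmetric matrix.
    """
    labels = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    arrays = [a[~np.isnan(a)] for a in arrays]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 values each")
    if p_adjust not in ("holm", "bonferroni", "none"):
        raise ValueError(f"unknown p_adjust {p_adjust!r}")

    h, p = sstats.kruskal(*arrays)
    omnibus = TestResult(float(h), float(p), "kruskal-wallis",
                         int(sum(a.size for a in arrays)), False)

    pooled = np.concatenate(arrays)
    ranks = sstats.rankdata(pooled)
    n_total = pooled.size
    sizes = [a.size for a in arrays]
    bounds = np.cumsum([0, *sizes])
    mean_ranks = [ranks[bounds[i]:bounds[i + 1]].mean()
                  for i in range(len(arrays))]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    pairs, raw_p, zvals = [], [], []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
            pairs.append((labels[i], labels[j]))
            zvals.append(z)
            raw_p.append(2.0 * sstats.norm.sf(abs(z)))
    if p_adjust == "none":
        adj = np.minimum(raw_p, 1.0)
    else:
        adj = multipletests(raw_p, method=p_adjust)[1]

    mat = pd.DataFrame(np.nan, index=labels, columns=labels)
    np.fill_diagonal(mat.values, 1.0)
    for (a, b), p_ij in zip(pairs, adj):
        mat.loc[a, b] = mat.loc[b, a] = p_ij
    return omnibus, mat
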