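"""Hypothesis tests used throughout the pipeline.

Classifier accuracies are tested against chance with the exact binomial
test (one-sided greater by default: the question is always "better than
chance"). Similarity distributions are compared with the Wilcoxon rank-sum
test (normal approximation with tie correction, reported as a Z score).
Groups of category accuracies are compared with the Kruskal-Wallis test,
optionally followed by a Tukey HSD post hoc on rank-transformed data (a
rank-based Dunn procedure is available as an alternative).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats as sps


@dataclass
class TestResult:
    test: str
    statistic: float
    p_value: float
    n: tuple
    side: str = "two-sided"
    alpha: float = 0.05
    extra: dict = field(default_factory=dict)

    @property
    def significant(self):
        return bool(self.p_value < self.alpha)


def binomial_test(k: int, n: int, p0: float = 0.5,
                  side: str = "greater") -> TestResult:
    """Exact binomial test of k successes in n trials against chance p0."""
    if not (0 <= k <= n) or n < 1:
        raise ValueError("need 0 <= k <= n, n >= 1")
    if not (0.0 < p0 < 1.0):
        raise ValueError("p0 must lie in (0, 1)")
    res = sps.binomtest(int(k), int(n), p0, alternative=side)
    return TestResult("binomial", k / n, float(res.pvalue), (n,), side)


def binomial_accuracy_bound(n: int, p0: float = 0.5, alpha: float = 0.001) -> float:
    """Smallest accuracy whose one-sided binomial p against p0 is < alpha."""
    k = int(sps.binom.isf(alpha, n, p0))
    while k <= n and sps.binom.sf(k - 1, n, p0) >= alpha:
        k += 1
    return k / n


def wilcoxon_rank_sum(x, y) -> TestResult:
    """Two-sided Wilcoxon rank-sum test, normal approximation with tie
    correction, reported as a Z statistic (positive when x ranks above y)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        raise ValueError("degenerate: all pooled values identical")
    ranks = sps.rankdata(pooled)
    W = ranks[:n1].sum()
    mu = n1 * (n1 + n2 + 1) / 2.0
    _, t = np.unique(pooled, return_counts=True)
    N = n1 + n2
    tie_term = (t**3 - t).sum() / (N * (N - 1.0))
    var = n1 * n2 / 12.0 * (N + 1.0 - tie_term)
    if var <= 0:
        raise ValueError("degenerate: zero rank variance")
    z = (W - mu) / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return TestResult("wilcoxon_rank_sum", float(z), float(min(p, 1.0)),
                      (n1, n2), "two-sided")


def kruskal_wallis(groups, posthoc: bool = False,
                   posthoc_method: str = "tukey") -> TestResult:
    """Kruskal-Wallis H test over >= 3 groups, chi-square p-value.

    With ``posthoc=True``, pairwise comparisons are added: Tukey HSD on the
    rank-transformed pooled data (default) or Dunn's z tests with Bonferroni
    correction.
    """
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 3:
        raise ValueError("need >= 3 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("groups must be non-empty")
    H, p = sps.kruskal(*groups)
    result = TestResult("kruskal_wallis", float(H), float(p),
                        tuple(len(g) for g in groups))
    if posthoc:
        pooled = np.concatenate(groups)
        labels = np.concatenate([np.full(len(g), i) for i, g in enumerate(groups)])
        ranks = sps.rankdata(pooled)
        if posthoc_method == "tukey":
            from statsmodels.stats.multicomp import pairwise_tukeyhsd

            from itertools import combinations

            hsd = pairwise_tukeyhsd(ranks, labels)
            pairs = list(combinations(range(len(groups)), 2))
            result.extra["posthoc"] = [
                {"groups": pair, "p": float(pv)}
                for pair, pv in zip(pairs, hsd.pvalues)]
        elif posthoc_method == "dunn":
            N = len(pooled)
            _, t = np.unique(pooled, return_counts=True)
            tie = 1.0 - (t**3 - t).sum() / (N**3 - N)
            var0 = N * (N + 1) / 12.0 * tie
            means = [ranks[labels == i].mean() for i in range(len(groups))]
            ns = [len(g) for g in groups]
            comps = []
            m = len(groups) * (len(groups) - 1) // 2
            for i in range(len(groups)):
                for j in range(i + 1, len(groups)):
                    se = np.sqrt(var0 * (1.0 / ns[i] + 1.0 / ns[j]))
                    z = (means[i] - means[j]) / se
                    comps.append({"groups": (i, j), "z": float(z),
                                  "p": float(min(1.0, 2 * sps.norm.sf(abs(z)) * m))})
            result.extra["posthoc"] = comps
        else:
            raise ValueError(f"unknown posthoc method {posthoc_method!r}")
    return result
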