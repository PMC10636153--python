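"""Bootstrap estimation statistics and the rank-test/Bonferroni policy.

Effect sizes are reported as bootstrap sampling distributions of the mean with
95% percentile confidence intervals, complementing Wilcoxon signed-rank /
rank-sum null-hypothesis tests with Bonferroni correction for the three
pairwise class comparisons (alpha/3 = 0.0167).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "BootResult",
    "boot_mean",
    "boot_mean_diff",
    "signed_rank_vs_zero",
    "rank_sum",
    "bonferroni",
]


@dataclass
class BootResult:
    point: float
    samples: np.ndarray
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int


def boot_mean(values, n_boot=10_000, seed=0, ci=95.0):
    """Bootstrap sampling distribution of the mean with a percentile CI."""
    x = np.asarray(values, float)
    if x.size < 2:
        raise ValueError("need at least 2 values to bootstrap")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(int(n_boot), x.size))
    samples = x[idx].mean(axis=1)
    lo, hi = np.percentile(samples, [(100 - ci) / 2, 100 - (100 - ci) / 2])
    return BootResult(float(x.mean()), samples, float(lo), float(hi), int(n_boot), int(seed))


def boot_mean_diff(a, b, n_boot=10_000, seed=0, ci=95.0):
    """Bootstrap distribution of mean(a) - mean(b) (independent resampling)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    rng = np.random.default_rng(seed)
    sa = a[rng.integers(0, a.size, size=(int(n_boot), a.size))].mean(axis=1)
    sb = b[rng.integers(0, b.size, size=(int(n_boot), b.size))].mean(axis=1)
    samples = sa - sb
    lo, hi = np.percentile(samples, [(100 - ci) / 2, 100 - (100 - ci) / 2])
    return BootResult(float(a.mean() - b.mean()), samples, float(lo), float(hi),
                      int(n_boot), int(seed))


def signed_rank_vs_zero(values):
    """Two-sided Wilcoxon signed-rank test of median difference from zero."""
    x = np.asarray(values, float)
    if np.all(x == 0):
        return 1.0
    return float(stats.wilcoxon(x, alternative="two-sided").pvalue)


def rank_sum(a, b):
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test between two samples."""
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def bonferroni(p_values, n=None, alpha=0.05):
    """Bonferroni decisions: significant iff p < alpha / n.

    Returns (decisions, threshold); with the study's three pairwise class
    comparisons (n=3) the threshold is 0.05/3 = 0.0167.
    """
    p = np.asarray(p_values, float)
    if n is None:
        n = p.size
    threshold = alpha / n
    return p < threshold, float(threshold)
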