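"""Distance-based multivariate permutation F-test and auxiliary tests.

Burst feature distributions are compared across regions with a
non-parametric multivariate analysis of variance: with K groups of feature
vectors Y_ij, the statistic is

    F = SS_A / SS_W,
    SS_A = sum_i n_i * ||Ybar - Ybar_i||^2 / (K - 1),
    SS_W = sum_i sum_j ||Ybar_i - Y_ij||^2 / (N - K),

where ||.|| is the Euclidean distance, Ybar the overall and Ybar_i the
group mean feature vector. Significance comes from shuffling the group
labels (group sizes fixed) and recomputing F; the p-value uses the +1
correction, so p >= 1/(n_perm + 1). For one-dimensional data with K = 2
this F is exactly the classical one-way ANOVA F.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from .exceptions import ConfigError, DegenerateStatisticError

ALPHA = 0.05


@dataclass
class PermFResult:
    f_stat: float
    p_value: float
    n_perm: int
    ss_a: float
    ss_w: float
    group_sizes: tuple[int, ...]
    effect_size: float  # SS_A / (SS_A + SS_W)


def _f_parts(y: np.ndarray, n_a: int) -> tuple[float, float]:
    """(SS_A, SS_W) for two groups: rows [:n_a] vs rows [n_a:]."""
    n, _ = y.shape
    n_b = n - n_a
    grand = y.mean(axis=0)
    mean_a = y[:n_a].mean(axis=0)
    mean_b = y[n_a:].mean(axis=0)
    ss_a = (n_a * np.sum((grand - mean_a) ** 2)
            + n_b * np.sum((grand - mean_b) ** 2)) / (2 - 1)
    ss_w = (np.sum((y[:n_a] - mean_a) ** 2)
            + np.sum((y[n_a:] - mean_b) ** 2)) / (n - 2)
    return float(ss_a), float(ss_w)


def multivariate_perm_f(group_a: np.ndarray, group_b: np.ndarray,
                        n_perm: int = 10_000, seed: int | None = 0,
                        standardize: bool = True) -> PermFResult:
    """Permutation F-test between two groups of feature vectors.

    With ``standardize`` the pooled features are z-scored before the test
    (the statistic is scale-sensitive, so mixed-unit features need a common
    scale); pass False to test in raw feature units.
    """
    a = np.atleast_2d(np.asarray(group_a, dtype=np.float64))
    b = np.atleast_2d(np.asarray(group_b, dtype=np.float64))
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ConfigError("groups must be 2-D with equal column counts")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ConfigError("each group needs at least 2 rows")
    y = np.vstack([a, b])
    if standardize:
        sd = y.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        y = (y - y.mean(axis=0)) / sd
    n_a = a.shape[0]
    n = y.shape[0]
    ss_a, ss_w = _f_parts(y, n_a)
    if ss_w == 0:
        raise DegenerateStatisticError(
            "within-group sum of squares is zero; F undefined")
    f_obs = ss_a / ss_w

    # vectorized label shuffles: SS_A depends only on the group-a row sums,
    # and SS_A + (N-2)/(N-1)... the total SS is permutation-invariant
    rng = np.random.default_rng(seed)
    grand = y.mean(axis=0)
    ss_tot = float(np.sum((y - grand) ** 2))  # unnormalized, invariant
    n_b = n - n_a
    sum_all = y.sum(axis=0)
    perm_sums = np.empty((n_perm, y.shape[1]))
    for s in range(n_perm):
        idx = rng.permutation(n)[:n_a]
        perm_sums[s] = y[idx].sum(axis=0)
    mean_a_p = perm_sums / n_a
    mean_b_p = (sum_all - perm_sums) / n_b
    ss_a_un = (n_a * np.sum((grand - mean_a_p) ** 2, axis=1)
               + n_b * np.sum((grand - mean_b_p) ** 2, axis=1))
    ss_w_un = ss_tot - ss_a_un
    f_perm = (ss_a_un / (2 - 1)) / (ss_w_un / (n - 2))
    p = (1.0 + np.count_nonzero(f_perm >= f_obs)) / (1.0 + n_perm)
    return PermFResult(
        f_stat=float(f_obs), p_value=float(p), n_perm=n_perm,
        ss_a=ss_a, ss_w=ss_w, group_sizes=(n_a, n_b),
        effect_size=float(ss_a / (ss_a + ss_w)))


def bonferroni(p_values) -> np.ndarray:
    """min(1, m * p) for m simultaneous tests."""
    p = np.asarray(p_values, dtype=np.float64)
    if np.any((p <= 0) | (p > 1)):
        raise ConfigError("p-values must lie in (0, 1]")
    return np.minimum(1.0, p * p.size)


def welch_t(sample_a, sample_b) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test; returns (t, df, two-sided p)."""
    a = np.asarray(sample_a, dtype=np.float64)
    b = np.asarray(sample_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ConfigError("need at least 2 observations per sample")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if np.isclose(a.mean(), b.mean()):
            return 0.0, float(a.size + b.size - 2), 1.0
        raise DegenerateStatisticError("zero variance in both samples")
    res = sstats.ttest_ind(a, b, equal_var=False)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    df = (va + vb) ** 2 / (va ** 2 / (a.size - 1) + vb ** 2 / (b.size - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def one_sample_t(sample, mu0: float = 0.0) -> tuple[float, float, float]:
    """One-sample t-test against mu0; returns (t, df, two-sided p)."""
    x = np.asarray(sample, dtype=np.float64)
    if x.size < 2:
        raise ConfigError("need at least 2 observations")
    if x.var(ddof=1) == 0:
        if np.isclose(x.mean(), mu0):
            return 0.0, float(x.size - 1), 1.0
        raise DegenerateStatisticError("zero variance; t undefined")
    res = sstats.ttest_1samp(x, mu0)
    return float(res.statistic), float(x.size - 1), float(res.pvalue)
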