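"""Nonparametric and parametric comparisons used across the pipeline.

The Mann-Whitney location test compares concentration samples across
transport modes (strictly it tests stochastic ordering, not means, but with
similar dispersion it tracks location shifts); an exact permutation p-value
is computed for small samples and a tie-corrected normal approximation
otherwise. Normality is screened with the Kolmogorov-Smirnov distance to a
normal with the sample's own mean and SD; because those parameters are
estimated, the p-value uses the Lilliefors correction rather than the plain
KS null distribution, which would be badly conservative here. Trip-dose
comparisons use Welch's t on replication means.

No multiple-testing correction is applied by default; a Holm option exists.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

#: significance-star thresholds, most stringent first
STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))

EXACT_MAX_N = 12  # combined sample size up to which the permutation null is enumerated


@dataclass(frozen=True)
class TestResult:
    name: str
    statistic: float
    pvalue: float
    n_x: int
    n_y: int | None = None
    stars: str = ""
    note: str = ""


def star_annotate(p: float) -> str:
    """Fig.-style significance stars: * p<=0.05 ... **** p<=0.0001."""
    if not 0 <= p <= 1:
        raise ValueError("p-value must lie in [0, 1]")
    for threshold, stars in STAR_THRESHOLDS:
        if p <= threshold:
            return stars
    return ""


def _u_statistic(ranks_x: np.ndarray, n_x: int) -> float:
    return float(ranks_x.sum() - n_x * (n_x + 1) / 2)


def _exact_mw_pvalue(pooled: np.ndarray, n_x: int, u_obs: float, alternative: str) -> float:
    """Enumerate all C(n, n_x) group assignments of the pooled values.

    Handles ties through midranks; the permutation distribution of U is the
    exact null under exchangeability.
    """
    ranks = sps.rankdata(pooled)
    n = len(pooled)
    mu = n_x * (n - n_x) / 2
    eps = 1e-9
    hits = 0
    for subset in combinations(range(n), n_x):
        u = _u_statistic(ranks[list(subset)], n_x)
        if alternative == "two-sided":
            hits += abs(u - mu) >= abs(u_obs - mu) - eps
        elif alternative == "greater":
            hits += u >= u_obs - eps
        else:  # less
            hits += u <= u_obs + eps
    return hits / comb(n, n_x)


def mann_whitney(
    x, y, mode: str = "auto", alternative: str = "two-sided"
) -> TestResult:
    """Mann-Whitney U test of location between two independent samples.

    ``mode``: 'exact' enumerates the permutation null (feasible for combined
    n <= ~14), 'approximate' uses the tie-corrected normal approximation with
    continuity correction, 'auto' picks exact when combined n <= 12.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    n = x.size + y.size
    if mode == "auto":
        mode = "exact" if n <= EXACT_MAX_N else "approximate"
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u_obs = _u_statistic(ranks[: x.size], x.size)
    if mode == "exact":
        p = _exact_mw_pvalue(pooled, x.size, u_obs, alternative)
        note = "exact permutation null"
    elif mode == "approximate":
        res = sps.mannwhitneyu(x, y, alternative=alternative, method="asymptotic")
        p = float(res.pvalue)
        note = "tie-corrected normal approximation"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    p = min(1.0, float(p))
    return TestResult("mann-whitney", u_obs, p, int(x.size), int(y.size),
                      stars=star_annotate(p), note=note)


def ks_normality(x) -> TestResult:
    """KS distance to a normal with the sample's mean/SD; Lilliefors p-value.

    The reference parameters are estimated from the same sample, so the plain
    KS null distribution does not apply; the Lilliefors correction calibrates
    the p-value for exactly this case.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 observations")
    if np.std(x, ddof=1) == 0:
        raise ValueError("zero-variance sample: normality test undefined")
    stat, p = lilliefors(x, dist="norm", pvalmethod="table")
    p = float(min(1.0, p))
    return TestResult("ks-normality", float(stat), p, int(x.size),
                      stars=star_annotate(p),
                      note="reference normal uses estimated parameters (Lilliefors)")


def two_sample_t(x, y) -> TestResult:
    """Welch two-sample t test (unequal variances), two-sided."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 observations per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        # degenerate replicate sets: identical -> no evidence; distinct -> certain
        if np.isclose(x.mean(), y.mean()):
            t, p = 0.0, 1.0
        else:
            t, p = np.inf if x.mean() > y.mean() else -np.inf, 0.0
    else:
        res = sps.ttest_ind(x, y, equal_var=False)
        t, p = float(res.statistic), float(res.pvalue)
    return TestResult("welch-t", t, p, int(x.size), int(y.size), stars=star_annotate(p))


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjustment (available but off by default in reports)."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj
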