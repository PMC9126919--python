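"""Shared statistical kernel.

One-sample and paired t-tests with effect sizes, Benjamini-Hochberg FDR,
permutation p-values, and Pearson correlation with explicit handling of
degenerate (zero-variance) inputs.  Brain-wide loops call these on hundreds
of parcels, so degenerate inputs produce flagged results instead of raising.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupStat",
    "one_sample_t",
    "paired_t",
    "bh_fdr",
    "perm_pvalue",
    "pearson_r",
]


@dataclass(frozen=True)
class GroupStat:
    """Result of a one-sample or paired t-test against zero.

    ``d`` is Cohen's d (mean / sd); ``ci_low``/``ci_high`` bound the 95%
    confidence interval of the mean.  ``degenerate`` flags zero-variance
    input, for which ``t`` is reported as +/-inf (or 0 for an all-zero
    sample) and ``p`` as 0 (or 1).
    """

    t: float
    df: int
    p: float
    d: float
    ci_low: float
    ci_high: float
    n: int
    degenerate: bool = False


def one_sample_t(x) -> GroupStat:
    """Two-tailed one-sample t-test of ``x`` against zero."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("one_sample_t requires a 1-D sample of size >= 2")
    n = x.size
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        t = 0.0 if mean == 0.0 else float(np.sign(mean)) * float("inf")
        p = 1.0 if mean == 0.0 else 0.0
        return GroupStat(t=t, df=n - 1, p=p, d=float("nan"),
                         ci_low=mean, ci_high=mean, n=n, degenerate=True)
    se = sd / np.sqrt(n)
    t = mean / se
    p = 2.0 * sps.t.sf(abs(t), df=n - 1)
    crit = sps.t.ppf(0.975, df=n - 1)
    return GroupStat(
        t=float(t), df=n - 1, p=float(p), d=mean / sd,
        ci_low=mean - crit * se, ci_high=mean + crit * se, n=n,
    )


def paired_t(x, y) -> GroupStat:
    """Two-tailed paired t-test, reduced to a one-sample test on x - y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"paired_t length mismatch: {x.shape} vs {y.shape}")
    return one_sample_t(x - y)


def bh_fdr(p, q: float = 0.05):
    """Benjamini-Hochberg step-up procedure.

    Returns ``(rejected, q_values)`` where ``q_values`` are BH-adjusted
    p-values (monotone in p).  NaN entries are never rejected and get NaN
    q-values.
    """
    p = np.asarray(p, dtype=float)
    if not 0.0 < q < 1.0:
        raise ValueError(f"q must lie in (0, 1), got {q}")
    finite = ~np.isnan(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    rejected = np.zeros(p.shape, dtype=bool)
    qvals = np.full(p.shape, np.nan)
    if finite.any():
        rej, qv, _, _ = multipletests(p[finite], alpha=q, method="fdr_bh")
        rejected[finite] = rej
        qvals[finite] = qv
    return rejected, qvals


def perm_pvalue(observed: float, null, smoothing: bool = False) -> float:
    """One-tailed permutation p: proportion of null values >= observed.

    With ``smoothing`` the (1 + count) / (1 + n) estimator is used, which
    never returns an exact zero.
    """
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("empty null distribution")
    count = int(np.sum(null >= observed))
    if smoothing:
        return (1 + count) / (1 + null.size)
    return count / null.size


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation; NaN if either input is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("pearson_r requires two equal-length vectors, n >= 2")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])
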