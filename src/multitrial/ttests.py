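"""One-sided two-sample t-tests and the two-significant-trials decision rule.

The per-trial test is the pooled-variance (Student) independent-samples
t-test of H1: mean(experimental) > mean(control).  Both arms are generated
with unit variance and equal n, so the Student and Welch versions coincide
in distribution; Student is the default and matches the classical trial
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "TTestResult",
    "one_sided_t_test",
    "t_tests_from_summaries",
    "count_significant",
    "analytic_fpr_five_trials",
]


@dataclass(frozen=True)
class TTestResult:
    t_statistic: float
    degrees_of_freedom: float
    p_one_sided: float
    mean_difference: float


def _pooled_t(mean_c, var_c, n_c, mean_e, var_e, n_e):
    """Pooled-variance t statistic and df for experimental minus control.

    All arguments may be arrays; variances are the ddof=1 sample variances.
    """
    df = n_c + n_e - 2
    sp2 = ((n_c - 1) * var_c + (n_e - 1) * var_e) / df
    se = np.sqrt(sp2 * (1.0 / n_c + 1.0 / n_e))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean_e - mean_c) / se
    return t, df


def one_sided_t_test(control, experimental) -> TTestResult:
    """Student t-test of H1: experimental mean exceeds control mean.

    p is the upper-tail probability of the central t with n_c + n_e - 2 df.
    Raises ``ValueError`` for arms of fewer than two observations or zero
    pooled variance (degenerate input).
    """
    c = np.asarray(control, dtype=float)
    e = np.asarray(experimental, dtype=float)
    if c.size < 2 or e.size < 2:
        raise ValueError("each arm needs at least 2 observations")
    t, df = _pooled_t(
        c.mean(), c.var(ddof=1), c.size, e.mean(), e.var(ddof=1), e.size
    )
    if not np.isfinite(t):
        raise ValueError("zero pooled variance: degenerate input")
    p = stats.t.sf(t, df)
    return TTestResult(
        t_statistic=float(t),
        degrees_of_freedom=float(df),
        p_one_sided=float(p),
        mean_difference=float(e.mean() - c.mean()),
    )


def t_tests_from_summaries(mean_c, sd_c, n_c, mean_e, sd_e, n_e):
    """Vectorized one-sided p-values from per-trial summary statistics.

    Returns ``(t, df, p_one_sided)`` arrays; used by the evaluation pipeline
    where trials are processed in bulk.
    """
    mean_c, sd_c, mean_e, sd_e = map(np.asarray, (mean_c, sd_c, mean_e, sd_e))
    n_c = np.asarray(n_c, dtype=float)
    n_e = np.asarray(n_e, dtype=float)
    t, df = _pooled_t(mean_c, sd_c**2, n_c, mean_e, sd_e**2, n_e)
    return t, df, stats.t.sf(t, df)


def count_significant(p_values, alpha: float) -> int:
    """Number of p-values strictly below ``alpha``."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return int(np.sum(np.asarray(p_values, dtype=float) < alpha))


def analytic_fpr_five_trials(alpha: float) -> float:
    """Exact null probability that >= 2 of 5 independent tests reject.

    1 - ((1-a)^5 + 5 a (1-a)^4): the chance a truly null treatment clears
    the two-significant-trials rule across five trials at per-trial level
    ``alpha``.
    """
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must be in [0, 1]")
    q = 1.0 - alpha
    return 1.0 - (q**5 + 5.0 * alpha * q**4)
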