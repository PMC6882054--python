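"""Standardized-mean-difference meta-analysis: fixed-effect, DSL and HKSJ CIs.

Per-trial effects are Cohen's d (no small-sample correction by default) with
the large-sample variance

    v = (n_c + n_e) / (n_c * n_e) + d^2 / (2 (n_c + n_e)).

Three 95% confidence intervals for the pooled effect are provided:

* ``fixed_effect_ci`` — inverse-variance weights, normal quantile;
* ``dsl_ci`` — DerSimonian–Laird: method-of-moments between-study variance
  tau^2 = max(0, (Q - (k-1)) / C), re-weighted estimate, normal quantile;
* ``hksj_ci`` — Hartung–Knapp–Sidik–Jonkman: DSL weights, weighted residual
  variance q, t quantile with k-1 df.  The plain (unmodified) HKSJ is used:
  on perfectly homogeneous inputs q = 0 and the interval has zero width.

Decisions downstream use the lower bound of these two-sided intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "StudySummary",
    "MetaResult",
    "summarize_trial",
    "summarize_trial_from_stats",
    "fixed_effect_ci",
    "dsl_ci",
    "hksj_ci",
    "ci_covers",
]

Z_975 = 1.959964  # standard normal 97.5% quantile as conventionally rounded


@dataclass(frozen=True)
class StudySummary:
    """Sufficient statistics of one trial on the SMD scale."""

    effect: float
    variance: float
    n_control: int
    n_experimental: int

    def __post_init__(self) -> None:
        if self.variance <= 0:
            raise ValueError("variance must be > 0")


@dataclass(frozen=True)
class MetaResult:
    method: str  # "fixed" | "DSL" | "HKSJ"
    estimate: float
    ci_lower: float
    ci_upper: float
    tau_squared: float
    q_statistic: float


def _smd(mean_c, sd_c, n_c, mean_e, sd_e, n_e, hedges: bool = False):
    """Cohen's d (optionally Hedges-corrected) and its variance; vectorized."""
    n_c = np.asarray(n_c, dtype=float)
    n_e = np.asarray(n_e, dtype=float)
    df = n_c + n_e - 2
    sp = np.sqrt(((n_c - 1) * np.asarray(sd_c) ** 2
                  + (n_e - 1) * np.asarray(sd_e) ** 2) / df)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (np.asarray(mean_e) - np.asarray(mean_c)) / sp
    if hedges:
        d = d * (1.0 - 3.0 / (4.0 * df - 1.0))
    n_tot = n_c + n_e
    v = n_tot / (n_c * n_e) + d**2 / (2.0 * n_tot)
    return d, v


def summarize_trial(control, experimental, hedges: bool = False) -> StudySummary:
    """SMD summary of one raw two-arm trial."""
    c = np.asarray(control, dtype=float)
    e = np.asarray(experimental, dtype=float)
    if c.size < 2 or e.size < 2:
        raise ValueError("each arm needs at least 2 observations")
    d, v = _smd(c.mean(), c.std(ddof=1), c.size,
                e.mean(), e.std(ddof=1), e.size, hedges=hedges)
    if not np.isfinite(d):
        raise ValueError("zero pooled SD: degenerate input")
    return StudySummary(float(d), float(v), int(c.size), int(e.size))


def summarize_trial_from_stats(
    mean_c: float, sd_c: float, n_c: int,
    mean_e: float, sd_e: float, n_e: int,
    hedges: bool = False,
) -> StudySummary:
    """SMD summary from reported per-arm mean/SD/n (external-summary route)."""
    d, v = _smd(mean_c, sd_c, n_c, mean_e, sd_e, n_e, hedges=hedges)
    if not np.isfinite(d):
        raise ValueError("zero pooled SD: degenerate input")
    return StudySummary(float(d), float(v), int(n_c), int(n_e))


def _as_arrays(studies: Sequence[StudySummary]):
    if len(studies) < 2:
        raise ValueError("meta-analysis needs at least 2 studies")
    y = np.array([s.effect for s in studies], dtype=float)
    v = np.array([s.variance for s in studies], dtype=float)
    return y, v


def _fixed(y: np.ndarray, v: np.ndarray):
    w = 1.0 / v
    est = float(np.sum(w * y) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    q = float(np.sum(w * (y - est) ** 2))
    return est, se, q, w


def fixed_effect_ci(studies: Sequence[StudySummary]) -> MetaResult:
    """Inverse-variance common-effect estimate with a normal 95% CI."""
    y, v = _as_arrays(studies)
    est, se, q, _ = _fixed(y, v)
    return MetaResult("fixed", est, est - Z_975 * se, est + Z_975 * se, 0.0, q)


def _dsl_core(y: np.ndarray, v: np.ndarray):
    est_f, _, q, w = _fixed(y, v)
    k = y.size
    c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (q - (k - 1)) / c)
    w_star = 1.0 / (v + tau2)
    est = float(np.sum(w_star * y) / np.sum(w_star))
    return est, w_star, tau2, q


def dsl_ci(studies: Sequence[StudySummary]) -> MetaResult:
    """DerSimonian–Laird random-effects estimate with a normal 95% CI."""
    y, v = _as_arrays(studies)
    est, w_star, tau2, q = _dsl_core(y, v)
    se = float(np.sum(w_star) ** -0.5)
    return MetaResult("DSL", est, est - Z_975 * se, est + Z_975 * se, tau2, q)


def hksj_ci(studies: Sequence[StudySummary]) -> MetaResult:
    """Hartung–Knapp–Sidik–Jonkman 95% CI (DSL weights, t_{k-1} quantile)."""
    y, v = _as_arrays(studies)
    est, w_star, tau2, q = _dsl_core(y, v)
    k = y.size
    scale2 = float(np.sum(w_star * (y - est) ** 2)
                   / ((k - 1) * np.sum(w_star)))
    hw = float(stats.t.ppf(0.975, k - 1) * np.sqrt(scale2))
    return MetaResult("HKSJ", est, est - hw, est + hw, tau2, q)


def ci_covers(result: MetaResult, true_effect: float) -> bool:
    """Whether the closed interval [ci_lower, ci_upper] contains the truth."""
    return bool(result.ci_lower <= true_effect <= result.ci_upper)
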