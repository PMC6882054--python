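"""Evaluation pipeline: run the grid, apply criteria, aggregate rates.

For every simulated iteration (one candidate treatment, ``k`` trials) each
endorsement criterion issues a binary decision:

* ``sig2_a{alpha}``   — at least two trials individually significant at the
  one-sided level alpha;
* ``ci_fixed/ci_dsl/ci_hksj`` — the lower bound of the 95% meta-analytic CI
  exceeds zero;
* ``jzs_bf{thr}``     — the one-sided JZS Bayes factor of the pooled data
  exceeds ``thr``;
* ``minbf_bf{thr}``   — the minimum Bayes factor bound from the pooled
  one-sided p-value exceeds ``thr``.

Decisions are crossed with the truth label "iteration effect strictly above
the clinically meaningful threshold Delta" to yield TP/FP/TN/FN counts and
TPR/FPR per criterion and Delta.  Truth always refers to the iteration-level
delta (under the random-effects variant, the mean of the trial-effect
distribution), as does confidence-interval coverage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import bayes, meta, ttests
from .simulate import EffectModel, SimulationConfig, TrialDataset, generate_batch

__all__ = [
    "CriteriaSettings",
    "DecisionRecord",
    "GridConfig",
    "apply_criteria",
    "classify",
    "aggregate",
    "run_decision_study",
    "run_coverage_study",
    "coverage_table",
    "run_grid",
]

DEFAULT_DELTAS = (0.0, 0.15, 0.3, 0.45)


@dataclass(frozen=True)
class CriteriaSettings:
    """Which criteria to evaluate and at which evidential thresholds."""

    alphas: tuple[float, ...] = (0.025,)
    bf_thresholds: tuple[float, ...] = (3.0, 10.0, 50.0)
    min_bf_thresholds: tuple[float, ...] = (3.0, 10.0, 50.0)
    prior_scale: float = bayes.DEFAULT_PRIOR_SCALE
    min_significant: int = 2
    include_meta: bool = True
    include_bayes: bool = True

    def criterion_ids(self) -> list[str]:
        ids = [f"sig2_a{a:g}" for a in self.alphas]
        if self.include_meta:
            ids += ["ci_fixed", "ci_dsl", "ci_hksj"]
        if self.include_bayes:
            ids += [f"jzs_bf{b:g}" for b in self.bf_thresholds]
            ids += [f"minbf_bf{b:g}" for b in self.min_bf_thresholds]
        return ids


@dataclass(frozen=True)
class DecisionRecord:
    iteration: int
    truth_delta: float
    null_flag: bool
    decisions: dict[str, bool]


def _trial_summaries(dataset: TrialDataset):
    mc = dataset.control.mean(axis=1)
    sc = dataset.control.std(axis=1, ddof=1)
    me = dataset.experimental.mean(axis=1)
    se = dataset.experimental.std(axis=1, ddof=1)
    n = dataset.n_per_arm
    return mc, sc, me, se, n


def apply_criteria(
    dataset: TrialDataset,
    settings: CriteriaSettings = CriteriaSettings(),
    iteration: int = 0,
) -> DecisionRecord:
    """Evaluate every configured criterion on one iteration's data."""
    if dataset.n_trials < 2:
        raise ValueError("criteria need at least 2 trials")
    try:
        decisions: dict[str, bool] = {}
        mc, sc, me, se, n = _trial_summaries(dataset)
        _, _, p = ttests.t_tests_from_summaries(mc, sc, n, me, se, n)
        for a in settings.alphas:
            decisions[f"sig2_a{a:g}"] = (
                ttests.count_significant(p, a) >= settings.min_significant
            )
        if settings.include_meta:
            d, v = meta._smd(mc, sc, n, me, se, n)
            studies = [
                meta.StudySummary(float(di), float(vi), n, n)
                for di, vi in zip(d, v)
            ]
            for key, fn in (
                ("ci_fixed", meta.fixed_effect_ci),
                ("ci_dsl", meta.dsl_ci),
                ("ci_hksj", meta.hksj_ci),
            ):
                decisions[key] = fn(studies).ci_lower > 0.0
        if settings.include_bayes:
            control, experimental = bayes.pool_trials(dataset)
            t_res = ttests.one_sided_t_test(control, experimental)
            jzs = bayes.jzs_bf_from_t(
                t_res.t_statistic, control.size, experimental.size,
                prior_scale=settings.prior_scale,
            )
            for thr in settings.bf_thresholds:
                decisions[f"jzs_bf{thr:g}"] = bayes.bf_decision(jzs, thr)
            mbf = bayes.min_bf(t_res.p_one_sided)
            for thr in settings.min_bf_thresholds:
                decisions[f"minbf_bf{thr:g}"] = bayes.bf_decision(mbf, thr)
    except (ValueError, ArithmeticError) as err:
        raise RuntimeError(f"iteration {iteration}: {err}") from err
    return DecisionRecord(iteration, dataset.iteration_delta,
                          dataset.is_null, decisions)


def classify(record: DecisionRecord, clinical_threshold: float) -> dict[str, str]:
    """Cross each decision with the truth label at threshold Delta.

    Truth is positive iff the iteration effect strictly exceeds Delta; null
    iterations (flagged) are negative for every Delta >= 0.
    """
    positive_truth = (not record.null_flag) and (
        record.truth_delta > clinical_threshold
    )
    out = {}
    for crit, decided in record.decisions.items():
        if positive_truth:
            out[crit] = "TP" if decided else "FN"
        else:
            out[crit] = "FP" if decided else "TN"
    return out


def aggregate(
    records: Sequence[DecisionRecord],
    clinical_thresholds: Iterable[float] = DEFAULT_DELTAS,
) -> pd.DataFrame:
    """TP/FP/TN/FN counts and TPR/FPR per (criterion, Delta).

    Rates with a zero denominator are emitted as NaN with the corresponding
    ``*_defined`` flag set to False (e.g. TPR in an all-null batch).
    """
    if len(records) == 0:
        raise ValueError("no records to aggregate")
    rows = []
    criteria = list(records[0].decisions)
    for delta in clinical_thresholds:
        counts = {c: {"TP": 0, "FP": 0, "TN": 0, "FN": 0} for c in criteria}
        for rec in records:
            for crit, outcome in classify(rec, delta).items():
                counts[crit][outcome] += 1
        for crit in criteria:
            c = counts[crit]
            n_pos = c["TP"] + c["FN"]
            n_neg = c["FP"] + c["TN"]
            rows.append({
                "criterion": crit,
                "clinical_threshold": delta,
                "tp": c["TP"], "fp": c["FP"], "tn": c["TN"], "fn": c["FN"],
                "tpr": c["TP"] / n_pos if n_pos else np.nan,
                "fpr": c["FP"] / n_neg if n_neg else np.nan,
                "tpr_defined": n_pos > 0,
                "fpr_defined": n_neg > 0,
            })
    return pd.DataFrame(rows)


def run_decision_study(
    config: SimulationConfig,
    settings: CriteriaSettings = CriteriaSettings(),
) -> list[DecisionRecord]:
    """Generate a batch and apply all criteria to every iteration."""
    return [
        apply_criteria(ds, settings, iteration=i)
        for i, ds in enumerate(generate_batch(config))
    ]


# ---------------------------------------------------------------------------
# coverage study (meta-analytic CIs only; no Bayes factors involved)

def run_coverage_study(
    n_per_arm_values: Sequence[int] = (20, 50, 100, 400),
    null_prevalences: Sequence[float] = (0.25, 0.50, 0.75, 0.0),
    n_trials: int = 5,
    n_replications: int = 2000,
    seed: int = 0,
    effect_mean: float = 0.4,
    effect_sd: float = 0.13,
    heterogeneity_sd: float = 0.0,
) -> pd.DataFrame:
    """Coverage of the iteration effect by the three meta-analytic 95% CIs.

    Returns one row per (n_per_arm, prevalence, replication, method) with a
    boolean ``covered``; each (prevalence, n) cell runs ``n_replications``
    fresh iterations.
    """
    rows = []
    for prev in null_prevalences:
        model = EffectModel(prev, effect_mean, effect_sd, heterogeneity_sd)
        for n in n_per_arm_values:
            cfg = SimulationConfig(model, n, n_trials, n_replications, seed)
            for i, ds in enumerate(generate_batch(cfg)):
                mc, sc, me, se, n_arm = _trial_summaries(ds)
                d, v = meta._smd(mc, sc, n_arm, me, se, n_arm)
                studies = [
                    meta.StudySummary(float(di), float(vi), n_arm, n_arm)
                    for di, vi in zip(d, v)
                ]
                for fn in (meta.fixed_effect_ci, meta.dsl_ci, meta.hksj_ci):
                    res = fn(studies)
                    rows.append({
                        "n_per_arm": n,
                        "null_prevalence": prev,
                        "replication": i,
                        "method": res.method,
                        "covered": meta.ci_covers(res, ds.iteration_delta),
                    })
    return pd.DataFrame(rows)


def coverage_table(coverage_rows: pd.DataFrame) -> pd.DataFrame:
    """Coverage proportions, methods x n_per_arm, pooled over prevalences."""
    table = (
        coverage_rows.groupby(["method", "n_per_arm"])["covered"]
        .mean()
        .unstack("n_per_arm")
    )
    return table.reindex(["fixed", "DSL", "HKSJ"])


# ---------------------------------------------------------------------------
# full grid driver

@dataclass(frozen=True)
class GridConfig:
    """The full simulation grid and evaluation settings."""

    null_prevalences: tuple[float, ...] = (0.25, 0.50, 0.75, 0.0)
    n_per_arm_values: tuple[int, ...] = (20, 50, 100, 400)
    n_trials_values: tuple[int, ...] = (5,)
    n_replications: int = 2000
    seed: int = 0
    effect_mean: float = 0.4
    effect_sd: float = 0.13
    heterogeneity_sd: float = 0.0
    clinical_thresholds: tuple[float, ...] = DEFAULT_DELTAS
    settings: CriteriaSettings = field(default_factory=CriteriaSettings)


def run_grid(grid: GridConfig, out_dir: str | Path | None = None):
    """Run every grid cell; return (rates, coverage) tidy frames.

    One rates row per (prevalence, n, k, criterion, Delta); one coverage row
    per (method, n) pooled over prevalences per k.  With ``out_dir`` set,
    writes ``rates.csv``, ``coverage.csv`` and a ``manifest.json`` recording
    the configuration.
    """
    rate_frames = []
    failures = 0
    for k in grid.n_trials_values:
        for prev in grid.null_prevalences:
            model = EffectModel(prev, grid.effect_mean, grid.effect_sd,
                                grid.heterogeneity_sd)
            for n in grid.n_per_arm_values:
                cfg = SimulationConfig(model, n, k, grid.n_replications,
                                       grid.seed)
                records = []
                for i, ds in enumerate(generate_batch(cfg)):
                    try:
                        records.append(apply_criteria(ds, grid.settings, i))
                    except RuntimeError:
                        failures += 1
                agg = aggregate(records, grid.clinical_thresholds)
                agg.insert(0, "n_trials", k)
                agg.insert(0, "n_per_arm", n)
                agg.insert(0, "null_prevalence", prev)
                rate_frames.append(agg)
    rates = pd.concat(rate_frames, ignore_index=True)

    cov_frames = []
    for k in grid.n_trials_values:
        cov = run_coverage_study(
            grid.n_per_arm_values, grid.null_prevalences, k,
            grid.n_replications, grid.seed, grid.effect_mean,
            grid.effect_sd, grid.heterogeneity_sd,
        )
        cov.insert(0, "n_trials", k)
        cov_frames.append(cov)
    coverage = pd.concat(cov_frames, ignore_index=True)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rates.to_csv(out / "rates.csv", index=False)
        coverage.to_csv(out / "coverage.csv", index=False)
        manifest = asdict(grid)
        manifest["excluded_iterations"] = failures
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return rates, coverage
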