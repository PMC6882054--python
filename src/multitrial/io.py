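"""Plain-text interfaces: YAML grid configs, summary tables, batch export."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .meta import StudySummary, summarize_trial_from_stats
from .pipeline import CriteriaSettings, GridConfig
from .simulate import TrialDataset

__all__ = [
    "load_grid_config",
    "read_trial_summaries",
    "export_batch",
]

SUMMARY_COLUMNS = ["mean_c", "sd_c", "n_c", "mean_e", "sd_e", "n_e"]


def load_grid_config(path: str | Path) -> GridConfig:
    """Read a grid configuration from a YAML mapping.

    Recognized keys mirror :class:`~multitrial.pipeline.GridConfig` fields
    (lists for prevalences / per-arm sizes / trial counts, scalars for the
    rest) plus an optional ``criteria`` sub-mapping for
    :class:`~multitrial.pipeline.CriteriaSettings`.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    crit = raw.pop("criteria", None)
    kwargs = {}
    for key in ("null_prevalences", "n_per_arm_values", "n_trials_values",
                "clinical_thresholds"):
        if key in raw:
            kwargs[key] = tuple(raw.pop(key))
    for key in ("n_replications", "seed", "effect_mean", "effect_sd",
                "heterogeneity_sd"):
        if key in raw:
            kwargs[key] = raw.pop(key)
    if raw:
        raise ValueError(f"unknown config keys: {sorted(raw)}")
    if crit is not None:
        for key in ("alphas", "bf_thresholds", "min_bf_thresholds"):
            if key in crit:
                crit[key] = tuple(crit[key])
        kwargs["settings"] = CriteriaSettings(**crit)
    return GridConfig(**kwargs)


def read_trial_summaries(path: str | Path) -> list[StudySummary]:
    """Per-trial summaries from a whitespace- or comma-separated table.

    Expected columns: mean_c, sd_c, n_c, mean_e, sd_e, n_e (one row per
    trial), the standalone route for meta-analysing real trial reports.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    missing = set(SUMMARY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"summary table missing columns: {sorted(missing)}")
    return [
        summarize_trial_from_stats(
            row.mean_c, row.sd_c, int(row.n_c),
            row.mean_e, row.sd_e, int(row.n_e),
        )
        for row in df.itertuples()
    ]


def export_batch(datasets: list[TrialDataset], path: str | Path) -> None:
    """Audit export: one row per trial with latent truth and arm summaries."""
    rows = []
    for i, ds in enumerate(datasets):
        for j in range(ds.n_trials):
            c, e = ds.control[j], ds.experimental[j]
            rows.append({
                "iteration": i,
                "trial": j,
                "delta": ds.iteration_delta,
                "is_null": ds.is_null,
                "trial_delta": ds.trial_deltas[j],
                "mean_c": c.mean(), "sd_c": c.std(ddof=1), "n_c": c.size,
                "mean_e": e.mean(), "sd_e": e.std(ddof=1), "n_e": e.size,
            })
    pd.DataFrame(rows).to_csv(path, index=False)
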