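"""End-to-end orchestration: trials in, Table-1-style summary and ANOVA
report out, fully deterministic from a single seed.

Every trial runs resample → highpass → resultant distance → trim →
(SD, FE, α).  Trial metrics are averaged per participant × condition ×
site to form the repeated-measures cells; two analyses follow the study
design: the movement-implication comparison (five conditions at the
Hand) and the sensor-site comparison (Hip/Shoulder/Hand in the relaxed
stance).  Trial-level metrics are kept in the output so the aggregation
is auditable, and each trial's DFA fit R² is reported as QC (flagged
below 0.9, never dropped).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .io import (
    CONDITIONS,
    SITES,
    KinematicTrial,
    RunConfig,
    write_results_table,
)
from .metrics import DegenerateSeriesError, compute_trial_metrics
from .preprocess import preprocess_trial
from .stats import AnovaResult, StudyTable, lilliefors_test, pairwise_comparisons, rm_anova
from .synthetic import DEFAULT_CONDITION_SPECS, gen_study

__all__ = ["StudyResult", "compute_metrics_table", "aggregate_cells", "summarize", "run_study"]

logger = logging.getLogger("kinevar")

DFA_QC_THRESHOLD = 0.9
METRIC_COLUMNS = ("sd", "fe", "alpha")


@dataclass
class StudyResult:
    """All artefacts of one study run."""

    per_trial: pd.DataFrame
    cells: pd.DataFrame
    summary: pd.DataFrame
    anovas: dict
    normality: pd.DataFrame
    manifest: dict
    failures: list = field(default_factory=list)


def compute_metrics_table(
    trials: Sequence[KinematicTrial], config: RunConfig | None = None
) -> tuple[pd.DataFrame, list[dict]]:
    """Preprocess every trial and compute its metric triple.

    Returns the per-trial table and a list of machine-readable failure
    records for trials that could not be processed (each logged; the
    study continues without them).
    """
    config = config or RunConfig()
    rows, failures = [], []
    for trial in trials:
        try:
            rd = preprocess_trial(trial, config)
            tm = compute_trial_metrics(rd, config.metric_params)
        except (DegenerateSeriesError, ValueError) as err:
            record = {**trial.provenance(), "stage_error": str(err)}
            failures.append(record)
            logger.warning("trial failed: %s", json.dumps(record))
            continue
        rows.append(
            {
                **trial.provenance(),
                "sd": tm.sd,
                "fe": tm.fe,
                "alpha": tm.alpha,
                "dfa_r_squared": tm.dfa_r_squared,
                "dfa_qc_flag": tm.dfa_r_squared < DFA_QC_THRESHOLD,
            }
        )
    return pd.DataFrame(rows), failures


def aggregate_cells(per_trial: pd.DataFrame) -> pd.DataFrame:
    """Participant × condition × site cell means over trials."""
    if per_trial.empty:
        raise ValueError("no trials to aggregate")
    return (
        per_trial.groupby(["participant", "condition", "site"], as_index=False)[
            list(METRIC_COLUMNS)
        ].mean()
    )


def _complete_participants(cells: pd.DataFrame, levels: Sequence[str], column: str) -> list:
    """Participants with a cell for every requested level of ``column``."""
    counts = (
        cells[cells[column].isin(levels)]
        .groupby("participant")[column]
        .nunique()
    )
    complete = sorted(counts[counts == len(levels)].index)
    dropped = sorted(set(cells["participant"]) - set(complete))
    if dropped:
        logger.warning(
            "excluding participants with incomplete coverage of %s: %s", levels, dropped
        )
    return complete


def build_study_table(
    cells: pd.DataFrame,
    metric: str,
    *,
    conditions: Sequence[str] = CONDITIONS,
    site: str = "Hand",
) -> StudyTable:
    """Conditions-at-one-site matrix for one metric (movement comparison)."""
    sub = cells[(cells["site"] == site) & cells["condition"].isin(conditions)]
    participants = _complete_participants(sub, conditions, "condition")
    if len(participants) < 2:
        raise ValueError(f"fewer than 2 complete participants for {metric} at {site}")
    wide = sub[sub["participant"].isin(participants)].pivot(
        index="participant", columns="condition", values=metric
    )[list(conditions)]
    return StudyTable(
        values=wide.to_numpy(),
        metric_name=metric,
        condition_labels=list(conditions),
        participant_ids=list(wide.index),
    )


def build_site_table(
    cells: pd.DataFrame,
    metric: str,
    *,
    condition: str = "ARelax",
    sites: Sequence[str] = ("Hip", "Shoulder", "Hand"),
) -> StudyTable:
    """Sites-within-one-condition matrix for one metric (site comparison)."""
    sub = cells[(cells["condition"] == condition) & cells["site"].isin(sites)]
    participants = _complete_participants(sub, sites, "site")
    if len(participants) < 2:
        raise ValueError(f"fewer than 2 complete participants for {metric} sites")
    wide = sub[sub["participant"].isin(participants)].pivot(
        index="participant", columns="site", values=metric
    )[list(sites)]
    return StudyTable(
        values=wide.to_numpy(),
        metric_name=metric,
        condition_labels=list(sites),
        participant_ids=list(wide.index),
    )


def summarize(cells: pd.DataFrame) -> pd.DataFrame:
    """Tidy mean ± SD across participants per (condition, site, metric)."""
    long = cells.melt(
        id_vars=["participant", "condition", "site"],
        value_vars=list(METRIC_COLUMNS),
        var_name="metric",
    )
    out = (
        long.groupby(["condition", "site", "metric"], as_index=False)["value"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0,
             n_participants="count")
    )
    order = {c: i for i, c in enumerate(CONDITIONS)}
    site_order = {s: i for i, s in enumerate(SITES)}
    out = out.sort_values(
        by=["condition", "site", "metric"],
        key=lambda col: col.map(order).fillna(col.map(site_order)).fillna(col.astype("object").map(str)),
        kind="stable",
    ).reset_index(drop=True)
    return out


def _anova_block(table: StudyTable, correction: str) -> dict:
    return {
        "anova": rm_anova(table),
        "pairwise": pairwise_comparisons(table, correction=correction),
        "table": table,
    }


def run_study(
    config: RunConfig | None = None,
    trials: Sequence[KinematicTrial] | None = None,
    *,
    simulate: bool = False,
    n_participants: int = 21,
    trials_per_condition: int = 3,
    condition_specs: Mapping | None = None,
    include_arelax_sites: bool = True,
    pairwise_correction: str = "bonferroni",
    outdir: str | Path | None = None,
) -> StudyResult:
    """Run the full analysis and (optionally) write its artefacts.

    Either pass ``trials`` explicitly or set ``simulate=True`` to generate
    a study with :func:`kinevar.synthetic.gen_study` from ``config.seed``.
    Writes, when ``outdir`` is given: per-trial metrics CSV, summary CSV,
    ANOVA report CSV, pairwise CSV and a JSON run manifest.
    """
    config = config or RunConfig()
    sim_spec = None
    if trials is None:
        if not simulate:
            raise ValueError("either supply trials or set simulate=True")
        sim_spec = {
            "n_participants": n_participants,
            "trials_per_condition": trials_per_condition,
            "include_arelax_sites": include_arelax_sites,
            "seed": config.seed,
        }
        trials = gen_study(
            n_participants=n_participants,
            trials_per_condition=trials_per_condition,
            condition_specs=condition_specs or DEFAULT_CONDITION_SPECS,
            seed=config.seed,
            include_arelax_sites=include_arelax_sites,
        )
    trials = list(trials)
    if not trials:
        raise ValueError("no trials to analyse")

    per_trial, failures = compute_metrics_table(trials, config)
    if per_trial.empty:
        raise ValueError("all trials failed preprocessing")
    cells = aggregate_cells(per_trial)

    present_conditions = [c for c in CONDITIONS if c in set(cells["condition"])]
    lost = set(CONDITIONS) - set(present_conditions) - {
        c for c in CONDITIONS if c not in {t.condition for t in trials}
    }
    if lost:
        raise ValueError(f"conditions lost all participants: {sorted(lost)}")

    anovas: dict = {}
    normality_rows = []
    for metric in METRIC_COLUMNS:
        block: dict = {}
        if len(present_conditions) >= 2:
            table = build_study_table(cells, metric, conditions=present_conditions)
            block["conditions"] = _anova_block(table, pairwise_correction)
            for j, cond in enumerate(table.condition_labels):
                res = lilliefors_test(table.values[:, j]) if table.n_subjects >= 4 else None
                normality_rows.append(
                    {
                        "metric": metric,
                        "level": cond,
                        "statistic": res.statistic if res else np.nan,
                        "p": res.p if res else np.nan,
                    }
                )
        sites_present = set(cells.loc[cells["condition"] == "ARelax", "site"])
        if {"Hip", "Shoulder", "Hand"} <= sites_present:
            block["sites"] = _anova_block(
                build_site_table(cells, metric), pairwise_correction
            )
        anovas[metric] = block

    summary = summarize(cells)
    manifest = {
        "software": {"name": "kinevar", "version": __version__},
        "config": config.to_dict(),
        "seed": config.seed,
        "simulation": sim_spec,
        "counts": {
            "trials_in": len(trials),
            "trials_analysed": int(len(per_trial)),
            "trials_failed": len(failures),
            "participants": int(cells["participant"].nunique()),
        },
    }
    result = StudyResult(
        per_trial=per_trial,
        cells=cells,
        summary=summary,
        anovas=anovas,
        normality=pd.DataFrame(normality_rows),
        manifest=manifest,
        failures=failures,
    )
    if outdir is not None:
        write_outputs(result, outdir)
    return result


def anova_report_frame(anovas: dict) -> pd.DataFrame:
    rows = []
    for metric, block in anovas.items():
        for comparison, sub in block.items():
            res: AnovaResult = sub["anova"]
            rows.append(
                {
                    "metric": metric,
                    "comparison": comparison,
                    "F": res.F,
                    "df_effect": res.df_effect,
                    "df_error": res.df_error,
                    "p": res.p,
                    "partial_eta_squared": res.pes,
                }
            )
    return pd.DataFrame(rows)


def write_outputs(result: StudyResult, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "metrics": outdir / "trial_metrics.csv",
        "summary": outdir / "summary.csv",
        "anova": outdir / "anova.csv",
        "pairwise": outdir / "pairwise.csv",
        "normality": outdir / "normality.csv",
        "manifest": outdir / "manifest.json",
    }
    result.per_trial.to_csv(paths["metrics"], index=False, float_format="%.12g")
    write_results_table(result.summary, paths["summary"])
    anova_report_frame(result.anovas).to_csv(paths["anova"], index=False, float_format="%.12g")
    pw_frames = []
    for metric, block in result.anovas.items():
        for comparison, sub in block.items():
            pw = sub["pairwise"].copy()
            pw.insert(0, "comparison", comparison)
            pw.insert(0, "metric", metric)
            pw_frames.append(pw)
    if pw_frames:
        pd.concat(pw_frames, ignore_index=True).to_csv(
            paths["pairwise"], index=False, float_format="%.12g"
        )
    result.normality.to_csv(paths["normality"], index=False, float_format="%.12g")
    paths["manifest"].write_text(json.dumps(result.manifest, indent=2, sort_keys=True))
    return paths
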