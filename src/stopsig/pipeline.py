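"""End-to-end study pipeline: simulate (or ingest) -> behavioral scoring ->
ERP measurement -> group statistics -> summary report.

Every stage writes its artifact under the output directory, and the report
carries the config hash and master seed so a run can be reproduced
exactly.  All randomness flows from the one master seed, split per stage
and per subject; no global RNG state is touched.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as beh
from . import erp as erp_mod
from . import stats as stats_mod
from .config import StudyConfig, config_to_dict, save_config
from .simulate import simulate_study

log = logging.getLogger("stopsig")

__all__ = ["run_pipeline", "behavioral_group_tests", "erp_group_anovas"]


def config_hash(cfg: StudyConfig) -> str:
    blob = json.dumps(config_to_dict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def behavioral_group_tests(metrics: pd.DataFrame,
                           equal_var: bool = True) -> pd.DataFrame:
    """Independent t-tests between groups for every behavioral metric,
    per condition (the layout of a behavioral results table)."""
    rows = []
    groups = sorted(metrics["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"expected two groups, found {groups}")
    value_cols = ["ssrt_right_ms", "ssrt_left_ms", "che_stopr", "che_stopl",
                  "om_go", "rt_go_ms"]
    for condition, sub in metrics.groupby("condition"):
        for col in value_cols:
            a = sub.loc[sub["group"] == groups[0], col].dropna()
            b = sub.loc[sub["group"] == groups[1], col].dropna()
            if len(a) < 2 or len(b) < 2:
                continue
            r = stats_mod.independent_t_test(a, b, equal_var=equal_var)
            rows.append(dict(condition=condition, metric=col,
                             **{f"mean_{groups[0]}": r.mean_a,
                                f"sd_{groups[0]}": r.sd_a,
                                f"mean_{groups[1]}": r.mean_b,
                                f"sd_{groups[1]}": r.sd_b},
                             t=r.t, df=r.df, p=r.p))
    return pd.DataFrame(rows)


def erp_group_anovas(measures: pd.DataFrame, dv: str = "amplitude_uv",
                     trial_factor: str = "condition") -> pd.DataFrame:
    """One mixed RM-ANOVA per ERP component: between = group, within =
    (trial factor, electrode)."""
    frames = []
    for comp, sub in measures.groupby("component"):
        cell = (sub.groupby(["subject", "group", trial_factor, "electrode"],
                            observed=True)[dv].mean().reset_index())
        try:
            res = stats_mod.mixed_rm_anova(cell, dv, "subject", "group",
                                           [trial_factor, "electrode"])
        except (ValueError, stats_mod.MissingCellError) as exc:
            log.warning("ANOVA skipped for %s: %s", comp, exc)
            continue
        tab = stats_mod.anova_table(res)
        tab.insert(0, "component", comp)
        tab.insert(1, "dv", dv)
        frames.append(tab)
    return (pd.concat(frames, ignore_index=True)
            if frames else pd.DataFrame())


def run_pipeline(cfg: StudyConfig, out_dir) -> dict:
    """Run the full study at the configured scale and write all artifacts.

    Returns the report dict (also written to ``report.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cfg)
    save_config(cfg, out / "config.yaml")
    stage = "simulate"
    try:
        sessions = simulate_study(
            n_per_group=cfg.n_per_group, group_effects=cfg.group_effects(),
            seed=cfg.seed, design=cfg.design, with_eeg=cfg.with_eeg)
        log.info("simulated %d sessions", len(sessions))

        stage = "behavior"
        metrics = beh.study_metrics_table(sessions)
        metrics["config_hash"] = chash
        metrics["seed"] = cfg.seed
        metrics.to_csv(out / "behavior_metrics.csv", index=False)
        behav_tests = behavioral_group_tests(
            metrics, equal_var=cfg.stats.equal_var_ttest)
        behav_tests.to_csv(out / "behavior_tests.csv", index=False)

        report: dict = {
            "config_hash": chash, "seed": cfg.seed,
            "n_per_group": cfg.n_per_group,
            "n_sessions": len(sessions),
            "behavior": behav_tests.to_dict(orient="records"),
        }

        if cfg.with_eeg:
            stage = "erp"
            ea = cfg.erp_analysis
            measures = erp_mod.study_measures_table(
                sessions, window_ms=ea.epoch_window_ms,
                baseline_ms=ea.baseline_ms,
                filter_band=(ea.filter_low_hz, ea.filter_high_hz),
                reject_uv=ea.reject_threshold_uv,
                clean_blinks=ea.clean_blinks)
            measures["config_hash"] = chash
            measures["seed"] = cfg.seed
            measures.to_csv(out / "erp_measures.csv", index=False)

            stage = "stats"
            anovas = erp_group_anovas(measures,
                                      trial_factor=cfg.stats.trial_factor)
            anovas.to_csv(out / "erp_anovas.csv", index=False)
            report["erp_anovas"] = anovas.to_dict(orient="records")

        (out / "report.json").write_text(json.dumps(report, indent=2,
                                                    default=float))
        return report
    except Exception as exc:
        raise RuntimeError(
            f"pipeline failed at stage {stage!r} (config {chash}, "
            f"seed {cfg.seed}): {exc}") from exc
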