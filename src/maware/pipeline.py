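"""End-to-end orchestration: simulate, analyze, recover.

`analyze` reproduces the study's quantitative chain on a dataset
directory: kinematic summaries per trial, psychometric fits per
participant x effector x task, a threshold/slope group table, and the
robust/Bayesian statistics comparing effectors. `recover` runs a
simulate -> analyze -> compare loop against the ground-truth sidecar.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import kinematics as kin
from . import psychometrics as psy
from . import stats as rstats
from .cohort import generate_study, read_trajectories
from .config import RunConfig
from .task_design import Effector, TaskGeometry, target_positions

log = logging.getLogger("maware")


def simulate(config: RunConfig, out_dir: str | Path) -> Path:
    """Generate a synthetic study dataset and a run manifest."""
    out = Path(out_dir)
    data = generate_study(
        calibration=config.calibration(),
        geometry=config.geometry,
        seed=config.seed,
        include_trajectories=True,
        out_dir=out,
    )
    manifest = {
        "seed": config.seed,
        "n_participants": config.n_participants,
        "n_trials": int(len(data.trials)),
        "n_blind_trials": int(len(data.blind)),
        "geometry": asdict(config.geometry),
        "deviation_onset_mm": config.geometry.deviation_onset_mm,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    log.info("simulated %d trials for %d participants -> %s",
             len(data.trials), config.n_participants, out)
    return out


def analyze_kinematics(
    dataset_dir: str | Path, config: RunConfig, geometry: TaskGeometry
) -> pd.DataFrame | None:
    """Per-trial kinematic summaries from trajectories.jsonl (or None
    with a warning when the file is absent)."""
    path = Path(dataset_dir) / "trajectories.jsonl"
    if not path.exists():
        log.warning("no trajectories.jsonl in %s: kinematic stages skipped", path.parent)
        return None
    rows = []
    n_bad = 0
    for pid, traj in read_trajectories(path):
        try:
            summary = kin.summarize_trial(
                traj,
                traj.trial,
                geometry,
                smooth=config.analysis.smooth,
                end_rule=config.analysis.end_rule,
            )
        except kin.TrajectoryError as err:
            n_bad += 1
            log.debug("trial skipped (%s %s): %s", pid, traj.trial.trial_index, err)
            continue
        rows.append(
            {
                "participant": pid,
                "effector": traj.trial.effector.value,
                "task": traj.trial.task.value,
                "trial_index": traj.trial.trial_index,
                "deviation_deg": traj.trial.deviation_deg,
                "mode": traj.trial.mode.value,
                "onset_time_s": summary.onset_time_s,
                "reaching_time_s": summary.reaching_time_s,
                "endpoint_x_mm": summary.endpoint_mm[0],
                "endpoint_y_mm": summary.endpoint_mm[1],
                "endpoint_angle_error_deg": summary.endpoint_angle_error_deg,
                "mp_compensation_deg": summary.mp_compensation_deg,
                "reach_error_mm": summary.reach_error_mm,
                "completed": summary.completed,
                "restarted": summary.restarted,
            }
        )
    if n_bad:
        log.info("skipped %d malformed/short trajectories", n_bad)
    return pd.DataFrame(rows)


def blind_reach_summary(blind: pd.DataFrame, geometry: TaskGeometry) -> pd.DataFrame:
    """Per-participant blind-reaching accuracy (mean error) and precision
    (SD of errors), mm, per effector."""
    targets = target_positions(geometry)
    rows = []
    for (pid, eff), sub in blind.groupby(["participant", "effector"]):
        errs = []
        for side, side_sub in sub.groupby("target_side"):
            pts = side_sub[["endpoint_x_mm", "endpoint_y_mm"]].to_numpy()
            from .task_design import TargetSide

            tgt = targets[TargetSide(side)]
            errs.append(np.hypot(*(pts - tgt).T))
        errs = np.concatenate(errs)
        rows.append(
            {
                "participant": pid,
                "effector": eff,
                "error_mm": float(errs.mean()),
                "variability_mm": float(errs.std(ddof=1)),
                "n_trials": len(errs),
            }
        )
    return pd.DataFrame(rows)


def _between_effector_stats(
    fits: pd.DataFrame, blind_summary: pd.DataFrame | None, config: RunConfig
) -> dict:
    """The study's headline statistics on the analyzed cohort."""
    opts = config.analysis
    report: dict = {"seed": config.seed, "n_boot": opts.n_boot}
    ok = fits[fits["converged"] & ~fits["degenerate"] & ~fits["boundary"]]
    # task-averaged threshold and slope per participant and effector
    avg = (
        ok.groupby(["participant", "effector"])[["mu", "slope"]]
        .mean()
        .reset_index()
        .pivot(index="participant", columns="effector")
    )
    complete = avg.dropna()
    for qty in ("mu", "slope"):
        pair = complete[qty]
        if {"hand", "full_body"} <= set(pair.columns) and len(pair) >= 10:
            corr = rstats.skipped_pearson(
                pair["hand"].to_numpy(),
                pair["full_body"].to_numpy(),
                n_boot=opts.n_boot,
                seed=config.seed,
            )
            report[f"{qty}_between_effector"] = {
                "r": corr.r_,
                "t": corr.t_,
                "df": corr.df_,
                "p": corr.p_,
                "n_outliers": int(corr.outlier_mask_.sum()),
                "ci95": list(corr.ci95_),
            }
    if blind_summary is not None and len(blind_summary):
        wide = blind_summary.pivot(index="participant", columns="effector")
        err = wide["error_mm"].dropna()
        if {"hand", "full_body"} <= set(err.columns):
            t, df, p, p_bonf = rstats.paired_t(
                err["hand"].to_numpy(), err["full_body"].to_numpy(), family_size=2
            )
            report["blind_error_hand_vs_body"] = {
                "t": t, "df": df, "p": p, "p_bonferroni": p_bonf,
                "mean_hand_mm": float(err["hand"].mean()),
                "mean_full_body_mm": float(err["full_body"].mean()),
            }
            var = wide["variability_mm"].dropna()
            t, df, p, p_bonf = rstats.paired_t(
                var["hand"].to_numpy(), var["full_body"].to_numpy(), family_size=2
            )
            report["blind_variability_hand_vs_body"] = {
                "t": t, "df": df, "p": p, "p_bonferroni": p_bonf,
            }
            # overall threshold vs overall blind error across participants
            overall_mu = complete["mu"].mean(axis=1)
            joined = pd.concat([overall_mu.rename("mu"), err.mean(axis=1).rename("err")],
                               axis=1).dropna()
            if len(joined) >= 10:
                corr = rstats.skipped_pearson(
                    joined["err"].to_numpy(), joined["mu"].to_numpy(),
                    n_boot=opts.n_boot, seed=config.seed,
                )
                report["threshold_vs_blind_error"] = {
                    "r": corr.r_, "t": corr.t_, "df": corr.df_, "p": corr.p_,
                }
    return report


def analyze(dataset_dir: str | Path, config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Run the full analysis chain on a dataset directory.

    Returns a dict of DataFrames / dicts and, when `out_dir` is given,
    writes kinematics.csv, fits.csv, table1.csv, tidy_trials.csv,
    blind_summary.csv, stats_report.json and (when truth.json exists)
    recovery_report.json.
    """
    dataset_dir = Path(dataset_dir)
    trials = pd.read_csv(dataset_dir / "trials.csv")
    geometry = config.geometry
    geom_path = dataset_dir / "geometry.json"
    if geom_path.exists():
        with open(geom_path) as fh:
            geometry = TaskGeometry(**json.load(fh))

    kin_table = analyze_kinematics(dataset_dir, config, geometry)

    fits = psy.fit_cohort(
        trials,
        include_control=config.analysis.include_control_level,
        fit_lapse_high=config.analysis.fit_lapse_high,
        lapse_high_max=config.analysis.lapse_high_max,
    )
    props = psy.ma_proportions(trials, by_mode=False)
    exclusions = psy.exclusion_check(props)
    dropped = exclusions.loc[~exclusions["keep"], "participant"]
    for pid in dropped:
        log.info("participant %s excluded: yes rate < 0.5 at every level", pid)
    fits = fits[~fits["participant"].isin(set(dropped))]
    table1 = psy.summarize_table1(fits)

    blind_path = dataset_dir / "blind_reaching.csv"
    blind_summary = None
    if blind_path.exists():
        blind_summary = blind_reach_summary(pd.read_csv(blind_path), geometry)

    # JZS Bayes factor: control-trial yes rates, hand vs full body
    ctrl = psy.control_yes_rates(trials).pivot(
        index="participant", columns="effector", values="proportion_yes"
    ).dropna()
    stats_report = _between_effector_stats(fits, blind_summary, config)
    if {"hand", "full_body"} <= set(ctrl.columns) and len(ctrl) >= 3:
        bf = rstats.jzs_paired_bf(
            ctrl["hand"].to_numpy(), ctrl["full_body"].to_numpy(),
            prior_scale=config.analysis.bf_prior_scale,
        )
        stats_report["control_yes_hand_vs_body_bf"] = {
            "bf10": bf.bf10, "bf01": bf.bf01, "t": bf.t, "n": bf.n,
            "prior_scale": bf.prior_scale,
        }
    tidy = psy.export_tidy(trials, kin_table)

    results = {
        "trials": trials,
        "kinematics": kin_table,
        "fits": fits,
        "table1": table1,
        "exclusions": exclusions,
        "blind_summary": blind_summary,
        "stats_report": stats_report,
        "tidy": tidy,
    }
    truth_path = dataset_dir / "truth.json"
    if truth_path.exists():
        with open(truth_path) as fh:
            truth = json.load(fh)
        results["recovery_report"] = recovery_report(fits, truth)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if kin_table is not None:
            kin_table.to_csv(out / "kinematics.csv", index=False)
        fits.to_csv(out / "fits.csv", index=False)
        table1.to_csv(out / "table1.csv", index=False)
        tidy.to_csv(out / "tidy_trials.csv", index=False)
        exclusions.to_csv(out / "exclusions.csv", index=False)
        if blind_summary is not None:
            blind_summary.to_csv(out / "blind_summary.csv", index=False)
        with open(out / "stats_report.json", "w") as fh:
            json.dump(stats_report, fh, indent=1)
        if "recovery_report" in results:
            with open(out / "recovery_report.json", "w") as fh:
                json.dump(results["recovery_report"], fh, indent=1)
    return results


def recovery_report(fits: pd.DataFrame, truth: dict) -> dict:
    """Compare fitted psychometric parameters against the generating ones.

    Reports bias, RMSE and Pearson correlation of fitted vs true mu and
    sigma over all participant x condition cells, plus the median
    absolute threshold error.
    """
    rows = []
    for _, row in fits.iterrows():
        if not row["converged"] or row["degenerate"]:
            continue
        p_truth = truth["participants"].get(row["participant"])
        if p_truth is None:
            continue
        obs = p_truth["observers"][f"{row['effector']}:{row['task']}"]
        rows.append(
            {
                "mu_true": obs["mu"],
                "mu_fit": row["mu"],
                "sigma_true": obs["sigma"],
                "sigma_fit": row["sigma"],
            }
        )
    if not rows:
        return {"n_cells": 0}
    df = pd.DataFrame(rows)
    out: dict = {"n_cells": int(len(df))}
    for name in ("mu", "sigma"):
        err = df[f"{name}_fit"] - df[f"{name}_true"]
        out[name] = {
            "bias": float(err.mean()),
            "rmse": float(np.sqrt((err**2).mean())),
            "median_abs_error": float(err.abs().median()),
            "correlation": float(
                np.corrcoef(df[f"{name}_true"], df[f"{name}_fit"])[0, 1]
            ),
        }
    return out


def recover(config: RunConfig, work_dir: str | Path) -> dict:
    """Simulate -> analyze -> compare parameter recovery, in one call."""
    work = Path(work_dir)
    simulate(config, work / "dataset")
    results = analyze(work / "dataset", config, out_dir=work / "analysis")
    report = results.get("recovery_report", {})
    with open(work / "recovery_report.json", "w") as fh:
        json.dump(report, fh, indent=1)
    return report
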