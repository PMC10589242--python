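"""End-to-end orchestration: simulate -> kinematics -> pairing -> psychometrics -> stats.

A run simulates ``n_participants`` full sessions (baseline blocks, practice, grasping
block — twice for the two Experiment-2 sessions), extracts the per-trial kinematic
measures, classifies trials by the previous mass distribution, fits the psychometric
functions, applies the false-alarm exclusion, and produces the group statistics in
the structure of the study's result tables.  Identical config + seed give
byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import design as dsg
from . import pairing, psychometrics, stats
from .config import RunConfig
from .kinematics import analyze_trial
from .synthdata import ExperimentDataset, simulate_experiment

__all__ = ["run_pipeline", "build_exp1_session", "build_exp2_session", "analyze_kinematics"]

log = logging.getLogger("graspsupp")


def build_exp1_session(seed: int, session: str = "none") -> dsg.SequenceDesign:
    """Baseline, practice, grasping (with lead-in), baseline — consecutive trial ids."""
    rng = np.random.default_rng(seed)
    s = [int(v) for v in rng.integers(2**31 - 1, size=4)]
    parts = [
        dsg.build_baseline_block(seed=s[0], block="baseline_pre", session=session, start_id=1),
        dsg.build_practice_block(seed=s[1], session=session, start_id=46),
        dsg.build_exp1_sequence(seed=s[2], lead_in=True, session=session, start_id=55),
        dsg.build_baseline_block(seed=s[3], block="baseline_post", session=session, start_id=236),
    ]
    trials = [t for p in parts for t in p.trials]
    return dsg.SequenceDesign(trials=trials, experiment="exp1", seed=seed)


def build_exp2_session(seed: int, first_constant_md: str, session: str) -> dsg.SequenceDesign:
    rng = np.random.default_rng(seed)
    s = [int(v) for v in rng.integers(2**31 - 1, size=4)]
    parts = [
        dsg.build_baseline_block(seed=s[0], block="baseline_pre", session=session, start_id=1),
        dsg.build_practice_block(seed=s[1], session=session, start_id=46),
        dsg.build_exp2_sequence(
            seed=s[2], first_constant_md=first_constant_md, session=session, start_id=55
        ),
        dsg.build_baseline_block(seed=s[3], block="baseline_post", session=session, start_id=271),
    ]
    trials = [t for p in parts for t in p.trials]
    return dsg.SequenceDesign(trials=trials, experiment="exp2", seed=seed)


def analyze_kinematics(dataset: ExperimentDataset, config: RunConfig) -> pd.DataFrame:
    """Per-trial kinematic measures merged onto the trial table."""
    filt = config.filter.to_spec()
    rows = []
    for trial_id, series in sorted(dataset.series.items()):
        m = analyze_trial(
            series,
            filt=filt,
            speed_threshold=config.speed_threshold_cm_s,
            separation_window_ms=config.separation_window_ms,
            roll_window_ms=config.roll_window_ms,
        )
        if not m.valid:
            log.warning("trial %d: invalid kinematics (%s)", trial_id, m.reason)
        rows.append(
            {
                "trial_id": trial_id,
                "contact_s": m.contact_time,
                "lift_s": m.lift_time,
                "separation_cm": m.digit_separation,
                "loading_ms": m.loading_time,
                "roll_deg": m.max_roll,
                "valid": m.valid,
                "reason": m.reason,
            }
        )
    measures = pd.DataFrame(rows)
    return dataset.trial_table.merge(measures, on="trial_id", how="left")


def _fit_thresholds(tables: dict, conditions, criterion: str) -> dict:
    out = {}
    for cond in conditions:
        fit = psychometrics.fit_psychometric(tables[cond])
        out[cond] = psychometrics.threshold(fit, criterion)
    return out


def _analyze_participant_exp1(dataset: ExperimentDataset, config: RunConfig) -> dict:
    df = analyze_kinematics(dataset, config)
    grasp = df[df["block"] == "grasping"].sort_values("trial_id")
    labels = pairing.classify_pairs(grasp["trial_id"], grasp["md"], grasp["lead_in"])
    config_of = {lab.trial_id: lab.configuration for lab in labels}

    valid = grasp["valid"].eq(True)
    sep = dict(zip(grasp["trial_id"], grasp["separation_cm"].where(valid)))
    load = dict(zip(grasp["trial_id"], grasp["loading_ms"].where(valid)))
    roll = dict(zip(grasp["trial_id"], grasp["roll_deg"].where(valid)))

    idx = pairing.separation_index(sep, labels)
    load_cells = pairing.aggregate_exp1(load, labels)
    roll_cells = pairing.aggregate_exp1(roll, labels)

    # Detection analysis: rest blocks plus classified grasping trials, with the
    # condition derived from the design sequence (not the simulator's bookkeeping).
    resp = df[df["block"].isin(["baseline_pre", "baseline_post", "grasping"])].copy()
    resp = resp[resp["block"] != "grasping"].assign(cond=lambda d: d["block"]).pipe(
        lambda base: pd.concat(
            [
                base,
                df[df["trial_id"].isin(config_of)].assign(
                    cond=lambda d: d["trial_id"].map(config_of)
                ),
            ]
        )
    )
    tables = psychometrics.tabulate_responses(resp, condition_col="cond")
    fa = psychometrics.false_alarm_rate(tables["baseline"])
    keep = psychometrics.apply_exclusion(fa, config.false_alarm_cutoff)
    thr = _fit_thresholds(
        tables, ("baseline", "MD_same", "MD_different"), config.psychometric.threshold_criterion
    )
    return {
        "false_alarm_rate": fa,
        "keep": keep,
        "index_same": idx.index_same,
        "index_different": idx.index_different,
        "loading_same": load_cells["MD_same"][0],
        "loading_different": load_cells["MD_different"][0],
        "roll_same": roll_cells["MD_same"][0],
        "roll_different": roll_cells["MD_different"][0],
        "thr_baseline": thr["baseline"],
        "thr_same": thr["MD_same"],
        "thr_different": thr["MD_different"],
        "supp_same": thr["MD_same"] - thr["baseline"],
        "supp_different": thr["MD_different"] - thr["baseline"],
    }


def _analyze_participant_exp2(datasets: dict, config: RunConfig) -> dict:
    """``datasets`` maps session ('implicit'/'explicit') to its simulated dataset."""
    frames = []
    supp = {}
    for session, dataset in datasets.items():
        df = analyze_kinematics(dataset, config)
        grasp = df[df["block"] == "grasping"].sort_values("trial_id")
        valid = grasp["valid"].eq(True)
        frames.append(
            pd.DataFrame(
                {
                    "trial_id": grasp["trial_id"],
                    "md": grasp["md"],
                    "part": grasp["part"],
                    "session": session,
                    "separation": grasp["separation_cm"].where(valid),
                    "loading": grasp["loading_ms"].where(valid),
                    "roll": grasp["roll_deg"].where(valid),
                }
            )
        )
        resp = df[df["block"].isin(["baseline_pre", "baseline_post"])].assign(
            cond=lambda d: d["block"]
        )
        resp = pd.concat(
            [resp, df[df["block"] == "grasping"].assign(cond=lambda d: d["part"])]
        )
        tables = psychometrics.tabulate_responses(resp, condition_col="cond")
        fa = psychometrics.false_alarm_rate(tables["baseline"])
        thr = _fit_thresholds(
            tables, ("baseline", "constant", "mixed"), config.psychometric.threshold_criterion
        )
        supp[session] = {
            "false_alarm_rate": fa,
            "keep": psychometrics.apply_exclusion(fa, config.false_alarm_cutoff),
            "constant": thr["constant"] - thr["baseline"],
            "mixed": thr["mixed"] - thr["baseline"],
        }
    trials = pd.concat(frames, ignore_index=True)
    out = {
        "false_alarm_rate": max(s["false_alarm_rate"] for s in supp.values()),
        "keep": all(s["keep"] for s in supp.values()),
    }
    for var in ("separation", "loading", "roll"):
        cells = pairing.aggregate_exp2(trials, var)
        for (part, session), val in cells.items():
            out[f"{var}_{part}_{session}"] = val
    for session, s in supp.items():
        out[f"suppression_constant_{session}"] = s["constant"]
        out[f"suppression_mixed_{session}"] = s["mixed"]
    return out


def _t_dict(res: stats.TTestResult) -> dict:
    return dataclasses.asdict(res)


def _anova_dict(res: stats.AnovaResult) -> dict:
    return {
        "factor_a": res.factor_a,
        "factor_b": res.factor_b,
        "n": res.n,
        "effects": {k: dataclasses.asdict(v) for k, v in res.effects.items()},
    }


def _group_stats_exp1(part_df: pd.DataFrame) -> dict:
    tests = {
        "index_same_vs_0": _t_dict(stats.one_sample_t(part_df["index_same"])),
        "index_different_vs_0": _t_dict(stats.one_sample_t(part_df["index_different"])),
        "index_same_vs_different": _t_dict(
            stats.paired_t(part_df["index_same"], part_df["index_different"])
        ),
        "loading_same_vs_different": _t_dict(
            stats.paired_t(part_df["loading_same"], part_df["loading_different"])
        ),
        "roll_same_vs_different": _t_dict(
            stats.paired_t(part_df["roll_same"], part_df["roll_different"])
        ),
        "suppression_same_vs_0": _t_dict(stats.one_sample_t(part_df["supp_same"])),
        "suppression_different_vs_0": _t_dict(stats.one_sample_t(part_df["supp_different"])),
        "suppression_same_vs_different": _t_dict(
            stats.paired_t(part_df["supp_same"], part_df["supp_different"])
        ),
    }
    return tests


def _group_stats_exp2(part_df: pd.DataFrame) -> dict:
    var_cells = {
        "separation": ["separation_{p}_{s}", "part", "session"],
        "loading": ["loading_{p}_{s}", "part", "session"],
        "roll": ["roll_{p}_{s}", "part", "session"],
        "suppression": ["suppression_{p}_{s}", "part", "session"],
    }
    tests = {}
    for var, (pattern, fa_name, fb_name) in var_cells.items():
        cells = np.stack(
            [
                np.stack(
                    [
                        [part_df[pattern.format(p=p, s=s)].iloc[i] for s in ("implicit", "explicit")]
                        for p in ("mixed", "constant")
                    ]
                )
                for i in range(len(part_df))
            ]
        )
        res = stats.rm_anova_2x2(cells, factor_a=fa_name, factor_b=fb_name)
        entry = {"anova": _anova_dict(res)}
        if res.effects["AxB"].p < 0.05:
            posthoc = {}
            raw = []
            for s in ("implicit", "explicit"):
                t = stats.paired_t(
                    part_df[pattern.format(p="mixed", s=s)],
                    part_df[pattern.format(p="constant", s=s)],
                )
                posthoc[f"mixed_vs_constant_{s}"] = _t_dict(t)
                raw.append(t.p)
            for p in ("mixed", "constant"):
                t = stats.paired_t(
                    part_df[pattern.format(p=p, s="implicit")],
                    part_df[pattern.format(p=p, s="explicit")],
                )
                posthoc[f"{p}_implicit_vs_explicit"] = _t_dict(t)
                raw.append(t.p)
            adj = stats.bonferroni(raw, m=len(raw))
            for key, p_adj in zip(posthoc, adj):
                posthoc[key]["p_bonferroni"] = float(p_adj)
            entry["posthoc"] = posthoc
        tests[var] = entry
    return tests


def run_pipeline(config: RunConfig, out_dir: str | None = None) -> dict:
    """Run the full simulated study and return (and optionally write) the report."""
    if config.n_participants < 2:
        raise ValueError("group statistics require at least 2 participants")
    out_dir = out_dir or config.out_dir
    rng = np.random.default_rng(config.seed)
    policy = config.policy.to_policy()
    observer = config.observer.to_observer()
    obj = config.to_object_model()

    participants = []
    for pid in range(config.n_participants):
        seeds = [int(v) for v in rng.integers(2**31 - 1, size=3)]
        if config.experiment == "exp1":
            log.info("participant %d: simulating exp1 session", pid)
            design = build_exp1_session(seeds[0])
            dataset = simulate_experiment(design, policy, observer, obj, seed=seeds[1])
            row = _analyze_participant_exp1(dataset, config)
        else:
            first_md = "L" if pid % 2 == 0 else "R"
            datasets = {}
            for session, sim_seed in zip(("implicit", "explicit"), seeds[1:]):
                design = build_exp2_session(seeds[0], first_md, session)
                datasets[session] = simulate_experiment(
                    design, policy, observer, obj, seed=sim_seed
                )
            row = _analyze_participant_exp2(datasets, config)
        row["participant"] = pid
        participants.append(row)

    part_df = pd.DataFrame(participants).set_index("participant")
    kept = part_df[part_df["keep"]]
    if len(kept) < 2:
        raise ValueError("fewer than 2 participants survive the false-alarm exclusion")
    tests = _group_stats_exp1(kept) if config.experiment == "exp1" else _group_stats_exp2(kept)

    report = {
        "schema_version": 1,
        "experiment": config.experiment,
        "seed": config.seed,
        "n_participants": config.n_participants,
        "n_analyzed": int(len(kept)),
        "excluded": [int(i) for i in part_df.index[~part_df["keep"]]],
        "participants": part_df.reset_index().to_dict(orient="records"),
        "tests": tests,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
        part_df.reset_index().to_csv(out / "participants.tsv", sep="\t", index=False)
    return report


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
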