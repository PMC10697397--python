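"""Run orchestration: simulate -> behavior -> decode -> traces ->
responsiveness -> modulation -> ROC -> group report.

Every stage reads the documented dataset bundle (trials.csv / licks.csv /
traces.h5 / ground_truth.json), writes its CSV artifact into the output
directory, and logs a line-delimited JSON record with its seed and runtime.
Re-running with the same config reproduces every artifact byte-identically.
Group comparisons (means, SEM, Cohen's d, Mann-Whitney) are reporting
plumbing around the per-animal metrics, clearly separate from the analysis
definitions themselves.
"""
from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from . import behavior, decoding, modulation, responsiveness, roc, traces
from .config import CohortConfig, TaskConfig, default_cohort_config
from .synthetic import (Cohort, load_cohort, save_cohort, simulate_cohort,
                        session_duration)

__all__ = ["RunConfig", "run_pipeline", "cohens_d", "group_report",
           "write_figures",
           "behavior_summary", "decode_sessions", "cell_activity_table",
           "responsiveness_table", "modulation_table", "roc_table"]


@dataclass
class RunConfig:
    """Configuration of one reproducible pipeline run."""
    outdir: Union[str, Path] = "vipgate_out"
    cohort: Optional[CohortConfig] = None     # simulate when set
    input_dir: Optional[Union[str, Path]] = None  # else read a bundle
    stages: tuple[str, ...] = ("simulate", "behavior", "decode", "traces",
                               "respond", "modulate", "roc", "report")
    seed: int = 0
    decode_iterations: int = 200
    n_scrambles: int = 1000
    dprime_threshold: float = 2.0
    bin_size: int = 10
    neuropil_r: float = 0.7


def cohens_d(group_a, group_b) -> float:
    """Effect size (mean_a - mean_b) / pooled SD; NaN when the pooled SD is 0."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 values")
    pooled = np.sqrt(((len(a) - 1) * a.var(ddof=1)
                      + (len(b) - 1) * b.var(ddof=1))
                     / (len(a) + len(b) - 2))
    if pooled == 0:
        return float("nan")
    return float((a.mean() - b.mean()) / pooled)


def behavior_summary(cohort: Cohort, threshold: float = 2.0,
                     bin_size: int = 10) -> pd.DataFrame:
    """Per animal x session: d′ (all / distractor / no-distractor trials),
    response-class counts, % incorrect, and bins-to-criterion statistics."""
    rows = []
    for (animal, session), tdf in cohort.trials.groupby(["animal", "session"]):
        responses = list(tdf["response_class"])
        counts = behavior.counts_from_responses(responses)
        full = behavior.session_dprime(tdf, last_n=100)
        binned = behavior.binned_dprime(tdf, bin_size=bin_size,
                                        threshold=threshold)
        row = {"animal": animal, "session": session,
               "d_prime": full.d_prime, "short_session": full.short_session,
               **{f"n_{k.lower()}": v for k, v in counts.items()},
               "pct_incorrect": 100.0 * (counts["Miss"] + counts["FA"])
               / max(len(responses), 1),
               "bins_to_criterion": binned.bins_to_criterion,
               "bins_to_two_consecutive": binned.bins_to_two_consecutive}
        for flag, label in ((True, "distractor"), (False, "no_distractor")):
            sub = tdf[tdf["distractor"] == flag]
            c = behavior.counts_from_responses(sub["response_class"])
            try:
                row[f"d_prime_{label}"] = behavior.dprime(
                    c["Hit"], c["Miss"], c["CR"], c["FA"]).d_prime
            except ValueError:
                row[f"d_prime_{label}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def decode_sessions(cohort: Cohort, n_iterations: int = 200,
                    seed: int = 0) -> pd.DataFrame:
    """Per animal x session lick-decoding accuracy with shuffled control."""
    rows = []
    ss = np.random.SeedSequence(seed)
    for (animal, session), tdf in cohort.trials.groupby(["animal", "session"]):
        ldf = cohort.licks[(cohort.licks["animal"] == animal)
                           & (cohort.licks["session"] == session)]
        feats = decoding.featurize_licks(tdf, ldf)
        s1, s2 = (int(c.generate_state(1)[0] % (2 ** 31 - 1))
                  for c in ss.spawn(2))
        try:
            res = decoding.decode_stimulus(feats, n_iterations=n_iterations,
                                           seed=s1)
            ctrl = decoding.shuffled_control(feats, n_iterations=n_iterations,
                                             seed=s2)
        except ValueError:
            continue
        for r, shuffled in ((res, False), (ctrl, True)):
            lo, hi = (np.percentile(r.accuracy_distribution, [2.5, 97.5])
                      if r.n_iterations else (np.nan, np.nan))
            rows.append({"animal": animal, "session": session,
                         "mean_accuracy": r.mean_accuracy, "ci_low": lo,
                         "ci_high": hi, "shuffled": shuffled})
    return pd.DataFrame(rows)


def _ztraces(cohort: Cohort, r: float = 0.7):
    out = {}
    for key, tr in sorted(cohort.traces.items()):
        out[key] = traces.process_trace(tr, r=r)
    return out


def cell_activity_table(cohort: Cohort, ztraces: dict) -> pd.DataFrame:
    """Per cell: evoked and spontaneous AUC rates, event rate, activity flag."""
    rows = []
    for (animal, fov, cell), zt in ztraces.items():
        recs = cohort.trial_records.get(animal) or _records_from_frame(
            cohort, animal)
        fr = zt.frame_rate
        stim_w, gray_w = [], []
        for tr in recs:
            s0 = int(round(tr.trial_start_s * fr))
            s1 = s0 + int(round(cohort.task.stimulus_duration * fr))
            g1 = s1 + int(round(cohort.task.iti_duration * fr))
            if g1 <= zt.n_frames:
                stim_w.append((s0, s1))
                gray_w.append((s1, g1))
        ev, sp = traces.evoked_and_spontaneous_means(zt, stim_w, gray_w)
        events = traces.detect_events(zt)
        vis = modulation.visual_modulation_index(ev, sp)
        rows.append({"animal": animal, "fov": fov, "cell": cell,
                     "cell_class": zt.cell_class, "evoked": ev,
                     "spontaneous": sp, "event_rate": events.event_rate,
                     "auc_rate": events.auc_rate, "active": events.active,
                     "visual_modulation": vis.value})
    return pd.DataFrame(rows)


def _records_from_frame(cohort: Cohort, animal: str):
    """Rebuild lightweight trial records from the CSV tables."""
    from .synthetic import TrialRecord
    tdf = cohort.trials[cohort.trials["animal"] == animal]
    ldf = cohort.licks[cohort.licks["animal"] == animal]
    lick_map = {k: g.to_numpy()
                for k, g in ldf.groupby("trial_index")["lick_time_s"]}
    recs = []
    for _, r in tdf.iterrows():
        recs.append(TrialRecord(
            trial_index=int(r["trial_index"]), stimulus=r["stimulus"],
            distractor=bool(r["distractor"]),
            distractor_modality=r.get("distractor_modality", "none"),
            lick_times=lick_map.get(int(r["trial_index"]), np.array([])),
            response_class=r["response_class"],
            trial_start_s=float(r["trial_start_s"]),
            session_id=str(r["session"])))
    return recs


def responsiveness_table(cohort: Cohort, ztraces: dict,
                         n_scrambles: int = 1000, seed: int = 0
                         ) -> pd.DataFrame:
    """Per cell: epoch-scramble responsiveness against the all-trial stimulus
    time course and against each stimulus class separately."""
    rows = []
    ss = np.random.SeedSequence(seed)
    for (animal, fov, cell), zt in sorted(ztraces.items()):
        recs = cohort.trial_records.get(animal) or _records_from_frame(
            cohort, animal)
        row = {"animal": animal, "fov": fov, "cell": cell,
               "cell_class": zt.cell_class}
        for which in ("all", "preferred", "nonpreferred"):
            ind = responsiveness.trials_indicator(recs, cohort.task,
                                                  zt.n_frames, which)
            rng = np.random.default_rng(ss.spawn(1)[0])
            res = responsiveness.responsiveness_test(
                zt, ind, n_scrambles=n_scrambles, rng=rng)
            tag = "" if which == "all" else f"_{which}"
            row[f"observed_r{tag}"] = res.observed_r
            row[f"percentile{tag}"] = res.null_percentile
            row[f"responsive{tag}"] = res.responsive
        rows.append(row)
    return pd.DataFrame(rows)


def modulation_table(cohort: Cohort, ztraces: dict) -> pd.DataFrame:
    """Per cell error-modulation indices by window, distractor condition, and
    first/last-20 trial subset."""
    rows = []
    for (animal, fov, cell), zt in sorted(ztraces.items()):
        recs = cohort.trial_records.get(animal) or _records_from_frame(
            cohort, animal)
        aligned = modulation.align_trials(zt, recs, cohort.task)
        for window in ("stimulus", "poststimulus"):
            for dis in (None, True, False):
                subsets = {"all": None}
                try:
                    split = modulation.early_late_split(recs, k=20,
                                                        distractor=dis)
                    subsets["first20"] = split.first
                    subsets["last20"] = split.last
                except ValueError:
                    pass
                for label, idx in subsets.items():
                    mi = modulation.error_modulation_index(
                        aligned, window=window, distractor=dis,
                        trial_indices=idx)
                    rows.append({
                        "animal": animal, "fov": fov, "cell": cell,
                        "cell_class": zt.cell_class, "kind": mi.kind,
                        "window": window,
                        "condition": {None: "all", True: "distractor",
                                      False: "no_distractor"}[dis],
                        "subset": label, "value": mi.value,
                        "n_error": mi.n_error_trials,
                        "n_correct": mi.n_correct_trials,
                        "reason": mi.reason})
    return pd.DataFrame(rows)


def roc_table(cohort: Cohort, ztraces: dict) -> pd.DataFrame:
    """Per pyramidal cell: leave-one-out DV ROC AUC over Hit vs CR trials."""
    rows = []
    for (animal, fov, cell), zt in sorted(ztraces.items()):
        if zt.cell_class != "pyramidal":
            continue
        recs = cohort.trial_records.get(animal) or _records_from_frame(
            cohort, animal)
        fr = zt.frame_rate
        n_stim = int(round(cohort.task.stimulus_duration * fr))
        psths = {"Hit": [], "CR": []}
        for tr in recs:
            if tr.response_class not in psths:
                continue
            s0 = int(round(tr.trial_start_s * fr))
            if s0 + n_stim <= zt.n_frames:
                psths[tr.response_class].append(zt.z[s0:s0 + n_stim])
        if len(psths["Hit"]) < 2 or len(psths["CR"]) < 2:
            continue
        dv_h, dv_c = roc.decision_variables(np.array(psths["Hit"]),
                                            np.array(psths["CR"]))
        rows.append({"animal": animal, "fov": fov, "cell": cell,
                     "n_hit": len(psths["Hit"]), "n_cr": len(psths["CR"]),
                     "auc": roc.roc_auc(dv_h, dv_c)})
    return pd.DataFrame(rows, columns=["animal", "fov", "cell", "n_hit",
                                       "n_cr", "auc"])


def group_report(per_animal: pd.DataFrame, value_cols: list[str],
                 group_col: str = "genotype") -> pd.DataFrame:
    """Per group x metric: mean, SEM, n, plus Cohen's d and Mann-Whitney U/p
    for two-group comparisons (omitted with a single group)."""
    rows = []
    groups = sorted(per_animal[group_col].dropna().unique())
    for col in value_cols:
        vals = {g: per_animal.loc[per_animal[group_col] == g, col].dropna()
                .to_numpy() for g in groups}
        for g in groups:
            rows.append({"metric": col, "group": g,
                         "mean": vals[g].mean() if len(vals[g]) else np.nan,
                         "sem": (vals[g].std(ddof=1) / np.sqrt(len(vals[g]))
                                 if len(vals[g]) > 1 else np.nan),
                         "n": len(vals[g])})
        if len(groups) == 2:
            a, b = vals[groups[0]], vals[groups[1]]
            if len(a) >= 2 and len(b) >= 2:
                try:
                    stat, p = mannwhitneyu(a, b, alternative="two-sided")
                except ValueError:
                    stat, p = np.nan, np.nan
                rows.append({"metric": col,
                             "group": f"{groups[0]} vs {groups[1]}",
                             "mean": np.nan, "sem": np.nan,
                             "n": len(a) + len(b),
                             "cohens_d": cohens_d(a, b),
                             "test": "mannwhitneyu", "statistic": stat,
                             "p_value": p})
    return pd.DataFrame(rows)


def write_figures(outdir: Path, summary: pd.DataFrame,
                  modulation_df: Optional[pd.DataFrame] = None) -> list[Path]:
    """Group-report figures: distractor-trial d′ by genotype, and the
    error-modulation vs %-incorrect scatter with its least-squares line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written: list[Path] = []
    if "d_prime_distractor" in summary.columns and "genotype" in summary:
        fig, ax = plt.subplots(figsize=(4, 3))
        for i, (g, sub) in enumerate(sorted(summary.groupby("genotype"))):
            vals = sub["d_prime_distractor"].dropna()
            ax.scatter(np.full(len(vals), i), vals, alpha=0.7)
            ax.hlines(vals.mean(), i - 0.2, i + 0.2, colors="k")
        ax.set_xticks(range(summary["genotype"].nunique()))
        ax.set_xticklabels(sorted(summary["genotype"].unique()))
        ax.axhline(2.0, ls="--", c="gray", lw=0.8)
        ax.set_ylabel("distractor-trial d'")
        fig.tight_layout()
        path = outdir / "dprime_distractor.svg"
        fig.savefig(path)
        plt.close(fig)
        written.append(path)
    if modulation_df is not None and len(modulation_df):
        per_animal = (modulation_df[(modulation_df["window"] == "poststimulus")
                                    & (modulation_df["condition"] == "all")
                                    & (modulation_df["subset"] == "all")]
                      .groupby("animal")["value"].mean())
        merged = summary.set_index("animal").join(per_animal.rename("mod"))
        merged = merged.dropna(subset=["mod", "pct_incorrect"])
        if len(merged) >= 3 and merged["mod"].std() > 0:
            corr = modulation.modulation_vs_performance(
                merged["mod"], merged["pct_incorrect"])
            fig, ax = plt.subplots(figsize=(4, 3))
            ax.scatter(merged["mod"], merged["pct_incorrect"])
            xs = np.linspace(merged["mod"].min(), merged["mod"].max(), 20)
            ax.plot(xs, corr.intercept + corr.slope * xs, "r-",
                    label=f"r = {corr.r:.2f}")
            ax.set_xlabel("mean poststimulus error modulation")
            ax.set_ylabel("% incorrect responses")
            ax.legend(frameon=False)
            fig.tight_layout()
            path = outdir / "modulation_vs_incorrect.svg"
            fig.savefig(path)
            plt.close(fig)
            written.append(path)
    return written


def _genotype_of(animal: str, cohort: Cohort) -> str:
    info = cohort.ground_truth.get("animals", {}).get(animal)
    if info:
        return info["genotype"]
    return animal.rsplit("_", 1)[0]


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the configured stages, writing every declared artifact.

    Returns a mapping of artifact name to path.  Stages that depend on missing
    upstream outputs raise a FileNotFoundError naming the missing file.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    log_path = outdir / "log.jsonl"
    log = open(log_path, "a")

    def stage(name: str, fn):
        t0 = time.perf_counter()
        result = fn()
        log.write(json.dumps({"stage": name, "seed": config.seed,
                              "runtime_s": round(time.perf_counter() - t0, 3)})
                  + "\n")
        return result

    cfg_dict = asdict(config)
    cfg_dict["outdir"] = str(config.outdir)
    if config.input_dir is not None:
        cfg_dict["input_dir"] = str(config.input_dir)
    (outdir / "run_config.json").write_text(json.dumps(cfg_dict, indent=1,
                                                       default=str))
    if "simulate" in config.stages:
        cohort_cfg = config.cohort or default_cohort_config(seed=config.seed)
        cohort = stage("simulate", lambda: simulate_cohort(cohort_cfg))
        save_cohort(cohort, outdir)
        for name in ("trials.csv", "licks.csv", "traces.h5",
                     "ground_truth.json"):
            artifacts[name] = outdir / name
    else:
        src = Path(config.input_dir or outdir)
        if not (src / "trials.csv").exists():
            raise FileNotFoundError(
                f"stage dependency missing: {src / 'trials.csv'}")
        cohort = load_cohort(src)

    if "behavior" in config.stages:
        summary = stage("behavior", lambda: behavior_summary(
            cohort, threshold=config.dprime_threshold,
            bin_size=config.bin_size))
        summary.insert(0, "genotype",
                       [_genotype_of(a, cohort) for a in summary["animal"]])
        summary.to_csv(outdir / "behavior_summary.csv", index=False)
        artifacts["behavior_summary.csv"] = outdir / "behavior_summary.csv"
        profiles = []
        for (animal, session), tdf in cohort.trials.groupby(
                ["animal", "session"]):
            ldf = cohort.licks[(cohort.licks["animal"] == animal)
                               & (cohort.licks["session"] == session)]
            prof = behavior.lick_probability_profile(tdf, ldf)
            prof.insert(0, "animal", animal)
            profiles.append(prof.reset_index(names="stimulus"))
        if profiles:
            pd.concat(profiles, ignore_index=True).to_csv(
                outdir / "lick_profiles.csv", index=False)
            artifacts["lick_profiles.csv"] = outdir / "lick_profiles.csv"

    if "decode" in config.stages:
        dec = stage("decode", lambda: decode_sessions(
            cohort, n_iterations=config.decode_iterations, seed=config.seed))
        dec.to_csv(outdir / "decoding.csv", index=False)
        artifacts["decoding.csv"] = outdir / "decoding.csv"

    ztr = None
    if {"traces", "respond", "modulate", "roc"} & set(config.stages):
        if not cohort.traces:
            ztr = {}
        else:
            ztr = stage("traces", lambda: _ztraces(cohort,
                                                   r=config.neuropil_r))
    if "traces" in config.stages and ztr:
        act = cell_activity_table(cohort, ztr)
        act.to_csv(outdir / "cell_activity.csv", index=False)
        artifacts["cell_activity.csv"] = outdir / "cell_activity.csv"
    if "respond" in config.stages and ztr:
        resp = stage("respond", lambda: responsiveness_table(
            cohort, ztr, n_scrambles=config.n_scrambles, seed=config.seed))
        resp.to_csv(outdir / "responsiveness.csv", index=False)
        artifacts["responsiveness.csv"] = outdir / "responsiveness.csv"
    if "modulate" in config.stages and ztr:
        mod = stage("modulate", lambda: modulation_table(cohort, ztr))
        mod.to_csv(outdir / "modulation.csv", index=False)
        artifacts["modulation.csv"] = outdir / "modulation.csv"
    if "roc" in config.stages and ztr:
        rdf = stage("roc", lambda: roc_table(cohort, ztr))
        rdf.to_csv(outdir / "neuron_roc.csv", index=False)
        artifacts["neuron_roc.csv"] = outdir / "neuron_roc.csv"

    if "report" in config.stages and "behavior_summary.csv" in artifacts:
        summary = pd.read_csv(outdir / "behavior_summary.csv")
        value_cols = [c for c in ("d_prime", "d_prime_distractor",
                                  "d_prime_no_distractor", "pct_incorrect")
                      if c in summary.columns]
        report = stage("report", lambda: group_report(summary, value_cols))
        if (outdir / "modulation.csv").exists():
            mod = pd.read_csv(outdir / "modulation.csv")
            per_animal = (mod[(mod["window"] == "poststimulus")
                              & (mod["condition"] == "all")
                              & (mod["subset"] == "all")]
                          .groupby("animal")["value"].mean().reset_index())
            per_animal["genotype"] = [_genotype_of(a, cohort)
                                      for a in per_animal["animal"]]
            report = pd.concat(
                [report, group_report(per_animal, ["value"])],
                ignore_index=True)
        report.to_csv(outdir / "group_summary.csv", index=False)
        artifacts["group_summary.csv"] = outdir / "group_summary.csv"
        mod_df = (pd.read_csv(outdir / "modulation.csv")
                  if (outdir / "modulation.csv").exists() else None)
        for fig_path in write_figures(outdir, summary, mod_df):
            artifacts[fig_path.name] = fig_path

    log.close()
    artifacts["log.jsonl"] = log_path
    artifacts["run_config.json"] = outdir / "run_config.json"
    return artifacts
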