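"""Validation studies: calibration, power, parameter recovery, and group-level
sign structure, all computed on synthetic data with known ground truth.

These are the package's self-checks.  Each study regenerates its inputs from a
seed, runs the full analysis path (simulate -> process -> measure), and
returns summary numbers; nothing is cached or looked up.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import behavior, decoding, modulation, responsiveness, traces
from .config import AgentParams, NeuronParams, TaskConfig, default_cohort_config
from .decoding import LickFeatureMatrix
from .pipeline import behavior_summary
from .synthetic import passive_trials, simulate_calcium, simulate_cohort, \
    simulate_session

__all__ = [
    "svm_calibration_study", "responsiveness_calibration_study",
    "responsiveness_power_study", "error_gain_recovery_study",
    "cohort_ordering_study", "baseline_agreement_study",
]


def svm_calibration_study(n_trials: int = 100, n_iterations: int = 1000,
                          seed: int = 0) -> dict[str, float]:
    """Chance, separable, and shuffled-control accuracies of the lick decoder.

    Chance: random balanced labels on all-zero lick features.  Separable:
    one class licks in every bin, the other never.  Shuffled control: the
    separable data with labels permuted each iteration.
    """
    half = n_trials // 2
    y = np.array(["preferred", "nonpreferred"] * half)
    zeros = LickFeatureMatrix(X=np.zeros((2 * half, 19), dtype=int), y=y,
                              bin=0.1, window=(0.0, 1.9))
    sep_y = np.array(["preferred"] * half + ["nonpreferred"] * half)
    sep = LickFeatureMatrix(
        X=np.vstack([np.ones((half, 19), int), np.zeros((half, 19), int)]),
        y=sep_y, bin=0.1, window=(0.0, 1.9))
    chance = decoding.decode_stimulus(zeros, n_iterations=n_iterations,
                                      seed=seed)
    separable = decoding.decode_stimulus(sep, n_iterations=min(n_iterations,
                                                               200),
                                         seed=seed + 1)
    shuffled = decoding.shuffled_control(sep, n_iterations=min(n_iterations,
                                                               300),
                                         seed=seed + 2)
    return {"chance_accuracy_pct": chance.mean_accuracy,
            "separable_accuracy_pct": separable.mean_accuracy,
            "shuffled_accuracy_pct": shuffled.mean_accuracy}


def _passive_setup(n_trials: int = 50):
    task = TaskConfig(n_trials=n_trials)
    trials = passive_trials(n_trials, task)
    return task, trials


def responsiveness_calibration_study(n_cells: int = 500,
                                     n_scrambles: int = 1000,
                                     alpha: float = 1.0,
                                     seed: int = 0) -> dict[str, float]:
    """Empirical false-positive rate of the epoch-scramble test on null cells
    whose events are independent of the stimulus (stim_gain = 1)."""
    task, trials = _passive_setup()
    rng = np.random.default_rng(seed)
    neuron = NeuronParams(cell_class="vip", baseline_event_rate=0.15,
                          stim_gain=1.0, noise_sd=0.1)
    false_positives = 0
    for _ in range(n_cells):
        tr = simulate_calcium(neuron, trials, task, rng)
        zt = traces.process_trace(tr)
        ind = responsiveness.trials_indicator(trials, task, zt.n_frames)
        res = responsiveness.responsiveness_test(zt, ind,
                                                 n_scrambles=n_scrambles,
                                                 alpha=alpha, rng=rng)
        false_positives += res.responsive
    return {"false_positive_rate_pct": 100.0 * false_positives / n_cells,
            "n_cells": n_cells}


def responsiveness_power_study(n_cells: int = 50, n_scrambles: int = 1000,
                               seed: int = 0) -> dict[str, float]:
    """Detection rate for stimulus-driven cells whose evoked Z-score exceeds
    the gray-screen level by >= 2 (measured, not assumed)."""
    task, trials = _passive_setup()
    rng = np.random.default_rng(seed)
    neuron = NeuronParams(cell_class="vip", baseline_event_rate=0.1,
                          stim_gain=6.0, noise_sd=0.1)
    detected, excesses = 0, []
    for _ in range(n_cells):
        tr = simulate_calcium(neuron, trials, task, rng)
        zt = traces.process_trace(tr)
        ind = responsiveness.trials_indicator(trials, task, zt.n_frames)
        on = ind.astype(bool)
        excesses.append(float(zt.z[on].mean() - zt.z[~on].mean()))
        res = responsiveness.responsiveness_test(zt, ind,
                                                 n_scrambles=n_scrambles,
                                                 rng=rng)
        detected += res.responsive
    return {"power_pct": 100.0 * detected / n_cells,
            "mean_evoked_z_excess": float(np.mean(excesses)),
            "n_cells": n_cells}


def error_gain_recovery_study(gains: tuple[float, ...] = (1.0, 1.5, 2.0),
                              n_seeds: int = 20,
                              seed: int = 0) -> dict[str, float]:
    """Recover injected VIP error gains through the full trace-processing and
    modulation-index path.

    Each replicate simulates a 200-trial session whose licking policy yields
    roughly 100 error and 100 correct trials, images one high-SNR VIP cell
    with the injected gain, and computes the stimulus-window error modulation
    index; the recovered value is the mean over replicates.
    """
    task = TaskConfig(n_trials=200)
    agent = AgentParams(p_hit=0.5, p_fa_base=0.5, distractor_fa_boost=0.0,
                        lapse_rate=0.0)
    ss = np.random.SeedSequence(seed)
    out: dict[str, float] = {}
    for gain in gains:
        rng = np.random.default_rng(ss.spawn(1)[0])
        estimates = []
        for _ in range(n_seeds):
            trials = simulate_session(agent, task, rng)
            neuron = NeuronParams(cell_class="vip", baseline_event_rate=0.1,
                                  stim_gain=8.0, error_gain=gain,
                                  noise_sd=0.05)
            tr = simulate_calcium(neuron, trials, task, rng)
            zt = traces.process_trace(tr)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                aligned = modulation.align_trials(zt, trials, task)
            mi = modulation.error_modulation_index(aligned, "stimulus")
            if mi.defined:
                estimates.append(mi.value)
        out[f"recovered_gain_{gain:g}"] = float(np.mean(estimates))
    return out


def cohort_ordering_study(n_replicates: int = 20, n_animals: int = 5,
                          seed: int = 0) -> dict[str, float]:
    """Group-level sign structure of default WT-like vs KO-like cohorts.

    Per replicate: (1) mean distractor-trial d′ ordering WT > KO, (2) mean
    poststimulus error-modulation ordering WT > KO, and (3) the sign of the
    across-animal correlation between mean error modulation and % incorrect
    responses.  Returns the fraction of replicates showing each effect.
    """
    wins = {"dprime": 0, "modulation": 0, "negative_correlation": 0}
    for rep in range(n_replicates):
        cfg = default_cohort_config(seed=seed + rep,
                                    n_animals_per_genotype=n_animals)
        cohort = simulate_cohort(cfg)
        summary = behavior_summary(cohort)
        summary["genotype"] = [a.rsplit("_", 1)[0]
                               for a in summary["animal"]]
        dp = summary.groupby("genotype")["d_prime_distractor"].mean()
        if dp["WT"] > dp["KO"]:
            wins["dprime"] += 1
        per_animal: dict[str, list[float]] = {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for (animal, fov, cell), tr in cohort.traces.items():
                if tr.cell_class != "vip":
                    continue
                zt = traces.process_trace(tr)
                aligned = modulation.align_trials(
                    zt, cohort.trial_records[animal], cohort.task)
                mi = modulation.error_modulation_index(aligned,
                                                       "poststimulus")
                if mi.defined:
                    per_animal.setdefault(animal, []).append(mi.value)
        means = {a: float(np.mean(vs)) for a, vs in per_animal.items()}
        wt = [m for a, m in means.items() if a.startswith("WT")]
        ko = [m for a, m in means.items() if a.startswith("KO")]
        if wt and ko and np.mean(wt) > np.mean(ko):
            wins["modulation"] += 1
        pct = summary.set_index("animal")["pct_incorrect"]
        animals = sorted(means)
        corr = modulation.modulation_vs_performance(
            [means[a] for a in animals], [pct[a] for a in animals])
        if corr.defined and corr.r < 0:
            wins["negative_correlation"] += 1
    return {f"{k}_fraction_pct": 100.0 * n / n_replicates
            for k, n in wins.items()} | {"n_replicates": n_replicates}


def baseline_agreement_study(n_traces: int = 100,
                             seed: int = 0) -> dict[str, float]:
    """Fraction of random traces where the quiet-baseline search matches an
    exhaustive per-window SD argmin."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_traces):
        n = int(rng.integers(200, 800))
        trace = rng.normal(0, 1, n) + np.sin(np.arange(n) / 40.0)
        start, length = traces.find_quiet_baseline(trace, 15.0)
        sds = np.array([trace[i:i + length].std()
                        for i in range(n - length + 1)])
        agree += start == int(np.argmin(sds))
    return {"agreement_fraction": agree / n_traces, "n_traces": n_traces}
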