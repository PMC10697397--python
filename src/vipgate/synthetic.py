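"""Synthetic cohort generator: behavior sessions and calcium traces with known
ground truth.

Every downstream stage of the package has a recoverable target here: the
licking policy fixes the Hit/Miss/CR/FA mixture and hence d′, the event-train
gains (``stim_gain``, ``error_gain``, orientation tuning) fix what the trace
processing, responsiveness bootstrap, modulation indices and ROC analysis
should recover.  Seeding is hierarchical and stable: each animal, neuron and
neuropil signal draws from a `numpy` SeedSequence keyed by its position in the
cohort, so adding a neuron never perturbs any other stream.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .behavior import classify_trial
from .config import (AgentParams, CohortConfig, ConfigError, GenotypeProfile,
                     NeuronParams, TaskConfig)

__all__ = [
    "TrialRecord", "FluorescenceTrace", "Cohort",
    "simulate_session", "simulate_calcium", "simulate_cohort",
    "passive_trials",
    "make_neuropil", "calcium_kernel", "session_duration",
    "trials_to_frame", "licks_to_frame", "save_cohort", "load_cohort",
]

SeedLike = Union[int, np.random.SeedSequence, np.random.Generator, None]


@dataclass(frozen=True)
class TrialRecord:
    """One behavioral trial: stimulus, distractor flag, licks, outcome, timing."""
    trial_index: int
    stimulus: str                  # 'preferred' | 'nonpreferred'
    distractor: bool
    distractor_modality: str       # 'none' | 'auditory' | 'visual'
    lick_times: np.ndarray         # seconds from stimulus onset, within [0, stim)
    response_class: str            # 'Hit' | 'Miss' | 'CR' | 'FA'
    trial_start_s: float
    session_id: str = "sim"

    @property
    def is_error(self) -> bool:
        return self.response_class in ("Miss", "FA")


@dataclass
class FluorescenceTrace:
    """Per-cell raw fluorescence plus matched neuropil trace."""
    samples: np.ndarray
    neuropil_samples: np.ndarray
    frame_rate: float
    cell_class: str
    animal: str = "sim"
    fov: str = "fov0"
    cell: str = "cell0"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.neuropil_samples = np.asarray(self.neuropil_samples, dtype=float)
        if self.samples.shape != self.neuropil_samples.shape:
            raise ValueError("samples and neuropil_samples must have equal length")
        if self.frame_rate <= 0:
            raise ConfigError("frame_rate must be > 0")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def n_frames(self) -> int:
        return len(self.samples)


def _rng(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_session(agent: AgentParams, task: TaskConfig,
                     rng_seed: SeedLike = None, session_id: str = "sim",
                     distractor_modality: str = "auditory") -> list[TrialRecord]:
    """Simulate one behavioral session of ``task.n_trials`` trials.

    Stimulus class is equiprobable, distractors are Bernoulli draws, and the
    probability of a go decision is ``p_hit`` on preferred trials and
    ``p_fa_base`` (plus a distractor boost decaying with ``recovery_tau``
    trials) on nonpreferred ones; a lapse flips the decision.  A go decision
    places one lick uniformly in the reward window plus anticipatory licks
    from a linearly ramping Poisson process over the stimulus period, so the
    stored response class always matches reclassification of the lick times.
    The trial-start clock accumulates the ITI plus a time-out after errors.
    """
    rng = _rng(rng_seed)
    trials: list[TrialRecord] = []
    t = 0.0
    lo, hi = task.reward_window
    for i in range(task.n_trials):
        stimulus = "preferred" if rng.random() < 0.5 else "nonpreferred"
        distractor = bool(rng.random() < task.distractor_fraction)
        if stimulus == "preferred":
            p_go = agent.p_hit
        else:
            p_go = agent.p_fa_base
            if distractor:
                p_go = p_go + agent.distractor_fa_boost * math.exp(
                    -i / agent.recovery_tau)
        p_go = min(max(p_go, 0.0), 1.0)
        go = rng.random() < p_go
        if rng.random() < agent.lapse_rate:
            go = not go
        if go:
            licks = [lo + rng.random() * (hi - lo)]
            # anticipatory ramp lambda(t) = ramp * t over [0, stim): expected
            # count ramp*T^2/2, inverse-CDF sampling t = T*sqrt(u)
            T = task.stimulus_duration
            n_extra = rng.poisson(agent.anticipatory_ramp_rate * T * T / 2.0)
            licks.extend(T * np.sqrt(rng.random(n_extra)))
            lick_times = np.sort(np.asarray(licks))
            lick_times = lick_times[lick_times < T]
        else:
            lick_times = np.array([])
        response = classify_trial(stimulus, lick_times, task.reward_window)
        trials.append(TrialRecord(
            trial_index=i, stimulus=stimulus, distractor=distractor,
            distractor_modality=distractor_modality if distractor else "none",
            lick_times=lick_times, response_class=response,
            trial_start_s=t, session_id=session_id))
        t += task.correct_trial_duration
        if response in ("Miss", "FA"):
            t += task.timeout_duration
    return trials


def passive_trials(n_trials: int, task: TaskConfig,
                   session_id: str = "passive") -> list[TrialRecord]:
    """Trial records for a passive-viewing session: stimuli alternate between
    the two classes on a fixed stimulus/gray cycle with no licking, no
    distractors, and no time-outs (all trials logged as CRs/Misses is
    meaningless here, so every trial is marked correct)."""
    out = []
    for i in range(n_trials):
        stim = "preferred" if i % 2 == 0 else "nonpreferred"
        out.append(TrialRecord(
            trial_index=i, stimulus=stim, distractor=False,
            distractor_modality="none", lick_times=np.array([]),
            response_class="Hit" if stim == "preferred" else "CR",
            trial_start_s=i * task.correct_trial_duration,
            session_id=session_id))
    return out


def session_duration(trials: Sequence[TrialRecord], task: TaskConfig) -> float:
    """Total session duration in seconds implied by the trial records."""
    if not trials:
        return 0.0
    last = trials[-1]
    dur = last.trial_start_s + task.correct_trial_duration
    if last.is_error:
        dur += task.timeout_duration
    return dur


def calcium_kernel(frame_rate: float, rise: float = 0.05,
                   decay: float = 0.7) -> np.ndarray:
    """Difference-of-exponentials impulse response, unit peak amplitude."""
    if frame_rate <= 0:
        raise ConfigError("frame_rate must be > 0")
    t = np.arange(0.0, 6.0 * decay, 1.0 / frame_rate)
    k = np.exp(-t / decay) - np.exp(-t / rise)
    peak = k.max()
    if peak <= 0:
        raise ConfigError("degenerate kernel (check rise < decay)")
    return k / peak


def make_neuropil(n_frames: int, frame_rate: float, rng_seed: SeedLike = None,
                  sd: float = 0.2, timescale_s: float = 2.0) -> np.ndarray:
    """Shared low-frequency neuropil signal: Gaussian noise smoothed over
    ``timescale_s`` and rescaled to the requested standard deviation."""
    rng = _rng(rng_seed)
    white = rng.normal(size=n_frames)
    half = max(int(round(timescale_s * frame_rate)), 1)
    win = np.exp(-0.5 * (np.arange(-3 * half, 3 * half + 1) / half) ** 2)
    win /= win.sum()
    smooth = fftconvolve(white, win, mode="same")
    s = smooth.std()
    return smooth * (sd / s) if s > 0 else smooth


def _tuning_factor(neuron: NeuronParams, stimulus: str) -> float:
    """Von Mises orientation tuning for pyramidal cells; the two task gratings
    are orthogonal, so the nonpreferred factor is exp(-2*kappa)."""
    if neuron.tuning_width is None or stimulus == "preferred":
        return 1.0
    return math.exp(neuron.tuning_width * (math.cos(math.pi) - 1.0))


def event_rate_vector(neuron: NeuronParams, trials: Sequence[TrialRecord],
                      task: TaskConfig, n_frames: int) -> np.ndarray:
    """Per-frame Poisson event rate (events/s) implied by the generative model."""
    fr = task.frame_rate
    rate = np.full(n_frames, neuron.baseline_event_rate)
    # windows are fixed frame offsets from each trial's start frame, matching
    # the alignment convention used by the analysis stages
    n_stim = int(round(task.stimulus_duration * fr))
    n_post = int(round((task.stimulus_duration + task.iti_duration) * fr))
    for tr in trials:
        s0 = int(round(tr.trial_start_s * fr))
        rate[s0:min(s0 + n_stim, n_frames)] *= (
            neuron.stim_gain * _tuning_factor(neuron, tr.stimulus))
        if tr.is_error and neuron.error_gain != 1.0:
            rate[s0:min(s0 + n_post, n_frames)] *= neuron.error_gain
    return rate


def simulate_calcium(neuron: NeuronParams, trials: Sequence[TrialRecord],
                     task: TaskConfig, rng_seed: SeedLike = None,
                     neuropil: Optional[np.ndarray] = None,
                     animal: str = "sim", fov: str = "fov0",
                     cell: str = "cell0") -> FluorescenceTrace:
    """Forward model of one cell's fluorescence over a session.

    An inhomogeneous Poisson event train (rate = baseline x stimulus gain x
    orientation tuning x error gain over the stimulus+poststimulus window of
    error trials) is convolved with a difference-of-exponentials kernel, mixed
    with ``neuropil_coupling`` times a shared low-frequency neuropil trace,
    and perturbed by additive white noise.
    """
    if not trials:
        raise ValueError("trials must be non-empty")
    if task.frame_rate <= 0:
        raise ConfigError("frame_rate must be > 0")
    rng = _rng(rng_seed)
    fr = task.frame_rate
    n_frames = int(round(session_duration(trials, task) * fr))
    rate = event_rate_vector(neuron, trials, task, n_frames)
    events = rng.poisson(rate / fr).astype(float)
    kernel = calcium_kernel(fr, neuron.kernel_rise, neuron.kernel_decay)
    signal = fftconvolve(events, kernel)[:n_frames] if events.any() else \
        np.zeros(n_frames)
    if neuropil is None:
        neuropil = make_neuropil(n_frames, fr, rng)
    neuropil = np.asarray(neuropil, dtype=float)
    if len(neuropil) != n_frames:
        raise ValueError("neuropil length does not match session duration")
    samples = signal + neuron.neuropil_coupling * neuropil
    if neuron.noise_sd > 0:
        samples = samples + rng.normal(scale=neuron.noise_sd, size=n_frames)
    return FluorescenceTrace(samples=samples, neuropil_samples=neuropil,
                             frame_rate=fr, cell_class=neuron.cell_class,
                             animal=animal, fov=fov, cell=cell)


@dataclass
class Cohort:
    """In-memory dataset bundle for a simulated cohort."""
    trials: pd.DataFrame
    licks: pd.DataFrame
    traces: dict[tuple[str, str, str], FluorescenceTrace]
    ground_truth: dict
    task: TaskConfig
    trial_records: dict[str, list[TrialRecord]] = field(default_factory=dict)

    def animals(self) -> list[str]:
        return sorted(self.trials["animal"].unique()) if len(self.trials) else []


def trials_to_frame(trials: Sequence[TrialRecord], animal: str = "sim",
                    session: str = "s1") -> pd.DataFrame:
    return pd.DataFrame({
        "animal": animal,
        "session": session,
        "trial_index": [t.trial_index for t in trials],
        "stimulus": [t.stimulus for t in trials],
        "distractor": [t.distractor for t in trials],
        "distractor_modality": [t.distractor_modality for t in trials],
        "response_class": [t.response_class for t in trials],
        "trial_start_s": [t.trial_start_s for t in trials],
    })


def licks_to_frame(trials: Sequence[TrialRecord], animal: str = "sim",
                   session: str = "s1") -> pd.DataFrame:
    rows = [(animal, session, t.trial_index, lt)
            for t in trials for lt in t.lick_times]
    return pd.DataFrame(rows, columns=["animal", "session", "trial_index",
                                       "lick_time_s"])


_TRIAL_COLUMNS = ["animal", "session", "trial_index", "stimulus", "distractor",
                  "distractor_modality", "response_class", "trial_start_s"]
_LICK_COLUMNS = ["animal", "session", "trial_index", "lick_time_s"]


def simulate_cohort(config: CohortConfig) -> Cohort:
    """Simulate behavior and calcium for every animal of every genotype.

    Deterministic under a fixed config: per-animal streams are keyed by
    (genotype index, animal index, role) through SeedSequence spawn keys.
    """
    trial_frames, lick_frames = [], []
    traces: dict[tuple[str, str, str], FluorescenceTrace] = {}
    records: dict[str, list[TrialRecord]] = {}
    gt: dict = {"config": config.to_dict(), "animals": {}}
    seen: set[str] = set()
    for gi, (genotype, profile) in enumerate(sorted(
            config.genotype_profiles.items())):
        for ai in range(config.n_animals_per_genotype):
            animal = f"{genotype}_{ai:02d}"
            if animal in seen:
                raise ValueError(f"duplicate animal identifier: {animal}")
            seen.add(animal)
            draw_rng = _rng(np.random.SeedSequence(config.seed,
                                                   spawn_key=(gi, ai, 0)))
            agent, vip, pyr = _animal_params(profile, draw_rng)
            beh_rng = _rng(np.random.SeedSequence(config.seed,
                                                  spawn_key=(gi, ai, 1)))
            trials = simulate_session(agent, config.task, beh_rng,
                                      session_id="s1")
            records[animal] = trials
            trial_frames.append(trials_to_frame(trials, animal, "s1"))
            lick_frames.append(licks_to_frame(trials, animal, "s1"))
            n_frames = int(round(session_duration(trials, config.task)
                                 * config.task.frame_rate))
            np_rng = _rng(np.random.SeedSequence(config.seed,
                                                 spawn_key=(gi, ai, 2)))
            neuropil = make_neuropil(n_frames, config.task.frame_rate, np_rng)
            cell_specs = (
                [("vip", ci, vip) for ci in range(profile.n_vip_cells)]
                + [("pyramidal", ci, pyr)
                   for ci in range(profile.n_pyramidal_cells)])
            gt["animals"][animal] = {
                "genotype": genotype, "agent": asdict(agent),
                "cells": {}}
            # cell streams keyed by (class, within-class index): growing one
            # class never perturbs the other
            for cls, ci, params in cell_specs:
                if params is None:
                    continue
                cell = f"{cls}_{ci:02d}"
                cell_rng = _rng(np.random.SeedSequence(
                    config.seed,
                    spawn_key=(gi, ai, 3, 0 if cls == "vip" else 1, ci)))
                traces[(animal, "fov0", cell)] = simulate_calcium(
                    params, trials, config.task, cell_rng, neuropil=neuropil,
                    animal=animal, fov="fov0", cell=cell)
                gt["animals"][animal]["cells"][cell] = asdict(params)
    trials_df = (pd.concat(trial_frames, ignore_index=True) if trial_frames
                 else pd.DataFrame(columns=_TRIAL_COLUMNS))
    licks_df = (pd.concat(lick_frames, ignore_index=True) if lick_frames
                else pd.DataFrame(columns=_LICK_COLUMNS))
    return Cohort(trials=trials_df, licks=licks_df, traces=traces,
                  ground_truth=gt, task=config.task, trial_records=records)


def _animal_params(profile: GenotypeProfile, rng: np.random.Generator):
    """Per-animal parameter draws: VIP error gain jitters lognormally around
    the template, and the behavioral distractor boost drops with the drawn
    gain (stronger error signals -> fewer errors)."""
    vip = profile.vip
    agent = profile.agent
    if profile.error_gain_cv > 0:
        sigma = math.sqrt(math.log(1.0 + profile.error_gain_cv ** 2))
        gain = vip.error_gain * float(rng.lognormal(-sigma ** 2 / 2.0, sigma))
        vip = NeuronParams(**{**asdict(vip), "error_gain": gain})
        boost = min(max(agent.distractor_fa_boost
                        - profile.boost_coupling * (gain - 1.0), 0.0), 1.0)
        agent = AgentParams(**{**asdict(agent), "distractor_fa_boost": boost})
    return agent, vip, profile.pyramidal


def save_cohort(cohort: Cohort, outdir: Union[str, Path]) -> None:
    """Write the on-disk dataset bundle: trials.csv, licks.csv, traces.h5,
    ground_truth.json."""
    import h5py
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.trials.to_csv(outdir / "trials.csv", index=False)
    cohort.licks.to_csv(outdir / "licks.csv", index=False)
    with h5py.File(outdir / "traces.h5", "w") as f:
        f.attrs["frame_rate"] = cohort.task.frame_rate
        for (animal, fov, cell), tr in sorted(cohort.traces.items()):
            g = f.create_group(f"{animal}/{fov}/{cell}")
            g.create_dataset("raw", data=tr.samples)
            g.create_dataset("neuropil", data=tr.neuropil_samples)
            g.attrs["frame_rate"] = tr.frame_rate
            g.attrs["cell_class"] = tr.cell_class
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(cohort.ground_truth, fh, indent=1, sort_keys=True)


def load_cohort(indir: Union[str, Path],
                task: Optional[TaskConfig] = None) -> Cohort:
    """Read a dataset bundle written by :func:`save_cohort`."""
    import h5py
    indir = Path(indir)
    trials = pd.read_csv(indir / "trials.csv")
    licks = pd.read_csv(indir / "licks.csv")
    gt_path = indir / "ground_truth.json"
    gt = json.loads(gt_path.read_text()) if gt_path.exists() else {}
    if task is None:
        cfg = gt.get("config", {}).get("task")
        task = TaskConfig(**{**cfg, "reward_window": tuple(cfg["reward_window"])}) \
            if cfg else TaskConfig()
    traces: dict[tuple[str, str, str], FluorescenceTrace] = {}
    h5_path = indir / "traces.h5"
    if h5_path.exists():
        with h5py.File(h5_path, "r") as f:
            for animal in f:
                for fov in f[animal]:
                    for cell in f[animal][fov]:
                        g = f[animal][fov][cell]
                        traces[(animal, fov, cell)] = FluorescenceTrace(
                            samples=g["raw"][...],
                            neuropil_samples=g["neuropil"][...],
                            frame_rate=float(g.attrs["frame_rate"]),
                            cell_class=str(g.attrs["cell_class"]),
                            animal=animal, fov=fov, cell=cell)
    return Cohort(trials=trials, licks=licks, traces=traces, ground_truth=gt,
                  task=task)
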