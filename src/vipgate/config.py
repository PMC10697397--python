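"""Configuration objects for the task, behavioral agents, neurons, and cohorts.

All times are in seconds relative to stimulus onset, intervals are half-open
``[start, stop)``, and frame indices are 0-based.  Every config validates its
invariants at construction time and raises :class:`ConfigError` on violation.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigError(msg)


def _finite(x: float, name: str) -> None:
    _require(math.isfinite(x), f"{name} must be finite, got {x!r}")


@dataclass(frozen=True)
class TaskConfig:
    """Timing and trial structure of the go/no-go discrimination task.

    Defaults follow the head-fixed protocol: a 3 s drifting-grating stimulus,
    a 3 s gray-screen intertrial interval, a 6.5 s time-out appended after
    incorrect responses, a water-reward window spanning the last second of the
    stimulus, and distractors on ~50% of trials of a distractor session.
    """

    stimulus_duration: float = 3.0
    iti_duration: float = 3.0
    timeout_duration: float = 6.5
    reward_window: tuple[float, float] = (2.0, 3.0)
    distractor_fraction: float = 0.5
    n_trials: int = 200
    frame_rate: float = 15.0
    lick_bin: float = 0.1

    def __post_init__(self) -> None:
        for name in ("stimulus_duration", "iti_duration", "timeout_duration",
                     "frame_rate", "lick_bin"):
            v = getattr(self, name)
            _finite(v, name)
            _require(v > 0, f"{name} must be > 0, got {v}")
        lo, hi = self.reward_window
        _require(0.0 <= lo < hi <= self.stimulus_duration,
                 "reward_window must be a nonempty interval inside "
                 f"[0, stimulus_duration), got {self.reward_window}")
        _require(0.0 <= self.distractor_fraction <= 1.0,
                 "distractor_fraction must be in [0, 1]")
        _require(self.n_trials >= 0, "n_trials must be >= 0")

    @property
    def correct_trial_duration(self) -> float:
        return self.stimulus_duration + self.iti_duration

    @property
    def error_trial_duration(self) -> float:
        return self.correct_trial_duration + self.timeout_duration

    @property
    def stimulus_frames(self) -> int:
        return int(round(self.stimulus_duration * self.frame_rate))


@dataclass(frozen=True)
class AgentParams:
    """Generative licking policy of a synthetic animal.

    The task defines no behavioral model; this parameterization is a stand-in
    that produces Hit/Miss/CR/FA mixtures with a distractor-induced false-alarm
    boost that decays exponentially across the session (``recovery_tau``, in
    trials), emulating recovery of expert performance under distraction.
    """

    p_hit: float = 0.9
    p_fa_base: float = 0.15
    distractor_fa_boost: float = 0.25
    recovery_tau: float = 30.0
    anticipatory_ramp_rate: float = 2.0  # licks / s^2
    lapse_rate: float = 0.02

    def __post_init__(self) -> None:
        for name in ("p_hit", "p_fa_base", "distractor_fa_boost", "lapse_rate"):
            v = getattr(self, name)
            _finite(v, name)
            _require(0.0 <= v <= 1.0, f"{name} must be in [0, 1], got {v}")
        _finite(self.recovery_tau, "recovery_tau")
        _require(self.recovery_tau > 0, "recovery_tau must be > 0")
        _finite(self.anticipatory_ramp_rate, "anticipatory_ramp_rate")
        _require(self.anticipatory_ramp_rate >= 0,
                 "anticipatory_ramp_rate must be >= 0")


@dataclass(frozen=True)
class NeuronParams:
    """Generative model of one cell's event train and fluorescence.

    Events are an inhomogeneous Poisson process whose rate is
    ``baseline_event_rate`` multiplied by ``stim_gain`` during stimulus frames,
    by an orientation tuning factor (pyramidal cells, von Mises concentration
    ``tuning_width``), and by ``error_gain`` during the stimulus and
    poststimulus windows of error trials (the VIP error signal).  Events are
    convolved with a difference-of-exponentials kernel (GCaMP7f-like defaults:
    50 ms rise, 700 ms decay) and mixed with a shared low-frequency neuropil
    signal plus white noise.
    """

    cell_class: str = "vip"
    baseline_event_rate: float = 0.1  # events / s
    stim_gain: float = 3.0
    tuning_width: Optional[float] = None  # von Mises kappa; None = untuned
    error_gain: float = 1.0
    kernel_rise: float = 0.05
    kernel_decay: float = 0.7
    noise_sd: float = 0.1
    neuropil_coupling: float = 0.7

    def __post_init__(self) -> None:
        _require(self.cell_class in ("pyramidal", "vip"),
                 f"cell_class must be 'pyramidal' or 'vip', got {self.cell_class!r}")
        for name in ("baseline_event_rate", "stim_gain", "error_gain", "noise_sd"):
            v = getattr(self, name)
            _finite(v, name)
            _require(v >= 0, f"{name} must be >= 0, got {v}")
        if self.tuning_width is not None:
            _finite(self.tuning_width, "tuning_width")
            _require(self.tuning_width >= 0, "tuning_width must be >= 0")
        _finite(self.kernel_rise, "kernel_rise")
        _finite(self.kernel_decay, "kernel_decay")
        _require(self.kernel_decay > self.kernel_rise > 0,
                 "need kernel_decay > kernel_rise > 0")
        _require(0.0 <= self.neuropil_coupling < 1.0,
                 "neuropil_coupling must be in [0, 1)")


@dataclass(frozen=True)
class GenotypeProfile:
    """Agent and neuron parameterization for one genotype.

    ``error_gain_cv`` draws per-animal VIP error gains from a lognormal around
    the template value, and ``boost_coupling`` lowers an animal's distractor
    false-alarm boost as its error gain rises, so that stronger error signals
    drive fewer mistakes (the behavioral coupling the error-modulation /
    %-incorrect correlation rests on).
    """

    agent: AgentParams
    vip: NeuronParams
    pyramidal: Optional[NeuronParams] = None
    n_vip_cells: int = 4
    n_pyramidal_cells: int = 0
    error_gain_cv: float = 0.2
    boost_coupling: float = 0.1

    def __post_init__(self) -> None:
        _require(self.vip.cell_class == "vip", "vip template must have cell_class 'vip'")
        if self.pyramidal is not None:
            _require(self.pyramidal.cell_class == "pyramidal",
                     "pyramidal template must have cell_class 'pyramidal'")
        _require(self.n_vip_cells >= 0 and self.n_pyramidal_cells >= 0,
                 "cell counts must be >= 0")
        _require(self.error_gain_cv >= 0, "error_gain_cv must be >= 0")


@dataclass(frozen=True)
class CohortConfig:
    """Full generative parameterization of a synthetic experiment.

    A fixed seed makes the emitted dataset byte-identical across runs; every
    animal and neuron draws from an independent, stably keyed random stream.
    """

    task: TaskConfig = field(default_factory=TaskConfig)
    genotype_profiles: dict[str, GenotypeProfile] = field(default_factory=dict)
    n_animals_per_genotype: int = 5
    n_sessions: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_animals_per_genotype >= 0,
                 "n_animals_per_genotype must be >= 0")
        _require(self.n_sessions >= 1, "n_sessions must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


def wt_like_profile() -> GenotypeProfile:
    """Control-like defaults: accurate licking policy that recovers quickly
    from distractors, and VIP cells whose rate doubles on error trials."""
    return GenotypeProfile(
        agent=AgentParams(p_hit=0.9, p_fa_base=0.12, distractor_fa_boost=0.25,
                          recovery_tau=25.0, lapse_rate=0.02),
        vip=NeuronParams(cell_class="vip", baseline_event_rate=0.1,
                         stim_gain=3.0, error_gain=2.0),
        pyramidal=NeuronParams(cell_class="pyramidal", baseline_event_rate=0.08,
                               stim_gain=4.0, tuning_width=1.5, error_gain=1.0,
                               noise_sd=0.1),
        n_pyramidal_cells=2,
    )


def ko_like_profile() -> GenotypeProfile:
    """Knockout-like defaults: elevated false-alarm rate, large and slowly
    recovering distractor boost, broadly tuned pyramidal cells, and VIP cells
    with no error-trial gain."""
    return GenotypeProfile(
        agent=AgentParams(p_hit=0.9, p_fa_base=0.3, distractor_fa_boost=0.5,
                          recovery_tau=80.0, lapse_rate=0.05),
        vip=NeuronParams(cell_class="vip", baseline_event_rate=0.1,
                         stim_gain=1.5, error_gain=1.0),
        pyramidal=NeuronParams(cell_class="pyramidal", baseline_event_rate=0.08,
                               stim_gain=4.0, tuning_width=0.4, error_gain=1.0,
                               noise_sd=0.1),
        n_pyramidal_cells=2,
    )


def default_cohort_config(seed: int = 0, n_animals_per_genotype: int = 5,
                          n_trials: int = 200) -> CohortConfig:
    """A WT-like vs KO-like two-genotype cohort under the default task."""
    return CohortConfig(
        task=TaskConfig(n_trials=n_trials),
        genotype_profiles={"WT": wt_like_profile(), "KO": ko_like_profile()},
        n_animals_per_genotype=n_animals_per_genotype,
        seed=seed,
    )
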