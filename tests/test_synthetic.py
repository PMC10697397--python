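"""Synthetic generator: deterministic policies, bookkeeping, rate conservation,
seeding contracts, and the forward-model identities downstream stages rely on."""
import json
from dataclasses import replace

import numpy as np
import pytest

import vipgate as v
from vipgate.synthetic import (event_rate_vector, make_neuropil,
                               save_cohort, session_duration)


def test_deterministic_policy_all_hits_and_crs(task):
    agent = v.AgentParams(p_hit=1.0, p_fa_base=0.0, distractor_fa_boost=0.0,
                          lapse_rate=0.0)
    trials = v.simulate_session(agent, task, 0)
    for t in trials:
        assert t.response_class == ("Hit" if t.stimulus == "preferred"
                                    else "CR")


def test_always_licking_makes_all_nonpreferred_fa(task):
    agent = v.AgentParams(p_hit=1.0, p_fa_base=1.0, distractor_fa_boost=0.0,
                          lapse_rate=0.0)
    trials = v.simulate_session(agent, task, 0)
    assert all(len(t.lick_times) >= 1 for t in trials)
    assert all(t.response_class == "FA" for t in trials
               if t.stimulus == "nonpreferred")


def test_hit_fraction_within_binomial_ci():
    task = v.TaskConfig(n_trials=10_000)
    agent = v.AgentParams(p_hit=0.9, p_fa_base=0.2, distractor_fa_boost=0.0,
                          lapse_rate=0.0)
    trials = v.simulate_session(agent, task, 123)
    pref = [t for t in trials if t.stimulus == "preferred"]
    hit_frac = np.mean([t.response_class == "Hit" for t in pref])
    sd = np.sqrt(0.9 * 0.1 / len(pref))
    assert abs(hit_frac - 0.9) < 3 * sd


def test_response_class_bookkeeping_exact(task):
    trials = v.simulate_session(v.AgentParams(), task, 7)
    counts = v.counts_from_responses(t.response_class for t in trials)
    n_pref = sum(t.stimulus == "preferred" for t in trials)
    assert counts["Hit"] + counts["Miss"] == n_pref
    assert counts["CR"] + counts["FA"] == task.n_trials - n_pref


def test_stored_classes_reproduce_under_reclassification(task):
    """classify_trial is pure: stored response classes round-trip exactly."""
    trials = v.simulate_session(v.AgentParams(), task, 21)
    for t in trials:
        assert v.classify_trial(t.stimulus, t.lick_times,
                                task.reward_window) == t.response_class


def test_trial_clock_accumulates_timeouts(task):
    trials = v.simulate_session(v.AgentParams(), task, 3)
    t = 0.0
    for tr in trials:
        assert tr.trial_start_s == pytest.approx(t)
        t += task.correct_trial_duration
        if tr.is_error:
            t += task.timeout_duration


def test_nonfinite_agent_rejected(task):
    with pytest.raises(v.ConfigError):
        v.AgentParams(p_hit=float("nan"))
    with pytest.raises(v.ConfigError):
        v.AgentParams(recovery_tau=-1.0)


def test_calcium_pure_neuropil_identity(task):
    """With no events and no noise the trace is exactly the coupled neuropil."""
    trials = v.passive_trials(10, task)
    neuron = v.NeuronParams(baseline_event_rate=0.0, noise_sd=0.0,
                            neuropil_coupling=0.6)
    tr = v.simulate_calcium(neuron, trials, task, 5)
    assert np.array_equal(tr.samples, 0.6 * tr.neuropil_samples)
    n_expected = int(round(session_duration(trials, task) * task.frame_rate))
    assert tr.n_frames == n_expected


def test_event_rate_conservation_with_unit_gains(task):
    """With all gains at 1 the empirical event rate matches baseline within
    3 SE over >= 10^4 s of simulated session."""
    rate = 0.5
    trials = v.passive_trials(2000, task)      # 12,000 s
    neuron = v.NeuronParams(baseline_event_rate=rate, stim_gain=1.0,
                            error_gain=1.0, noise_sd=0.0,
                            neuropil_coupling=0.0)
    rng = np.random.default_rng(9)
    n_frames = int(round(session_duration(trials, task) * task.frame_rate))
    rates = event_rate_vector(neuron, trials, task, n_frames)
    assert np.all(rates == rate)
    events = rng.poisson(rates / task.frame_rate)
    total_s = n_frames / task.frame_rate
    se = np.sqrt(rate / total_s)
    assert abs(events.sum() / total_s - rate) < 3 * se


def test_stim_gain_unity_means_evoked_equals_spontaneous(task):
    """With stim_gain = error_gain = 1 the stimulus-window mean activity
    matches the gray-screen mean within Monte-Carlo error."""
    trials = v.passive_trials(160, task)       # ~14,000 frames
    neuron = v.NeuronParams(baseline_event_rate=0.4, stim_gain=1.0,
                            error_gain=1.0, noise_sd=0.05,
                            neuropil_coupling=0.0)
    tr = v.simulate_calcium(neuron, trials, task, 13)
    zt = v.process_trace(tr, r=0.0)
    fr = task.frame_rate
    stim, gray = [], []
    for t in trials:
        s0 = int(round(t.trial_start_s * fr))
        s1 = s0 + int(round(task.stimulus_duration * fr))
        g1 = s1 + int(round(task.iti_duration * fr))
        if g1 <= zt.n_frames:
            stim.append((s0, s1))
            gray.append((s1, g1))
    ev, sp = v.evoked_and_spontaneous_means(zt, stim, gray)
    # both are mean-z rates; scale by their pooled spread for the comparison
    assert abs(ev - sp) / max(abs(ev), abs(sp), 1.0) < 0.15


def test_error_gain_shapes_rate_vector(task):
    trials = v.simulate_session(
        v.AgentParams(p_hit=0.5, p_fa_base=0.5, lapse_rate=0.0,
                      distractor_fa_boost=0.0), task, 17)
    neuron = v.NeuronParams(baseline_event_rate=0.2, stim_gain=2.0,
                            error_gain=3.0)
    n_frames = int(round(session_duration(trials, task) * task.frame_rate))
    rates = event_rate_vector(neuron, trials, task, n_frames)
    fr = task.frame_rate
    for t in trials:
        s0 = int(round(t.trial_start_s * fr))
        expected = 0.2 * 2.0 * (3.0 if t.is_error else 1.0)
        assert rates[s0] == pytest.approx(expected)
        post = s0 + int(round(task.stimulus_duration * fr))
        expected_post = 0.2 * (3.0 if t.is_error else 1.0)
        assert rates[post] == pytest.approx(expected_post)


def test_pyramidal_tuning_attenuates_nonpreferred(task):
    trials = v.passive_trials(4, task)
    neuron = v.NeuronParams(cell_class="pyramidal", baseline_event_rate=1.0,
                            stim_gain=2.0, tuning_width=1.0)
    n_frames = int(round(session_duration(trials, task) * task.frame_rate))
    rates = event_rate_vector(neuron, trials, task, n_frames)
    fr = task.frame_rate
    pref = rates[int(round(trials[0].trial_start_s * fr))]
    nonpref = rates[int(round(trials[1].trial_start_s * fr))]
    assert pref == pytest.approx(2.0)
    assert nonpref == pytest.approx(2.0 * np.exp(-2.0))  # orthogonal grating


def test_cohort_empty_is_valid(tmp_path):
    cfg = v.CohortConfig(task=v.TaskConfig(n_trials=10),
                         genotype_profiles={"WT": v.wt_like_profile()},
                         n_animals_per_genotype=0, seed=1)
    cohort = v.simulate_cohort(cfg)
    assert len(cohort.trials) == 0 and len(cohort.traces) == 0
    save_cohort(cohort, tmp_path)
    assert (tmp_path / "trials.csv").read_text().startswith("animal,")


def test_cohort_seed_determinism_byte_identical(tmp_path):
    cfg = v.CohortConfig(task=v.TaskConfig(n_trials=25),
                         genotype_profiles={"WT": v.wt_like_profile(),
                                            "KO": v.ko_like_profile()},
                         n_animals_per_genotype=1, seed=42)
    for name in ("a", "b"):
        save_cohort(v.simulate_cohort(cfg), tmp_path / name)
    for fname in ("trials.csv", "licks.csv", "ground_truth.json"):
        assert ((tmp_path / "a" / fname).read_bytes()
                == (tmp_path / "b" / fname).read_bytes()), fname
    # HDF5 containers embed no timestamps under h5py defaults; compare content
    a = v.load_cohort(tmp_path / "a")
    b = v.load_cohort(tmp_path / "b")
    assert sorted(a.traces) == sorted(b.traces)
    for key in a.traces:
        assert np.array_equal(a.traces[key].samples, b.traces[key].samples)


def test_cohort_roundtrip_io(small_cohort, tmp_path):
    save_cohort(small_cohort, tmp_path)
    loaded = v.load_cohort(tmp_path)
    assert len(loaded.trials) == len(small_cohort.trials)
    assert sorted(loaded.traces) == sorted(small_cohort.traces)
    key = sorted(loaded.traces)[0]
    assert np.array_equal(loaded.traces[key].samples,
                          small_cohort.traces[key].samples)
    assert loaded.task == small_cohort.task
    gt = json.loads((tmp_path / "ground_truth.json").read_text())
    assert set(gt["animals"]) == set(small_cohort.ground_truth["animals"])


def test_adding_neurons_never_perturbs_existing_streams():
    """Stable sub-seeding: growing a cohort leaves shared streams untouched."""
    base = v.wt_like_profile()
    bigger = replace(base, n_vip_cells=base.n_vip_cells + 2)
    cfg_a = v.CohortConfig(task=v.TaskConfig(n_trials=20),
                           genotype_profiles={"WT": base},
                           n_animals_per_genotype=1, seed=3)
    cfg_b = replace(cfg_a, genotype_profiles={"WT": bigger})
    a, b = v.simulate_cohort(cfg_a), v.simulate_cohort(cfg_b)
    assert a.trials.equals(b.trials)
    for key in a.traces:
        assert np.array_equal(a.traces[key].samples, b.traces[key].samples)
    assert len(b.traces) == len(a.traces) + 2


def test_neuropil_is_low_frequency():
    np_trace = make_neuropil(3000, 15.0, 2, sd=0.2)
    assert np_trace.std() == pytest.approx(0.2)
    spectrum = np.abs(np.fft.rfft(np_trace)) ** 2
    freqs = np.fft.rfftfreq(3000, d=1 / 15.0)
    low = spectrum[freqs < 0.5].sum()
    assert low / spectrum.sum() > 0.9
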