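"""Trial alignment, modulation indices, early/late splits, and the
modulation-vs-performance correlation."""
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import vipgate as v
from vipgate.synthetic import TrialRecord, session_duration


def _mk_trials(classes, task, distractor=None):
    out, t = [], 0.0
    for i, cls in enumerate(classes):
        stim = "preferred" if cls in ("Hit", "Miss") else "nonpreferred"
        dis = bool(distractor[i]) if distractor is not None else False
        out.append(TrialRecord(i, stim, dis, "none", np.array([]), cls, t))
        t += task.correct_trial_duration
        if cls in ("Miss", "FA"):
            t += task.timeout_duration
    return out


def test_align_constant_trace_gives_frame_rate(task):
    trials = _mk_trials(["Hit", "FA", "CR", "Miss"], task)
    n = int(round(session_duration(trials, task) * task.frame_rate))
    aligned = v.align_trials(np.ones(n), trials, task, frame_rate=15.0)
    tab = aligned.table
    assert np.allclose(tab["stimulus_auc"], 15.0)
    assert np.allclose(tab["poststimulus_auc"], 15.0)
    assert np.isnan(tab.loc[tab["response_class"] == "Hit",
                            "timeout_auc"]).all()
    assert np.allclose(tab.loc[tab["response_class"].isin(["FA", "Miss"]),
                               "timeout_auc"], 15.0)


def test_align_indicator_trace_isolates_stimulus_window(task):
    trials = _mk_trials(["Hit"], task)
    n = int(round(session_duration(trials, task) * task.frame_rate))
    z = np.zeros(n)
    z[:45] = 1.0
    aligned = v.align_trials(z, trials, task, frame_rate=15.0)
    assert aligned.table["stimulus_auc"].iloc[0] == pytest.approx(15.0)
    assert aligned.table["poststimulus_auc"].iloc[0] == 0.0


def test_align_drops_truncated_trials(task):
    trials = _mk_trials(["Hit", "CR"], task)
    n_one = int(round(task.correct_trial_duration * task.frame_rate))
    with pytest.warns(UserWarning, match="dropped 1 trial"):
        aligned = v.align_trials(np.ones(n_one), trials, task,
                                 frame_rate=15.0)
    assert len(aligned.table) == 1 and aligned.n_dropped == 1


def test_raster_identities(task):
    trials = _mk_trials(["Hit", "Hit", "FA"], task)
    n = int(round(session_duration(trials, task) * task.frame_rate))
    rng = np.random.default_rng(0)
    z = rng.normal(0, 1, n)
    rasters = v.response_type_raster(z, trials, task, frame_rate=15.0)
    assert set(rasters) == {"Hit", "FA"}        # empty classes omitted
    n_short = int(task.correct_trial_duration * task.frame_rate + 1e-9)
    # single-trial class: the row equals that trial's own trace
    fa_start = int(round(trials[2].trial_start_s * 15.0))
    n_long = int(task.error_trial_duration * 15.0 + 1e-9)
    assert np.allclose(rasters["FA"][:n_long],
                       z[fa_start:fa_start + n_long])
    # correct classes padded with NaN past the ITI
    assert np.isnan(rasters["Hit"][n_short:]).all()
    # count-weighted mean of class rasters equals the all-trial mean over the
    # common 0-6 s portion
    starts = [int(round(t.trial_start_s * 15.0)) for t in trials]
    all_mean = np.mean([z[s:s + n_short] for s in starts], axis=0)
    weighted = (2 * rasters["Hit"][:n_short] + 1 * rasters["FA"][:n_short]) / 3
    assert np.allclose(weighted, all_mean, atol=1e-12)


def _aligned_from_values(err_vals, cor_vals, distractor=None):
    n_err, n_cor = len(err_vals), len(cor_vals)
    tab = pd.DataFrame({
        "trial_index": range(n_err + n_cor),
        "response_class": ["FA"] * n_err + ["Hit"] * n_cor,
        "distractor": (distractor if distractor is not None
                       else [False] * (n_err + n_cor)),
        "stimulus": ["nonpreferred"] * n_err + ["preferred"] * n_cor,
        "stimulus_auc": list(err_vals) + list(cor_vals),
        "poststimulus_auc": list(err_vals) + list(cor_vals),
        "timeout_auc": np.nan})
    return v.TrialAlignedActivity(table=tab, windows_s={})


def test_error_modulation_trivial_ratios():
    eq = v.error_modulation_index(_aligned_from_values([2.0, 2.0], [2.0]))
    assert eq.value == pytest.approx(1.0) and eq.defined
    double = v.error_modulation_index(_aligned_from_values([4.0], [2.0]))
    assert double.value == pytest.approx(2.0)
    assert double.n_error_trials == 1 and double.n_correct_trials == 1


@given(c=st.floats(0.1, 50.0))
def test_error_modulation_scale_invariance(c):
    base = v.error_modulation_index(_aligned_from_values([3.0, 5.0],
                                                         [2.0, 2.0]))
    scaled = v.error_modulation_index(_aligned_from_values(
        [3.0 * c, 5.0 * c], [2.0 * c, 2.0 * c]))
    assert scaled.value == pytest.approx(base.value, rel=1e-9)


def test_error_modulation_undefined_cases():
    no_err = v.error_modulation_index(_aligned_from_values([], [1.0]))
    assert not no_err.defined and "empty" in no_err.reason
    bad_denom = v.error_modulation_index(_aligned_from_values([1.0], [-2.0]))
    assert not bad_denom.defined and "non-positive" in bad_denom.reason


def test_error_modulation_conditions_on_distractor():
    aligned = _aligned_from_values([4.0, 8.0], [2.0, 2.0],
                                   distractor=[True, False, True, False])
    with_d = v.error_modulation_index(aligned, distractor=True)
    without = v.error_modulation_index(aligned, distractor=False)
    assert with_d.value == pytest.approx(2.0)    # 4 / 2
    assert without.value == pytest.approx(4.0)   # 8 / 2


def test_visual_modulation_arithmetic():
    assert v.visual_modulation_index(1.0, 1.0).value == 0.0
    assert v.visual_modulation_index(1.0, 0.0).value == 1.0
    res = v.visual_modulation_index(1.1, 1.0)
    assert res.value == pytest.approx(0.1 / 2.1)
    assert not v.visual_modulation_index(0.0, 0.0).defined


@given(e=st.floats(0, 100), s=st.floats(0, 100))
def test_visual_modulation_bounded(e, s):
    res = v.visual_modulation_index(e, s)
    if res.defined:
        assert -1.0 <= res.value <= 1.0


def test_early_late_split_basic(task):
    trials = _mk_trials(["Hit"] * 200, task)
    split = v.early_late_split(trials, k=20)
    assert np.array_equal(split.first, np.arange(20))
    assert np.array_equal(split.last, np.arange(180, 200))
    assert not split.overlap


def test_early_late_split_overlap_flagged(task):
    trials = _mk_trials(["Hit"] * 30, task)
    split = v.early_late_split(trials, k=20)
    assert split.overlap


def test_early_late_split_distractor_conditioning(task):
    rng = np.random.default_rng(1)
    flags = rng.random(120) < 0.5
    trials = _mk_trials(["Hit"] * 120, task, distractor=flags)
    split = v.early_late_split(trials, k=20, distractor=True)
    eligible = np.flatnonzero(flags)             # brute-force filter oracle
    assert np.array_equal(split.first, eligible[:20])
    assert np.array_equal(split.last, eligible[-20:])
    assert flags[split.first[-1]] and flags[split.last[0]]


def test_modulation_vs_performance_extremes():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    res = v.modulation_vs_performance(x, 10 - 2 * x)
    assert res.r == pytest.approx(-1.0)
    assert res.slope == pytest.approx(-2.0)
    flat = v.modulation_vs_performance(np.ones(4), [1.0, 2, 3, 4])
    assert not flat.defined and np.isnan(flat.r)
    with pytest.raises(ValueError):
        v.modulation_vs_performance([1.0, 2.0], [1.0, 2.0])


def test_error_gain_recovery_single_cell(task):
    """A single high-SNR cell with error_gain = 2 recovers the gain within
    the parameter-recovery tolerance."""
    agent = v.AgentParams(p_hit=0.5, p_fa_base=0.5, distractor_fa_boost=0.0,
                          lapse_rate=0.0)
    vals = []
    for seed in range(4):
        trials = v.simulate_session(agent, task, seed)
        neuron = v.NeuronParams(baseline_event_rate=0.1, stim_gain=8.0,
                                error_gain=2.0, noise_sd=0.05)
        tr = v.simulate_calcium(neuron, trials, task, 100 + seed)
        zt = v.process_trace(tr)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            aligned = v.align_trials(zt, trials, task)
        vals.append(v.error_modulation_index(aligned, "stimulus").value)
    assert np.mean(vals) == pytest.approx(2.0, rel=0.15)
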