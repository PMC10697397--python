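"""Behavioral metrics: classification, d′ conventions, criteria, lick profiles."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import vipgate as v
from conftest import oracle_dprime

from vipgate.behavior import adapted_timeout


@pytest.mark.parametrize("stimulus,licks,expected", [
    ("preferred", [2.3], "Hit"),
    ("preferred", [], "Miss"),
    ("preferred", [0.5], "Miss"),          # lick outside reward window
    ("nonpreferred", [2.1, 2.8], "FA"),
    ("nonpreferred", [], "CR"),
    ("nonpreferred", [1.1], "CR"),         # reward-window convention
])
def test_classify_trial_reward_window(stimulus, licks, expected):
    assert v.classify_trial(stimulus, licks, (2.0, 3.0)) == expected


def test_classify_trial_whole_stimulus_switch():
    # with the whole-stimulus decision window an early lick counts
    assert v.classify_trial("nonpreferred", [1.1], (2.0, 3.0),
                            decision_window=(0.0, 3.0)) == "FA"


def test_classify_trial_unknown_stimulus():
    with pytest.raises(ValueError):
        v.classify_trial("oblique", [2.5], (2.0, 3.0))


def test_dprime_symmetric_chance_is_zero():
    res = v.dprime(50, 50, 50, 50)
    assert res.d_prime == pytest.approx(0.0, abs=1e-12)
    assert not res.clip_applied


def test_dprime_unit_quantiles():
    # hit fraction Phi(1), FA fraction Phi(-1) -> d' = 2
    res = v.dprime(841345, 1000000 - 841345, 841345, 1000000 - 841345)
    assert res.d_prime == pytest.approx(2.0, abs=1e-3)


def test_dprime_wt_session4_mix():
    """The learned-session response mix (41.6% Hit, 8.4% Miss, 27.5% CR,
    22.5% FA of all trials) gives d' ~ 1.088 under within-type fractions."""
    res = v.dprime(416, 84, 275, 225)
    assert res.d_prime == pytest.approx(1.088, abs=1e-3)
    assert res.d_prime == pytest.approx(oracle_dprime(416, 84, 275, 225),
                                        abs=1e-6)


def test_dprime_clipping_keeps_finite():
    res = v.dprime(10, 0, 10, 0)
    assert np.isfinite(res.d_prime) and res.clip_applied
    # log-linear rule: both fractions 1/(2*10) off the boundary
    expected = oracle_dprime(10, 0, 10, 0)
    assert res.d_prime == pytest.approx(expected, abs=1e-6)


def test_dprime_requires_both_trial_types():
    with pytest.raises(ValueError):
        v.dprime(5, 5, 0, 0)
    with pytest.raises(ValueError):
        v.dprime(0, 0, 5, 5)


@given(h=st.integers(1, 99), f=st.integers(1, 99))
def test_dprime_antisymmetry(h, f):
    """Swapping hit and FA fractions flips the sign of d'."""
    a = v.dprime(h, 100 - h, 100 - f, f).d_prime
    b = v.dprime(f, 100 - f, 100 - h, h).d_prime
    assert a == pytest.approx(-b, abs=1e-12)


def test_dprime_monotone_in_fractions():
    grid = np.arange(1, 100)
    col = np.array([v.dprime(h, 100 - h, 50, 50).d_prime for h in grid])
    row = np.array([v.dprime(50, 50, 100 - f, f).d_prime for f in grid])
    assert np.all(np.diff(col) > 0)      # increasing in hit fraction
    assert np.all(np.diff(row) < 0)      # decreasing in FA fraction


def test_human_dprime_symmetry_and_example():
    assert v.human_dprime(25, 25, 0).d_prime == pytest.approx(0.0, abs=1e-12)
    # 40 Right, 5 Wrong, 5 NR of 50: Phi^-1(0.8) - Phi^-1(0.1)
    res = v.human_dprime(40, 5, 5)
    assert res.d_prime == pytest.approx(2.123, abs=1e-3)


def test_human_dprime_counts_nr_in_denominator():
    with_nr = v.human_dprime(20, 10, 20).d_prime
    without = v.human_dprime(20, 10, 0).d_prime
    assert with_nr != pytest.approx(without)
    with pytest.raises(ValueError):
        v.human_dprime(0, 0, 0)


def _session(responses):
    return pd.DataFrame({"response_class": responses,
                         "trial_index": range(len(responses))})


def test_session_dprime_uses_trailing_window():
    chance = ["Hit", "FA", "Miss", "CR"] * 63        # 252 trials at chance
    perfect = ["Hit", "CR"] * 50                     # last 100 perfect
    res = v.session_dprime(_session(chance + perfect))
    direct = v.dprime(50, 0, 50, 0)
    assert res.d_prime == direct.d_prime
    assert not res.short_session


def test_session_dprime_short_session_flagged():
    res = v.session_dprime(_session(["Hit", "CR"] * 40))
    assert res.short_session and res.n_trials == 80


def test_session_dprime_matches_manual_slice():
    rng = np.random.default_rng(5)
    responses = list(rng.choice(["Hit", "Miss", "CR", "FA"], size=350))
    res = v.session_dprime(_session(responses))
    c = v.counts_from_responses(responses[-100:])
    manual = v.dprime(c["Hit"], c["Miss"], c["CR"], c["FA"])
    assert res.d_prime == manual.d_prime


@pytest.mark.parametrize("seq,consecutive,expected", [
    ([1.0, 1.5, 2.1], 1, 3),
    ([2.1, 1.0, 2.2, 2.3], 2, 3),
    ([1.0, 2.0, 1.9], 1, None),            # threshold is strict
])
def test_sessions_to_criterion_examples(seq, consecutive, expected):
    assert v.sessions_to_criterion(seq, 2.0, consecutive) == expected


def test_sessions_to_criterion_matches_scan_oracle():
    rng = np.random.default_rng(0)
    for _ in range(1000):
        seq = rng.normal(2.0, 1.0, size=rng.integers(1, 12))
        k = int(rng.integers(1, 4))
        got = v.sessions_to_criterion(seq, 2.0, k)
        expected = None
        for i in range(len(seq) - k + 1):      # exhaustive scan oracle
            if all(x > 2.0 for x in seq[i:i + k]):
                expected = i + 1
                break
        assert got == expected


def test_binned_dprime_perfect_bins():
    responses = ["Hit", "CR"] * 10                     # 20 perfect trials
    res = v.binned_dprime(_session(responses), bin_size=10)
    assert len(res.d_primes) == 2
    assert np.allclose(res.d_primes, res.d_primes[0])  # both at clip maximum
    assert res.bins_to_criterion == 1
    assert res.bins_to_two_consecutive == 1


def test_binned_dprime_chance_never_reaches():
    responses = ["Hit", "FA"] * 30
    res = v.binned_dprime(_session(responses), bin_size=10)
    assert np.allclose(res.d_primes, 0.0)
    assert res.bins_to_criterion is None


def test_binned_dprime_missing_type_is_undefined_and_skipped():
    responses = ["Hit"] * 10 + ["Hit", "CR"] * 5
    res = v.binned_dprime(_session(responses), bin_size=10)
    assert np.isnan(res.d_primes[0]) and np.isfinite(res.d_primes[1])
    assert res.bins_to_criterion == 2


def test_binned_dprime_rejects_tiny_bins():
    with pytest.raises(ValueError):
        v.binned_dprime(_session(["Hit", "CR"]), bin_size=1)


def _lick_tables(lick_lists):
    trials = pd.DataFrame({
        "trial_index": range(len(lick_lists)),
        "stimulus": ["preferred" if i % 2 == 0 else "nonpreferred"
                     for i in range(len(lick_lists))]})
    licks = pd.DataFrame([(i, t) for i, lt in enumerate(lick_lists)
                          for t in lt],
                         columns=["trial_index", "lick_time_s"])
    return trials, licks


def test_lick_profile_extremes():
    trials, licks = _lick_tables([[] for _ in range(10)])
    prof = v.lick_probability_profile(trials, licks)
    assert (prof.to_numpy() == 0).all()
    dense = [list(np.arange(0.05, 3.0, 0.1)) for _ in range(10)]
    trials, licks = _lick_tables(dense)
    prof = v.lick_probability_profile(trials, licks)
    assert (prof.to_numpy() == 1).all()


def test_lick_profile_poisson_rate_closed_form():
    """Poisson licking at rate r -> per-bin lick probability 1 - exp(-r*dt)."""
    rng = np.random.default_rng(3)
    r, dt, n = 4.0, 0.1, 4000
    lists = [list(rng.uniform(0, 3.0, size=rng.poisson(r * 3.0)))
             for _ in range(n)]
    trials, licks = _lick_tables(lists)
    prof = v.lick_probability_profile(trials, licks, bin=dt)
    expected = 1 - np.exp(-r * dt)
    assert np.abs(prof.to_numpy().mean() - expected) < 0.01


def test_adapted_timeout_rules():
    assert adapted_timeout(5, 0.5, 30, 5) == 6.5      # before session 6
    assert adapted_timeout(6, 1.5, 30, 5) == 6.5      # performing fine
    assert adapted_timeout(6, 0.5, 30, 5) == 4.5      # misses dominate
    assert adapted_timeout(6, 0.5, 5, 30) == 9.5      # FAs dominate
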