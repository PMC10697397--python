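"""Behavioral metrics: trial classification, d′, learning criteria, lick profiles.

The discriminability index is the signal-detection statistic

    d' = Phi^{-1}(hit fraction) - Phi^{-1}(false-alarm fraction)

with within-trial-type fractions by default (Hits/(Hits+Misses) and
FAs/(FAs+CRs)).  Fractions of exactly 0 or 1 are replaced by the log-linear
correction 1/(2N) and 1 - 1/(2N) before taking the normal quantile, so d′ is
always finite.  Daily performance uses the trailing 100 trials of a session;
within-session recovery uses bins of 10 trials.  The human forced-choice
variant normalizes Right and Wrong counts by all trials including no-responses.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "RESPONSE_CLASSES", "DPrimeResult", "BinnedDPrime",
    "classify_trial", "dprime", "human_dprime", "session_dprime",
    "sessions_to_criterion", "binned_dprime", "lick_probability_profile",
    "counts_from_responses",
]

RESPONSE_CLASSES = ("Hit", "Miss", "CR", "FA")
_ERROR_CLASSES = ("Miss", "FA")


@dataclass(frozen=True)
class DPrimeResult:
    d_prime: float
    n_hit: int
    n_miss: int
    n_cr: int
    n_fa: int
    clip_applied: bool
    short_session: bool = False

    @property
    def n_trials(self) -> int:
        return self.n_hit + self.n_miss + self.n_cr + self.n_fa


def classify_trial(stimulus: str, lick_times: Sequence[float],
                   reward_window: tuple[float, float] = (2.0, 3.0),
                   decision_window: Optional[tuple[float, float]] = None) -> str:
    """Classify one trial as Hit / Miss / CR / FA.

    A trial counts as licked when any lick time falls inside the decision
    window (the reward window by default; pass ``decision_window`` to use the
    whole stimulus period instead).  Preferred-stimulus trials map lick/no-lick
    to Hit/Miss and nonpreferred trials to FA/CR.
    """
    if stimulus not in ("preferred", "nonpreferred"):
        raise ValueError(f"unknown stimulus class: {stimulus!r}")
    lo, hi = decision_window if decision_window is not None else reward_window
    licked = any(lo <= t < hi for t in np.asarray(lick_times, dtype=float))
    if stimulus == "preferred":
        return "Hit" if licked else "Miss"
    return "FA" if licked else "CR"


def counts_from_responses(responses: Iterable[str]) -> dict[str, int]:
    counts = {c: 0 for c in RESPONSE_CLASSES}
    for r in responses:
        if r not in counts:
            raise ValueError(f"unknown response class: {r!r}")
        counts[r] += 1
    return counts


def _clipped_fraction(k: int, n: int, clip: str) -> float:
    """Fraction k/n with 0/1 replaced per the clip rule before the quantile."""
    frac = k / n
    if clip == "loglinear":
        if frac <= 0.0:
            frac = 1.0 / (2 * n)
        elif frac >= 1.0:
            frac = 1.0 - 1.0 / (2 * n)
    elif clip is not None and clip != "none":
        raise ValueError(f"unknown clip rule: {clip!r}")
    return frac


def dprime(n_hit: int, n_miss: int, n_cr: int, n_fa: int,
           clip: str = "loglinear", fractions: str = "within_type") -> DPrimeResult:
    """d′ from response-class counts.

    ``fractions='within_type'`` (default) uses Hits/(Hits+Misses) and
    FAs/(FAs+CRs); ``'all_trials'`` divides both counts by the total trial
    count instead.  With the default log-linear clip, degenerate fractions are
    pulled off 0/1 so the result is always finite.
    """
    n_go = n_hit + n_miss
    n_nogo = n_cr + n_fa
    if n_go < 1:
        raise ValueError("d' requires at least one preferred (go) trial")
    if n_nogo < 1:
        raise ValueError("d' requires at least one nonpreferred (no-go) trial")
    if fractions == "within_type":
        denom_hit, denom_fa = n_go, n_nogo
    elif fractions == "all_trials":
        denom_hit = denom_fa = n_go + n_nogo
    else:
        raise ValueError(f"unknown fractions convention: {fractions!r}")
    raw_hit, raw_fa = n_hit / denom_hit, n_fa / denom_fa
    hit_frac = _clipped_fraction(n_hit, denom_hit, clip)
    fa_frac = _clipped_fraction(n_fa, denom_fa, clip)
    d = float(norm.ppf(hit_frac) - norm.ppf(fa_frac))
    return DPrimeResult(d_prime=d, n_hit=n_hit, n_miss=n_miss, n_cr=n_cr,
                        n_fa=n_fa,
                        clip_applied=(hit_frac != raw_hit or fa_frac != raw_fa))


def human_dprime(n_right: int, n_wrong: int, n_nr: int,
                 clip: str = "loglinear") -> DPrimeResult:
    """Modified d′ for the forced two-choice task: Phi^{-1}(Rights/total) -
    Phi^{-1}(Wrongs/total), where total includes no-response (NR) trials.

    Counts are reported through the DPrimeResult fields with Right -> n_hit,
    Wrong -> n_fa, and NR split out of both via n_miss (n_cr is unused).
    """
    total = n_right + n_wrong + n_nr
    if total < 1:
        raise ValueError("human d' requires at least one trial")
    raw_r, raw_w = n_right / total, n_wrong / total
    r_frac = _clipped_fraction(n_right, total, clip)
    w_frac = _clipped_fraction(n_wrong, total, clip)
    d = float(norm.ppf(r_frac) - norm.ppf(w_frac))
    return DPrimeResult(d_prime=d, n_hit=n_right, n_miss=n_nr, n_cr=0,
                        n_fa=n_wrong,
                        clip_applied=(r_frac != raw_r or w_frac != raw_w))


def _responses_of(trials) -> list[str]:
    """Accept a DataFrame with a response_class column, a sequence of
    TrialRecord-like objects, or a plain sequence of class labels."""
    if isinstance(trials, pd.DataFrame):
        return list(trials["response_class"])
    out = []
    for t in trials:
        out.append(t if isinstance(t, str) else t.response_class)
    return out


def session_dprime(trials, last_n: int = 100, clip: str = "loglinear",
                   fractions: str = "within_type") -> DPrimeResult:
    """d′ over the trailing ``last_n`` trials of a session (daily performance).

    Sessions shorter than ``last_n`` use all their trials and are flagged
    ``short_session``.
    """
    responses = _responses_of(trials)
    short = len(responses) < last_n
    window = responses if short else responses[-last_n:]
    c = counts_from_responses(window)
    res = dprime(c["Hit"], c["Miss"], c["CR"], c["FA"], clip=clip,
                 fractions=fractions)
    return DPrimeResult(**{**res.__dict__, "short_session": short})


def sessions_to_criterion(dprime_by_session: Sequence[float],
                          threshold: float = 2.0,
                          consecutive: int = 1) -> Optional[int]:
    """1-based index of the first session starting a run of ``consecutive``
    sessions with d′ > threshold; None if the criterion is never reached.

    NaN entries (e.g. undefined bins) never satisfy the criterion.
    """
    vals = list(dprime_by_session)
    if not vals:
        raise ValueError("empty d' sequence")
    if consecutive < 1:
        raise ValueError("consecutive must be >= 1")
    run = 0
    for i, v in enumerate(vals):
        if not math.isnan(v) and v > threshold:
            run += 1
            if run == consecutive:
                return i - consecutive + 2  # 1-based start of the run
        else:
            run = 0
    return None


@dataclass(frozen=True)
class BinnedDPrime:
    d_primes: np.ndarray          # one entry per complete bin; NaN = undefined
    results: list[Optional[DPrimeResult]]
    bin_size: int
    bins_to_criterion: Optional[int]
    bins_to_two_consecutive: Optional[int]


def binned_dprime(trials, bin_size: int = 10, threshold: float = 2.0,
                  clip: str = "loglinear") -> BinnedDPrime:
    """d′ per consecutive bin of ``bin_size`` trials, in presentation order.

    Bins missing one trial type yield NaN and are skipped (not imputed) by the
    criterion search.  Also reports the 1-based index of the first bin with
    d′ > threshold and of the first bin starting two consecutive such bins,
    the within-session recovery statistics of the distractor task.
    """
    if bin_size < 2:
        raise ValueError("bin_size must be >= 2")
    responses = _responses_of(trials)
    n_bins = len(responses) // bin_size
    d_primes = np.full(n_bins, np.nan)
    results: list[Optional[DPrimeResult]] = [None] * n_bins
    for b in range(n_bins):
        c = counts_from_responses(responses[b * bin_size:(b + 1) * bin_size])
        if c["Hit"] + c["Miss"] == 0 or c["CR"] + c["FA"] == 0:
            continue  # undefined marker stays NaN
        res = dprime(c["Hit"], c["Miss"], c["CR"], c["FA"], clip=clip)
        results[b] = res
        d_primes[b] = res.d_prime
    if n_bins:
        to_crit = sessions_to_criterion(d_primes, threshold, consecutive=1)
        to_two = sessions_to_criterion(d_primes, threshold, consecutive=2)
    else:
        to_crit = to_two = None
    return BinnedDPrime(d_primes=d_primes, results=results, bin_size=bin_size,
                        bins_to_criterion=to_crit,
                        bins_to_two_consecutive=to_two)


def lick_probability_profile(trials: pd.DataFrame, licks: pd.DataFrame,
                             bin: float = 0.1,
                             window: tuple[float, float] = (0.0, 3.0),
                             group_by: str = "stimulus") -> pd.DataFrame:
    """Per time-bin probability of licking, by trial group.

    Entry (group, bin) is the fraction of that group's trials with at least
    one lick in the half-open bin.  Groups with no trials yield NaN rows.
    Returns a DataFrame indexed by group with bin start times as columns.
    """
    lo, hi = window
    edges = np.arange(lo, hi + bin / 2, bin)
    n_bins = len(edges) - 1
    groups = sorted(trials[group_by].unique())
    out = pd.DataFrame(np.nan, index=groups, columns=edges[:-1].round(6))
    lick_map = {k: g.to_numpy()
                for k, g in licks.groupby("trial_index")["lick_time_s"]}
    for g in groups:
        idx = trials.loc[trials[group_by] == g, "trial_index"].to_numpy()
        if len(idx) == 0:
            continue
        hits = np.zeros(n_bins)
        for ti in idx:
            lt = lick_map.get(ti, np.array([]))
            counts, _ = np.histogram(lt, bins=edges)
            hits += counts > 0
        out.loc[g] = hits / len(idx)
    return out


def adapted_timeout(session_index: int, prior_dprime: float, n_miss: int,
                    n_fa: int, base_timeout: float = 6.5,
                    dprime_threshold: float = 1.0) -> float:
    """Optional punish-time adjustment applied from session 6 onward: if the
    animal has not reached d′ >= threshold, the time-out shortens to 4.5 s when
    misses dominate the errors and lengthens to 9.5 s when false alarms do.
    Affects task timing only, never the metrics."""
    if session_index < 6 or prior_dprime >= dprime_threshold:
        return base_timeout
    if n_miss > n_fa:
        return 4.5
    if n_fa > n_miss:
        return 9.5
    return base_timeout
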