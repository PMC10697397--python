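"""Shared fixtures and independent oracles for the test suite."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import vipgate as v

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("suite")


def acklam_norminv(p: float) -> float:
    """Inverse normal CDF via Acklam's rational approximation (relative error
    ~1.15e-9) — an oracle independent of scipy's quantile implementation."""
    a = (-3.969683028665376e+01, 2.209460984245205e+02,
         -2.759285104469687e+02, 1.383577518672690e+02,
         -3.066479806614716e+01, 2.506628277459239e+00)
    b = (-5.447609879822406e+01, 1.615858368580409e+02,
         -1.556989798598866e+02, 6.680131188771972e+01,
         -1.328068155288572e+01)
    c = (-7.784894002430293e-03, -3.223964580411365e-01,
         -2.400758277161838e+00, -2.549732539343734e+00,
         4.374664141464968e+00, 2.938163982698783e+00)
    d = (7.784695709041462e-03, 3.224671290700398e-01,
         2.445134137142996e+00, 3.754408661907416e+00)
    p_low, p_high = 0.02425, 1 - 0.02425
    if not 0.0 < p < 1.0:
        raise ValueError("p must be in (0, 1)")
    if p < p_low:
        q = np.sqrt(-2 * np.log(p))
        return (((((c[0] * q + c[1]) * q + c[2]) * q + c[3]) * q + c[4]) * q
                + c[5]) / ((((d[0] * q + d[1]) * q + d[2]) * q + d[3]) * q + 1)
    if p > p_high:
        q = np.sqrt(-2 * np.log(1 - p))
        return -(((((c[0] * q + c[1]) * q + c[2]) * q + c[3]) * q + c[4]) * q
                 + c[5]) / ((((d[0] * q + d[1]) * q + d[2]) * q + d[3]) * q + 1)
    q = p - 0.5
    r = q * q
    return (((((a[0] * r + a[1]) * r + a[2]) * r + a[3]) * r + a[4]) * r
            + a[5]) * q / (((((b[0] * r + b[1]) * r + b[2]) * r + b[3]) * r
                            + b[4]) * r + 1)


def oracle_dprime(n_hit: int, n_miss: int, n_cr: int, n_fa: int) -> float:
    """Brute-force d′ with log-linear clipping through the Acklam quantile."""
    def frac(k, n):
        f = k / n
        if f == 0:
            f = 1 / (2 * n)
        elif f == 1:
            f = 1 - 1 / (2 * n)
        return f
    return (acklam_norminv(frac(n_hit, n_hit + n_miss))
            - acklam_norminv(frac(n_fa, n_fa + n_cr)))


@pytest.fixture(scope="session")
def task():
    return v.TaskConfig(n_trials=200)


@pytest.fixture(scope="session")
def small_cohort():
    """Two animals per genotype, short sessions, few cells — smoke-scale."""
    cfg = v.CohortConfig(
        task=v.TaskConfig(n_trials=40),
        genotype_profiles={"WT": v.wt_like_profile(), "KO": v.ko_like_profile()},
        n_animals_per_genotype=2, seed=11)
    return v.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def passive_session(task):
    """A 50-trial passive-viewing session and its stimulus indicator."""
    trials = v.passive_trials(50, task)
    n_frames = int(round(50 * task.correct_trial_duration * task.frame_rate))
    indicator = v.trials_indicator(trials, task, n_frames)
    return trials, indicator, n_frames
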