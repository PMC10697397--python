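"""Trial-aligned activity and modulation indices.

Per-trial activity is the AUC rate of the Z-score trace in three windows
relative to stimulus onset: stimulus [0, 3) s, poststimulus/ITI [3, 6) s, and
time-out [6, 12.5) s (error trials only).  The error modulation index is the
ratio of mean activity on error trials (FAs and Misses) to mean activity on
correct trials (Hits and CRs) within a window; the visual modulation index is
the normalized evoked-vs-spontaneous difference (E - S)/(E + S).  Undefined
indices (empty group, non-positive denominator) propagate as flagged missing
values rather than being imputed.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import linregress

from .config import TaskConfig
from .synthetic import TrialRecord
from .traces import ZTrace, auc_rate

__all__ = [
    "TrialAlignedActivity", "ModulationIndex", "EarlyLateSplit",
    "CorrelationResult", "align_trials", "response_type_raster",
    "error_modulation_index", "visual_modulation_index", "early_late_split",
    "modulation_vs_performance",
]

_ERROR = ("FA", "Miss")
_CORRECT = ("Hit", "CR")


@dataclass(frozen=True)
class TrialAlignedActivity:
    """Per-trial, per-window AUC-rate activity of one cell.

    ``table`` has one row per aligned trial with columns trial_index,
    response_class, distractor, stimulus, and the window activities
    stimulus_auc, poststimulus_auc, timeout_auc (NaN on correct trials).
    """
    table: pd.DataFrame
    windows_s: dict
    n_dropped: int = 0


@dataclass(frozen=True)
class ModulationIndex:
    value: float
    kind: str                    # 'visual' | 'error'
    window: str                  # 'stimulus' | 'poststimulus' | 'timeout'
    n_correct_trials: int = 0
    n_error_trials: int = 0
    reason: Optional[str] = None  # set when the index is undefined

    @property
    def defined(self) -> bool:
        return self.reason is None


@dataclass(frozen=True)
class EarlyLateSplit:
    first: np.ndarray
    last: np.ndarray
    overlap: bool


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    slope: float
    intercept: float
    n: int
    defined: bool


def align_trials(z: Union[ZTrace, np.ndarray], trials: Sequence[TrialRecord],
                 task: TaskConfig,
                 frame_rate: Optional[float] = None) -> TrialAlignedActivity:
    """AUC-rate activity per trial in the stimulus, poststimulus, and (error
    trials only) time-out windows.  Trials whose windows extend past the end
    of the trace are dropped with a warning."""
    if isinstance(z, ZTrace):
        arr, fr = z.z, z.frame_rate
    else:
        arr = np.asarray(z, dtype=float)
        if frame_rate is None:
            raise ValueError("frame_rate required for a bare array")
        fr = frame_rate
    stim, iti, timeout = (task.stimulus_duration, task.iti_duration,
                          task.timeout_duration)
    windows_s = {"stimulus": (0.0, stim), "poststimulus": (stim, stim + iti),
                 "timeout": (stim + iti, stim + iti + timeout)}
    rows, dropped = [], 0
    for tr in trials:
        start = int(round(tr.trial_start_s * fr))
        row = {"trial_index": tr.trial_index,
               "response_class": tr.response_class,
               "distractor": tr.distractor, "stimulus": tr.stimulus}
        ok = True
        for name, (w0, w1) in windows_s.items():
            if name == "timeout" and not tr.is_error:
                row["timeout_auc"] = np.nan
                continue
            # floor keeps a trailing error trial's half-frame time-out inside
            # the trace instead of dropping the trial
            f0 = start + int(w0 * fr + 1e-9)
            f1 = start + int(w1 * fr + 1e-9)
            if f1 > len(arr):
                ok = False
                break
            row[f"{name}_auc"] = auc_rate(arr, (f0, f1), fr)
        if ok:
            rows.append(row)
        else:
            dropped += 1
    if dropped:
        warnings.warn(f"dropped {dropped} trial(s) extending past trace end")
    cols = ["trial_index", "response_class", "distractor", "stimulus",
            "stimulus_auc", "poststimulus_auc", "timeout_auc"]
    table = pd.DataFrame(rows, columns=cols)
    return TrialAlignedActivity(table=table, windows_s=windows_s,
                                n_dropped=dropped)


def response_type_raster(z: Union[ZTrace, np.ndarray],
                         trials: Sequence[TrialRecord], task: TaskConfig,
                         frame_rate: Optional[float] = None
                         ) -> dict[str, np.ndarray]:
    """Mean Z-score time course per response class on a 0-12.5 s time base.

    Each row averages the aligned trials of one class; correct classes, which
    have no time-out, are padded with NaN past 6 s.  Classes without trials
    are omitted.
    """
    if isinstance(z, ZTrace):
        arr, fr = z.z, z.frame_rate
    else:
        arr = np.asarray(z, dtype=float)
        if frame_rate is None:
            raise ValueError("frame_rate required for a bare array")
        fr = frame_rate
    n_short = int(task.correct_trial_duration * fr + 1e-9)
    n_long = int(task.error_trial_duration * fr + 1e-9)
    out: dict[str, np.ndarray] = {}
    for cls in ("Hit", "Miss", "CR", "FA"):
        segs = []
        n_keep = n_long if cls in _ERROR else n_short
        for tr in trials:
            if tr.response_class != cls:
                continue
            start = int(round(tr.trial_start_s * fr))
            if start + n_keep <= len(arr):
                segs.append(arr[start:start + n_keep])
        if not segs:
            continue
        mean = np.vstack(segs).mean(axis=0)
        row = np.full(n_long, np.nan)
        row[:len(mean)] = mean
        out[cls] = row
    return out


def error_modulation_index(aligned: TrialAlignedActivity,
                           window: str = "stimulus",
                           distractor: Optional[bool] = None,
                           trial_indices: Optional[Sequence[int]] = None
                           ) -> ModulationIndex:
    """Mean activity on error trials divided by mean activity on correct
    trials, within one window; optionally restricted to distractor-present or
    -absent trials and/or to an explicit trial-index subset (first/last-20
    comparisons)."""
    col = f"{window}_auc"
    if col not in aligned.table.columns:
        raise ValueError(f"unknown window {window!r}")
    tab = aligned.table
    if distractor is not None:
        tab = tab[tab["distractor"] == distractor]
    if trial_indices is not None:
        tab = tab[tab["trial_index"].isin(np.asarray(trial_indices))]
    err = tab.loc[tab["response_class"].isin(_ERROR), col].dropna()
    cor = tab.loc[tab["response_class"].isin(_CORRECT), col].dropna()
    if len(err) == 0 or len(cor) == 0:
        return ModulationIndex(np.nan, "error", window, len(cor), len(err),
                               reason="empty trial group")
    denom = float(cor.mean())
    if denom <= 0:
        return ModulationIndex(np.nan, "error", window, len(cor), len(err),
                               reason="non-positive correct-trial mean")
    return ModulationIndex(float(err.mean()) / denom, "error", window,
                           len(cor), len(err))


def visual_modulation_index(evoked: float, spontaneous: float
                            ) -> ModulationIndex:
    """Normalized visual modulation (E - S)/(E + S): the signed change in
    activity under visual stimulation relative to gray screen.  Bounded in
    [-1, 1] for non-negative inputs; a cell is positively modulated when the
    value exceeds 0."""
    total = evoked + spontaneous
    if total == 0:
        return ModulationIndex(np.nan, "visual", "stimulus",
                               reason="evoked + spontaneous is zero")
    return ModulationIndex((evoked - spontaneous) / total, "visual",
                           "stimulus")


def early_late_split(trials: Union[Sequence[TrialRecord], pd.DataFrame],
                     k: int = 20,
                     distractor: Optional[bool] = None) -> EarlyLateSplit:
    """Trial indices of the first k and last k trials, after restricting to
    the requested distractor condition.  Fewer than 2k eligible trials flag an
    overlap between the two subsets."""
    if isinstance(trials, pd.DataFrame):
        idx = trials["trial_index"].to_numpy()
        dis = trials["distractor"].to_numpy()
    else:
        idx = np.array([t.trial_index for t in trials])
        dis = np.array([t.distractor for t in trials])
    if distractor is not None:
        idx = idx[dis == distractor]
    if len(idx) == 0:
        raise ValueError("no eligible trials")
    k_eff = min(k, len(idx))
    return EarlyLateSplit(first=idx[:k_eff], last=idx[-k_eff:],
                          overlap=len(idx) < 2 * k)


def modulation_vs_performance(modulation: Sequence[float],
                              pct_incorrect: Sequence[float]
                              ) -> CorrelationResult:
    """Pearson correlation and least-squares line between per-animal mean
    error-modulation index and percentage of incorrect responses."""
    x = np.asarray(modulation, dtype=float)
    y = np.asarray(pct_incorrect, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need at least 3 animals with defined values")
    if x.std() == 0 or y.std() == 0:
        return CorrelationResult(np.nan, np.nan, np.nan, len(x), False)
    fit = linregress(x, y)
    return CorrelationResult(float(fit.rvalue), float(fit.slope),
                             float(fit.intercept), len(x), True)
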