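"""Single-neuron discrimination via leave-one-out decision variables and ROC.

Each Hit or CR trial's PSTH (the trial's Z-score time course over the stimulus
window) is scored with a decision variable: the dot product with the mean Hit
PSTH minus the dot product with the mean CR PSTH, where the trial's own class
template excludes the current trial,

    DV(hit i) = t_i . (meanHit_{k != i} - meanCR)
    DV(cr  i) = t_i . (meanHit - meanCR_{k != i}).

Sweeping a criterion over the DVs (strict '>' classifies a trial as Hit, ties
fall to CR) traces the ROC curve; the trapezoidal area under it is the
per-neuron discrimination performance.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .responsiveness import ResponsivenessResult

__all__ = ["ROCResult", "decision_variables", "roc_curve", "roc_auc",
           "neuron_roc_auc", "both_stimuli_fraction"]


@dataclass(frozen=True)
class ROCResult:
    dv_hits: np.ndarray
    dv_crs: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def decision_variables(hit_psths: np.ndarray, cr_psths: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Leave-one-out DV scores for every Hit and every CR trial.

    ``hit_psths`` and ``cr_psths`` are (n_trials, n_frames) arrays of equal
    frame count.  A class with a single trial has no leave-one-out template;
    its trials are skipped with a warning (an empty DV array is returned for
    that class).
    """
    hits = np.atleast_2d(np.asarray(hit_psths, dtype=float))
    crs = np.atleast_2d(np.asarray(cr_psths, dtype=float))
    if hits.shape[0] < 1 or crs.shape[0] < 1:
        raise ValueError("both classes need at least one trial")
    if hits.shape[1] != crs.shape[1]:
        raise ValueError("PSTH lengths differ between classes")
    mean_hit, mean_cr = hits.mean(axis=0), crs.mean(axis=0)
    n_h, n_c = hits.shape[0], crs.shape[0]
    if n_h >= 2:
        # leave-one-out hit template: (sum - t_i) / (n - 1)
        loo_hit = (hits.sum(axis=0) - hits) / (n_h - 1)
        dv_hits = np.einsum("ij,ij->i", hits, loo_hit - mean_cr)
    else:
        warnings.warn("single Hit trial: skipped (no leave-one-out template)")
        dv_hits = np.array([])
    if n_c >= 2:
        loo_cr = (crs.sum(axis=0) - crs) / (n_c - 1)
        dv_crs = np.einsum("ij,ij->i", crs, mean_hit - loo_cr)
    else:
        warnings.warn("single CR trial: skipped (no leave-one-out template)")
        dv_crs = np.array([])
    return dv_hits, dv_crs


def roc_curve(dv_hits: np.ndarray, dv_crs: np.ndarray) -> ROCResult:
    """ROC curve from the two DV sets.

    The criterion sweeps over all unique DV values plus sentinels; at each
    criterion TPR is the fraction of hit DVs strictly greater than it and FPR
    the fraction of CR DVs strictly greater.  Endpoints are exactly (0,0) and
    (1,1).
    """
    dv_hits = np.asarray(dv_hits, dtype=float)
    dv_crs = np.asarray(dv_crs, dtype=float)
    if len(dv_hits) == 0 or len(dv_crs) == 0:
        raise ValueError("both DV sets must be non-empty")
    crit = np.unique(np.concatenate([dv_hits, dv_crs]))
    crit = np.concatenate([[-np.inf], crit])  # -inf sentinel -> (1,1) point
    tpr = (dv_hits[None, :] > crit[:, None]).mean(axis=1)
    fpr = (dv_crs[None, :] > crit[:, None]).mean(axis=1)
    # the largest criterion yields (0,0) since '>' is strict
    order = np.lexsort((tpr, fpr))
    fpr, tpr = fpr[order], tpr[order]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(dv_hits=dv_hits, dv_crs=dv_crs, fpr=fpr, tpr=tpr, auc=auc)


def roc_auc(dv_hits: np.ndarray, dv_crs: np.ndarray) -> float:
    """Trapezoidal area under the ROC curve of the two DV sets."""
    return roc_curve(dv_hits, dv_crs).auc


def neuron_roc_auc(hit_psths: np.ndarray, cr_psths: np.ndarray) -> float:
    """Convenience: leave-one-out DVs then ROC AUC for one cell."""
    dv_h, dv_c = decision_variables(hit_psths, cr_psths)
    return roc_auc(dv_h, dv_c)


def both_stimuli_fraction(
        preferred: Sequence[ResponsivenessResult],
        nonpreferred: Sequence[ResponsivenessResult]) -> float:
    """Percentage of cells responsive to both the preferred and the
    nonpreferred stimulus, among all cells tested — the tuning-breadth readout
    (broadly tuned populations respond to both)."""
    if len(preferred) != len(nonpreferred):
        raise ValueError("per-stimulus result lists must align cell-by-cell")
    if len(preferred) == 0:
        raise ValueError("no cells")
    both = sum(p.responsive and n.responsive
               for p, n in zip(preferred, nonpreferred))
    return 100.0 * both / len(preferred)
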