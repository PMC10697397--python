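"""Stimulus decoding from pre-reward licking with an RBF-kernel SVM.

Licks are counted in 0.1 s bins over the pre-reward window [0, 1.9) s (19
features per trial).  Decoding accuracy is bootstrapped: on each iteration a
stratified 80/20 train/test split is drawn, an RBF-kernel support vector
classifier is fit on the training trials, and the test accuracy recorded; the
accuracy distribution and its mean summarize how well licking predicts the
stimulus.  Per-feature accuracies run the same bootstrap on one time bin at a
time, and the shuffled control permutes the stimulus labels independently on
every iteration.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC

__all__ = ["LickFeatureMatrix", "DecodingResult", "featurize_licks",
           "decode_stimulus", "per_feature_accuracy", "shuffled_control"]


@dataclass(frozen=True)
class LickFeatureMatrix:
    """Trials x time-bin lick counts with per-trial stimulus labels."""
    X: np.ndarray          # (n_trials, n_bins) non-negative integer counts
    y: np.ndarray          # stimulus class per trial
    bin: float
    window: tuple[float, float]

    def __post_init__(self) -> None:
        if self.X.ndim != 2 or len(self.X) != len(self.y):
            raise ValueError("X must be (n_trials, n_bins) aligned with y")
        if (self.X < 0).any():
            raise ValueError("lick counts must be non-negative")

    @property
    def bin_starts(self) -> np.ndarray:
        return np.round(np.arange(self.window[0], self.window[1] - 1e-9,
                                  self.bin), 6)

    @property
    def n_trials(self) -> int:
        return len(self.X)


@dataclass(frozen=True)
class DecodingResult:
    mean_accuracy: float               # percent
    accuracy_distribution: np.ndarray  # per-iteration percents
    n_iterations: int
    seed: Optional[int]
    shuffled: bool = False


def featurize_licks(trials: pd.DataFrame, licks: pd.DataFrame,
                    bin: float = 0.1,
                    window: tuple[float, float] = (0.0, 1.9),
                    binary: bool = False) -> LickFeatureMatrix:
    """Bin lick times into the pre-reward feature window, one row per trial.

    The window is half-open, so a lick at exactly 1.9 s is excluded.  Trials
    with no licks contribute all-zero rows.  ``binary`` converts counts to
    lick/no-lick indicators.
    """
    lo, hi = window
    n_bins = (hi - lo) / bin
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError(f"window {window} is not a multiple of bin {bin}")
    n_bins = int(round(n_bins))
    edges = lo + bin * np.arange(n_bins + 1)
    lick_map = {k: g.to_numpy()
                for k, g in licks.groupby("trial_index")["lick_time_s"]}
    X = np.zeros((len(trials), n_bins), dtype=int)
    for row, ti in enumerate(trials["trial_index"].to_numpy()):
        lt = lick_map.get(ti, np.array([]))
        lt = lt[(lt >= lo) & (lt < hi)]
        X[row], _ = np.histogram(lt, bins=edges)
    if binary:
        X = (X > 0).astype(int)
    return LickFeatureMatrix(X=X, y=trials["stimulus"].to_numpy(), bin=bin,
                             window=window)


def _check_classes(y: np.ndarray) -> None:
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("decoding requires two stimulus classes")
    if counts.min() < 2:
        raise ValueError("need at least 2 trials per class")


def decode_stimulus(features: LickFeatureMatrix, n_iterations: int = 1000,
                    train_fraction: float = 0.8,
                    seed: Optional[int] = None,
                    shuffle_labels: bool = False,
                    resample: bool = False) -> DecodingResult:
    """Bootstrap the test accuracy of an RBF-kernel SVM over random splits.

    Each iteration draws a stratified train/test split (``train_fraction`` of
    trials for training), fits ``SVC(kernel='rbf')`` with scaled bandwidth and
    unit regularization, and records the test accuracy in percent.
    ``shuffle_labels`` permutes the labels before splitting (chance control);
    ``resample`` draws the training set with replacement instead of re-
    splitting.  A fixed seed reproduces the accuracy distribution exactly.
    """
    X, y = features.X.astype(float), features.y
    _check_classes(y)
    rng = np.random.default_rng(seed)
    accs = np.empty(n_iterations)
    for it in range(n_iterations):
        yy = rng.permutation(y) if shuffle_labels else y
        state = int(rng.integers(2 ** 31 - 1))
        if resample:
            idx = rng.integers(len(yy), size=int(round(train_fraction
                                                       * len(yy))))
            test = np.setdiff1d(np.arange(len(yy)), idx)
            if len(test) == 0 or len(np.unique(yy[idx])) < 2:
                accs[it] = np.nan
                continue
            X_tr, y_tr, X_te, y_te = X[idx], yy[idx], X[test], yy[test]
        else:
            X_tr, X_te, y_tr, y_te = train_test_split(
                X, yy, train_size=train_fraction, stratify=yy,
                random_state=state)
        clf = SVC(kernel="rbf", gamma="scale", C=1.0)
        clf.fit(X_tr, y_tr)
        accs[it] = 100.0 * float(np.mean(clf.predict(X_te) == y_te))
    mean = float(np.nanmean(accs)) if n_iterations else float("nan")
    return DecodingResult(mean_accuracy=mean, accuracy_distribution=accs,
                          n_iterations=n_iterations, seed=seed,
                          shuffled=shuffle_labels)


def per_feature_accuracy(features: LickFeatureMatrix,
                         n_iterations: int = 10000,
                         seed: Optional[int] = None,
                         shuffle_labels: bool = False) -> pd.Series:
    """Bootstrapped decoding accuracy of each time bin on its own, indexed by
    bin start time — the most predictive lick-timing features."""
    out = {}
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(features.X.shape[1])
    for j, t0 in enumerate(features.bin_starts):
        single = LickFeatureMatrix(X=features.X[:, [j]], y=features.y,
                                   bin=features.bin, window=features.window)
        res = decode_stimulus(single, n_iterations=n_iterations,
                              seed=int(children[j].generate_state(1)[0]
                                       % (2 ** 31 - 1)),
                              shuffle_labels=shuffle_labels)
        out[t0] = res.mean_accuracy
    return pd.Series(out, name="accuracy_pct")


def shuffled_control(features: LickFeatureMatrix, n_iterations: int = 1000,
                     seed: Optional[int] = None) -> DecodingResult:
    """Chance control: stimulus labels permuted independently per iteration."""
    return decode_stimulus(features, n_iterations=n_iterations, seed=seed,
                           shuffle_labels=True)
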