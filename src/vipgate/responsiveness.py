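"""Epoch-scrambling bootstrap test of stimulus responsiveness.

A cell is called stimulus-responsive when the Pearson correlation between its
Z-score trace and the binary stimulus time course exceeds the correlation of
1000 epoch-scrambled surrogates at the <1% percentile (upper tail).  An epoch
is a maximal run of consecutive frames with z >= 3; a scramble permutes the
epoch segments among epoch slots and the gap segments among gap slots, which
preserves every sample value and the total length while destroying stimulus
alignment.  Cells with zero epochs show no transients at all and are declared
non-responsive by convention.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .traces import ZTrace

__all__ = [
    "Epoch", "ResponsivenessResult", "stimulus_indicator", "trials_indicator",
    "find_epochs", "scramble_epochs", "responsiveness_test",
    "fraction_responsive",
]


@dataclass(frozen=True)
class Epoch:
    """Maximal run of consecutive frames at or above the Z threshold."""
    start_frame: int
    length: int

    @property
    def stop_frame(self) -> int:
        return self.start_frame + self.length


@dataclass(frozen=True)
class ResponsivenessResult:
    observed_r: float
    null_percentile: float      # % of scrambles with r >= observed
    responsive: bool
    n_scrambles: int
    n_epochs: int = 0


def stimulus_indicator(stim_times: Sequence[tuple[float, float]],
                       n_frames: int, frame_rate: float) -> np.ndarray:
    """Binary stimulus time course: 1 during stimulus frames, 0 elsewhere.

    ``stim_times`` are (onset, offset) pairs in seconds; offsets beyond the
    trace raise an error.
    """
    indicator = np.zeros(n_frames)
    for on, off in stim_times:
        f0 = int(round(on * frame_rate))
        f1 = int(round(off * frame_rate))
        if f0 < 0 or f1 > n_frames:
            raise ValueError(
                f"stimulus window ({on}, {off}) s extends beyond the trace")
        indicator[f0:f1] = 1.0
    return indicator


def trials_indicator(trials, task, n_frames: int,
                     which: str = "all") -> np.ndarray:
    """Stimulus indicator built from trial records, optionally restricted to
    preferred or nonpreferred trials (for per-stimulus responsiveness)."""
    times = []
    for tr in trials:
        if which != "all" and tr.stimulus != which:
            continue
        stop = min(tr.trial_start_s + task.stimulus_duration,
                   n_frames / task.frame_rate)
        times.append((tr.trial_start_s, stop))
    return stimulus_indicator(times, n_frames, task.frame_rate)


def find_epochs(z: Union[ZTrace, np.ndarray],
                threshold: float = 3.0) -> list[Epoch]:
    """Maximal runs of consecutive frames with z >= threshold, in order."""
    arr = z.z if isinstance(z, ZTrace) else np.asarray(z, dtype=float)
    above = arr >= threshold
    if not above.any():
        return []
    padded = np.diff(np.concatenate(([0], above.astype(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    stops = np.flatnonzero(padded == -1)
    return [Epoch(int(a), int(b - a)) for a, b in zip(starts, stops)]


def _segments(arr: np.ndarray, epochs: Sequence[Epoch]):
    """Decompose the trace into the alternating gap/epoch segment sequence.

    Returns (kinds, segments) where kinds[i] is 'gap' or 'epoch'.  Zero-length
    leading/trailing gaps are omitted, so concatenating the segments in order
    reproduces the trace exactly.
    """
    kinds: list[str] = []
    segs: list[np.ndarray] = []
    pos = 0
    for ep in epochs:
        if ep.start_frame > pos:
            kinds.append("gap")
            segs.append(arr[pos:ep.start_frame])
        kinds.append("epoch")
        segs.append(arr[ep.start_frame:ep.stop_frame])
        pos = ep.stop_frame
    if pos < len(arr):
        kinds.append("gap")
        segs.append(arr[pos:])
    return kinds, segs


def scramble_epochs(z: Union[ZTrace, np.ndarray], epochs: Sequence[Epoch],
                    rng: np.random.Generator,
                    mode: str = "joint") -> np.ndarray:
    """One scramble, concatenated back in the alternating gap/epoch order.

    ``mode='joint'`` permutes epoch segments among epoch slots and gap
    segments among gap slots; ``mode='epochs_only'`` permutes the epochs while
    leaving the gaps in place.
    """
    arr = z.z if isinstance(z, ZTrace) else np.asarray(z, dtype=float)
    if len(epochs) == 0:
        raise ValueError("signal with zero epochs is not scramblable")
    kinds, segs = _segments(arr, epochs)
    return np.concatenate(_permuted_segments(kinds, segs, rng, mode))


def _permuted_segments(kinds, segs, rng, mode: str = "joint"):
    if mode not in ("joint", "epochs_only"):
        raise ValueError(f"unknown scramble mode: {mode!r}")
    ep_idx = [i for i, k in enumerate(kinds) if k == "epoch"]
    gap_idx = [i for i, k in enumerate(kinds) if k == "gap"]
    out = list(segs)
    ep_order = rng.permutation(len(ep_idx))
    for slot, src in zip(ep_idx, ep_order):
        out[slot] = segs[ep_idx[src]]
    if mode == "joint":
        gap_order = rng.permutation(len(gap_idx))
        for slot, src in zip(gap_idx, gap_order):
            out[slot] = segs[gap_idx[src]]
    return out


def responsiveness_test(z: Union[ZTrace, np.ndarray], indicator: np.ndarray,
                        n_scrambles: int = 1000, alpha: float = 1.0,
                        threshold: float = 3.0,
                        rng: Optional[Union[int, np.random.Generator]] = None,
                        mode: str = "joint") -> ResponsivenessResult:
    """Rank the observed trace/stimulus correlation against the scramble null.

    The percentile is the upper-tail rank: 100 x (fraction of scrambles whose
    correlation is >= the observed one).  ``responsive`` means percentile <
    ``alpha`` (percent).  Scrambling preserves the multiset of samples, so
    only the cross-term with the indicator varies and the null correlations
    reduce to affine functions of segment-permuted dot products.
    """
    arr = z.z if isinstance(z, ZTrace) else np.asarray(z, dtype=float)
    indicator = np.asarray(indicator, dtype=float)
    if len(arr) != len(indicator):
        raise ValueError("z and indicator lengths differ")
    sz, ss = arr.std(), indicator.std()
    if sz <= 0 or ss <= 0:
        raise ValueError("zero-variance z or indicator")
    n = len(arr)
    mz, ms = arr.mean(), indicator.mean()

    def corr_from_dot(dot: float) -> float:
        return (dot / n - mz * ms) / (sz * ss)

    observed = corr_from_dot(float(arr @ indicator))
    epochs = find_epochs(arr, threshold)
    if len(epochs) == 0:
        return ResponsivenessResult(observed_r=observed, null_percentile=100.0,
                                    responsive=False, n_scrambles=0, n_epochs=0)
    gen = rng if isinstance(rng, np.random.Generator) \
        else np.random.default_rng(rng)
    kinds, segs = _segments(arr, epochs)
    # cumulative slot boundaries depend on the permuted segment lengths, so
    # each scramble rebuilds the trace; the dot with the indicator is all that
    # is needed for the null correlation
    null = np.empty(n_scrambles)
    for s in range(n_scrambles):
        scrambled = np.concatenate(_permuted_segments(kinds, segs, gen, mode))
        null[s] = corr_from_dot(float(scrambled @ indicator))
    percentile = 100.0 * float(np.mean(null >= observed))
    return ResponsivenessResult(observed_r=observed,
                                null_percentile=percentile,
                                responsive=percentile < alpha,
                                n_scrambles=n_scrambles,
                                n_epochs=len(epochs))


def fraction_responsive(results: Sequence[ResponsivenessResult]) -> float:
    """Percentage of responsive cells among the cells tested (active cells)."""
    if len(results) == 0:
        raise ValueError("no cells")
    return 100.0 * sum(r.responsive for r in results) / len(results)
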