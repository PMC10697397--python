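"""Fluorescence trace processing: neuropil correction, quietest-baseline
search, modified Z-scores, event detection, and AUC-rate activity.

The modified Z-score standardizes the (neuropil-corrected) fluorescence by the
mean and SD of the quietest 10 s window of the trace — the contiguous window
with the lowest standard deviation of dF/F.  Because dF/F is an affine
rescaling of F by the whole-trace median, the minimizing window is found
directly on the corrected fluorescence.  Activity per window is summarized as
the AUC rate, mean(z) x frame_rate, a Z-score of fluorescence per second:
summing z over the window, dividing by the frame count (45 frames for 3 s at
15 Hz), and multiplying by the frame rate.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import find_peaks

from .synthetic import FluorescenceTrace

__all__ = [
    "ZTrace", "EventSet", "neuropil_correct", "find_quiet_baseline",
    "zscore_trace", "process_trace", "detect_events", "auc_rate",
    "evoked_and_spontaneous_means",
]


@dataclass(frozen=True)
class ZTrace:
    """Modified Z-score trace with the baseline window that defined it."""
    z: np.ndarray
    baseline_window: tuple[int, int]   # (start frame, length in frames)
    baseline_mean: float
    baseline_sd: float
    frame_rate: float = 15.0
    cell_class: str = "vip"

    @property
    def n_frames(self) -> int:
        return len(self.z)


@dataclass(frozen=True)
class EventSet:
    """Detected calcium transients of one cell."""
    peak_frames: np.ndarray
    peak_heights: np.ndarray           # Z units
    event_rate: float                  # events / s
    mean_peak_height: float
    auc_rate: float                    # whole-trace mean(z) * frame_rate

    @property
    def n_events(self) -> int:
        return len(self.peak_frames)

    @property
    def active(self) -> bool:
        """Cells with no transients at all are excluded from group analyses."""
        return self.n_events > 0


def neuropil_correct(trace: FluorescenceTrace, r: float = 0.7) -> np.ndarray:
    """Subtract the scaled local neuropil signal: corrected = F - r * F_neu."""
    if not 0.0 <= r < 1.0:
        raise ValueError(f"neuropil coefficient must be in [0, 1), got {r}")
    if len(trace.samples) != len(trace.neuropil_samples):
        raise ValueError("trace and neuropil lengths differ")
    return trace.samples - r * trace.neuropil_samples


def find_quiet_baseline(samples: np.ndarray, frame_rate: float,
                        window_s: float = 10.0) -> tuple[int, int]:
    """Locate the quietest window: the contiguous ``window_s`` stretch (stride
    one frame) minimizing the SD of dF/F; ties resolve to the earliest window.

    dF/F uses the whole-trace median as F0, a positive affine map of F, so the
    argmin is computed on the raw samples directly.  Returns (start, length)
    in frames.
    """
    samples = np.asarray(samples, dtype=float)
    n_win = int(round(window_s * frame_rate))
    if n_win < 1:
        raise ValueError("window shorter than one frame")
    if len(samples) < n_win:
        raise ValueError(
            f"trace of {len(samples)} frames shorter than the "
            f"{n_win}-frame baseline window")
    windows = sliding_window_view(samples, n_win)
    sds = windows.std(axis=-1)
    start = int(np.argmin(sds))  # argmin returns the first minimum
    return start, n_win


def zscore_trace(samples: np.ndarray, baseline: tuple[int, int],
                 frame_rate: float = 15.0, cell_class: str = "vip") -> ZTrace:
    """z(t) = (F(t) - mean(baseline)) / SD(baseline) over the given window."""
    samples = np.asarray(samples, dtype=float)
    start, length = baseline
    if not (0 <= start and start + length <= len(samples) and length >= 2):
        raise ValueError(f"baseline window {baseline} not inside trace")
    window = samples[start:start + length]
    mean = float(window.mean())
    sd = float(window.std())
    if sd <= 0.0:
        raise ValueError("degenerate trace: zero baseline SD")
    return ZTrace(z=(samples - mean) / sd, baseline_window=(start, length),
                  baseline_mean=mean, baseline_sd=sd, frame_rate=frame_rate,
                  cell_class=cell_class)


def process_trace(trace: FluorescenceTrace, r: float = 0.7,
                  baseline_window_s: float = 10.0) -> ZTrace:
    """Full preprocessing of one cell: neuropil correction, quietest-baseline
    search on the corrected trace, then the modified Z-score."""
    corrected = neuropil_correct(trace, r)
    baseline = find_quiet_baseline(corrected, trace.frame_rate,
                                   baseline_window_s)
    return zscore_trace(corrected, baseline, frame_rate=trace.frame_rate,
                        cell_class=trace.cell_class)


def detect_events(z: Union[ZTrace, np.ndarray], threshold: float = 3.0,
                  min_separation: int = 3,
                  frame_rate: Optional[float] = None) -> EventSet:
    """Detect transient peaks: local maxima of the Z-score at or above the
    threshold, separated by at least ``min_separation`` frames."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if isinstance(z, ZTrace):
        arr, fr = z.z, z.frame_rate
    else:
        arr = np.asarray(z, dtype=float)
        if frame_rate is None:
            raise ValueError("frame_rate required for a bare array")
        fr = frame_rate
    peaks, props = find_peaks(arr, height=threshold,
                              distance=max(int(min_separation), 1))
    heights = props["peak_heights"] if len(peaks) else np.array([])
    duration_s = len(arr) / fr
    return EventSet(
        peak_frames=peaks, peak_heights=heights,
        event_rate=len(peaks) / duration_s if duration_s > 0 else 0.0,
        mean_peak_height=float(heights.mean()) if len(peaks) else float("nan"),
        auc_rate=float(arr.mean()) * fr)


def auc_rate(z: Union[ZTrace, np.ndarray], window: tuple[int, int],
             frame_rate: Optional[float] = None) -> float:
    """AUC rate over a half-open frame window: mean(z[window]) x frame_rate.

    Equivalently the rectangular-sum AUC divided by the frame count and
    multiplied by the frame rate (45-frame normalization for 3 s at 15 Hz).
    """
    if isinstance(z, ZTrace):
        arr, fr = z.z, z.frame_rate
    else:
        arr = np.asarray(z, dtype=float)
        if frame_rate is None:
            raise ValueError("frame_rate required for a bare array")
        fr = frame_rate
    start, stop = window
    if not (0 <= start < stop <= len(arr)):
        raise ValueError(f"empty or out-of-range window {window}")
    return float(arr[start:stop].mean()) * fr


def evoked_and_spontaneous_means(
        z: Union[ZTrace, np.ndarray],
        stim_windows: Sequence[tuple[int, int]],
        gray_windows: Sequence[tuple[int, int]],
        frame_rate: Optional[float] = None) -> tuple[float, float]:
    """Mean AUC rate over stimulus windows (evoked) and gray-screen windows
    (spontaneous).  Gray windows may come from the ITIs of the same recording
    or from a dedicated gray-screen session."""
    if len(stim_windows) == 0:
        raise ValueError("no stimulus windows")
    evoked = float(np.mean([auc_rate(z, w, frame_rate) for w in stim_windows]))
    spont = (float(np.mean([auc_rate(z, w, frame_rate) for w in gray_windows]))
             if len(gray_windows) else float("nan"))
    return evoked, spont
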