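"""Trace normalization, calcium-event detection and peri-event responses.

z-scoring is session-wide per neuron (rasters show negative pre-onset values,
implying global standardization, not per-trial baselining).  Windows are
closed at both ends in frames; seconds convert to frames by round(t * rate).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal
from scipy.stats import median_abs_deviation

from .containers import seconds_to_frames

__all__ = [
    "zscore_traces",
    "detect_events",
    "align_to_onsets",
    "mean_window_response",
    "event_frequency",
    "PeriEventTensor",
]


def zscore_traces(traces: np.ndarray) -> np.ndarray:
    """Per-neuron z-score over the whole session (population-SD convention).

    Constant rows map to all-zero rows with a warning.
    """
    traces = np.asarray(traces, dtype=float)
    if traces.size == 0:
        raise ValueError("cannot z-score an empty trace matrix")
    if traces.ndim == 1:
        traces = traces[None, :]
    mean = traces.mean(axis=1, keepdims=True)
    sd = traces.std(axis=1, keepdims=True)
    constant = (sd == 0).ravel()
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant trace row(s) mapped to zeros", stacklevel=2
        )
    sd[sd == 0] = 1.0
    return (traces - mean) / sd


def detect_events(
    trace: np.ndarray,
    frame_rate: float = 10.0,
    k_mad: float = 3.0,
    rise_time: float = 0.1,
    lowpass_hz: float = 1.0,
) -> np.ndarray:
    """Rising-phase calcium events: local maxima of the low-pass-filtered
    trace whose prominence exceeds ``k_mad`` x MAD of the raw trace
    (normal-consistent MAD, a robust noise-SD estimate).

    Returns strictly increasing peak frame indices; no two events fall within
    one kernel rise time.  The zero-phase low-pass (default 1 Hz, second-order
    Butterworth) suppresses frame noise without delaying the transient peak.
    """
    trace = np.asarray(trace, dtype=float).ravel()
    if not np.all(np.isfinite(trace)):
        raise ValueError("trace contains non-finite values")
    if trace.size < 3:
        return np.array([], dtype=int)
    nyq = frame_rate / 2.0
    if 0 < lowpass_hz < nyq:
        b, a = sp_signal.butter(2, lowpass_hz / nyq)
        padlen = min(3 * max(len(a), len(b)), trace.size - 1)
        filtered = sp_signal.filtfilt(b, a, trace, padlen=padlen)
    else:
        filtered = trace
    mad = median_abs_deviation(trace, scale="normal")
    if mad == 0:  # flat (or near-flat) trace: fall back to a tiny floor
        mad = np.finfo(float).eps
    distance = max(1, seconds_to_frames(rise_time, frame_rate))
    peaks, _ = sp_signal.find_peaks(filtered, prominence=k_mad * mad, distance=distance)
    return peaks.astype(int)


@dataclass
class PeriEventTensor:
    """z-scores aligned to a named onset: neurons x kept-trials x window frames.

    Onsets whose window would cross the session edge are excluded from the
    tensor and reported in ``excluded`` (never silently dropped).
    """

    tensor: np.ndarray
    onsets: np.ndarray  # kept onset frames, one per tensor trial
    excluded: np.ndarray  # onset frames whose window crossed the session edge
    window: tuple[float, float]
    frame_rate: float

    @property
    def n_window_frames(self) -> int:
        return int(self.tensor.shape[2])


def align_to_onsets(
    ztraces: np.ndarray,
    onsets,
    window: tuple[float, float],
    frame_rate: float = 10.0,
) -> PeriEventTensor:
    """Slice z-traces around each onset; window in seconds, closed at both ends."""
    ztraces = np.atleast_2d(np.asarray(ztraces, dtype=float))
    onsets = np.asarray(onsets, dtype=int)
    if onsets.size == 0:
        raise ValueError("onset list is empty")
    t_pre, t_post = window
    if t_pre > t_post:
        raise ValueError(f"window must satisfy start <= end, got {window}")
    lo = seconds_to_frames(t_pre, frame_rate)
    hi = seconds_to_frames(t_post, frame_rate)
    n_frames = ztraces.shape[1]
    ok = (onsets + lo >= 0) & (onsets + hi < n_frames)
    kept = onsets[ok]
    if kept.size == 0:
        raise ValueError("no onset fits inside the session with this window")
    idx = kept[:, None] + np.arange(lo, hi + 1)[None, :]
    tensor = ztraces[:, idx]  # (neurons, trials, window frames)
    return PeriEventTensor(
        tensor=tensor,
        onsets=kept,
        excluded=onsets[~ok],
        window=(t_pre, t_post),
        frame_rate=frame_rate,
    )


def mean_window_response(
    peri: PeriEventTensor, response_window: tuple[float, float]
) -> np.ndarray:
    """Mean z within a sub-window of the peri-event tensor -> neurons x trials."""
    t0, t1 = response_window
    if t0 > t1:
        raise ValueError("response_window must satisfy start <= end")
    if t0 < peri.window[0] - 1e-9 or t1 > peri.window[1] + 1e-9:
        raise ValueError(
            f"response_window {response_window} not contained in peri window {peri.window}"
        )
    lo = seconds_to_frames(t0 - peri.window[0], peri.frame_rate)
    hi = seconds_to_frames(t1 - peri.window[0], peri.frame_rate)
    if hi < lo:
        raise ValueError("response window is empty")
    return peri.tensor[:, :, lo : hi + 1].mean(axis=2)


def event_frequency(events: np.ndarray, windows) -> float:
    """Events per frame inside the given closed frame intervals.

    ``windows`` is a sequence of (start, end) inclusive frame intervals;
    overlapping intervals are merged before counting.
    """
    events = np.asarray(events, dtype=int)
    ivs = sorted((int(a), int(b)) for a, b in windows)
    merged: list[list[int]] = []
    for a, b in ivs:
        if b < a:
            raise ValueError(f"window ({a}, {b}) has negative length")
        if merged and a <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    total = sum(b - a + 1 for a, b in merged)
    if total == 0:
        raise ValueError("total window length is zero")
    count = 0
    for a, b in merged:
        count += int(((events >= a) & (events <= b)).sum())
    return count / total
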