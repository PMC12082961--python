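"""Breath detection from the 100-Hz nasal-temperature signal.

Inhaled air cools the perinasal sensor, so temperature falls during
inspiration and rises during expiration; each local temperature maximum
marks an inspiration onset.  Breaths are counted as detected maxima and the
respiratory rate follows as breaths * 60 / recording duration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .errors import ConfigError
from .types import RespirationTrace

__all__ = ["BreathAnnotation", "smooth_trace", "detect_peaks", "respiratory_rate"]


@dataclass
class BreathAnnotation:
    """Detected inspiration onsets and derived breath statistics."""

    inspiration_onsets_s: np.ndarray
    n_breaths: int
    mean_cycle_s: float          # nan when fewer than 2 onsets
    respiratory_rate_bpm: float  # 60 / mean_cycle_s; nan when undefined

    def to_json(self, path=None) -> str:
        payload = json.dumps({
            "inspiration_onsets_s": [float(t) for t in self.inspiration_onsets_s],
            "n_breaths": int(self.n_breaths),
            "mean_cycle_s": None if np.isnan(self.mean_cycle_s) else float(self.mean_cycle_s),
            "respiratory_rate_bpm": (None if np.isnan(self.respiratory_rate_bpm)
                                     else float(self.respiratory_rate_bpm)),
        }, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def smooth_trace(trace: RespirationTrace, window_s: float = 0.5) -> RespirationTrace:
    """Centered moving average; edges use truncated windows, window 0 = identity."""
    if window_s < 0:
        raise ConfigError("window_s must be non-negative")
    half = int(round(window_s * trace.fs_hz / 2.0))
    if half == 0:
        return RespirationTrace(trace.values.copy(), fs_hz=trace.fs_hz)
    kernel = np.ones(2 * half + 1)
    sums = np.convolve(trace.values, kernel, mode="same")
    counts = np.convolve(np.ones(len(trace)), kernel, mode="same")
    return RespirationTrace(sums / counts, fs_hz=trace.fs_hz)


def detect_peaks(trace: RespirationTrace, min_separation_s: float = 1.5,
                 min_prominence: float = 0.2,
                 smooth_window_s: float = 0.5) -> BreathAnnotation:
    """Detect inspiration onsets as local temperature maxima.

    The trace is smoothed first (0.5-s moving average by default); peaks
    must be separated by at least ``min_separation_s`` (below the fastest
    expected 2-s spontaneous cycle) and have prominence of at least
    ``min_prominence`` times the smoothed peak-to-peak amplitude.  The trace
    is padded on the left so the onset at t = 0 is detectable; the right
    boundary is deliberately not padded, so a temperature rise running into
    the end of the record (toward an onset beyond it) is not counted as an
    extra breath.  A flat trace yields zero breaths.
    """
    if len(trace) < 2:
        raise ConfigError("trace must contain at least 2 samples")
    smoothed = smooth_trace(trace, smooth_window_s)
    x = smoothed.values
    amplitude = float(x.max() - x.min())
    if amplitude == 0.0:
        return BreathAnnotation(np.array([]), 0, np.nan, np.nan)
    pad_value = x.min() - amplitude
    padded = np.concatenate([[pad_value], x])
    distance = max(1, int(round(min_separation_s * trace.fs_hz)))
    idx, _ = find_peaks(padded, distance=distance,
                        prominence=min_prominence * amplitude)
    onsets = (idx - 1) / trace.fs_hz
    n = len(onsets)
    if n >= 2:
        mean_cycle = float(np.mean(np.diff(onsets)))
        rate = 60.0 / mean_cycle
    else:
        mean_cycle = np.nan
        rate = np.nan
    return BreathAnnotation(onsets, n, mean_cycle, rate)


def respiratory_rate(annotation: BreathAnnotation, duration_s: float) -> float:
    """Breaths per minute over the recording: n_breaths * 60 / duration."""
    if duration_s <= 0:
        raise ConfigError("duration_s must be positive")
    return annotation.n_breaths * 60.0 / duration_s
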