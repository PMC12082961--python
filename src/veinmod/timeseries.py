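"""Ensemble averaging, tonic baseline and linear-trend statistics.

Paced-breathing recordings are aligned to the first detected inspiration
onset before ensemble averaging, so respiration-locked modulation survives
the average while unlocked components cancel; spontaneous-breathing
recordings are averaged from record start (their phases are incoherent and
the ensemble flattens).  The tonic state of a recording is summarised by its
50-s mean diameter (the "baseline") and by an ordinary-least-squares linear
trend with its coefficient of determination r^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .errors import AlignmentError, ConfigError
from .respiration import BreathAnnotation
from .types import DiameterSeries, FLAG_MISSING

__all__ = ["Alignment", "EnsembleResult", "TrendResult", "Baseline",
           "align_series", "ensemble_average", "linear_trend_r2", "baseline_mean"]


class Alignment(str, Enum):
    RECORD_START = "record_start"
    INSPIRATION_ONSET = "inspiration_onset"


@dataclass
class EnsembleResult:
    """Pointwise mean/SD across aligned recordings, with per-point count."""

    mean_trace: np.ndarray
    sd_trace: np.ndarray
    n: np.ndarray
    alignment: Alignment = Alignment.RECORD_START

    def to_csv(self, path) -> None:
        pd.DataFrame({
            "time_s": np.arange(len(self.mean_trace), dtype=float),
            "mean_mm": self.mean_trace,
            "sd_mm": self.sd_trace,
            "n": self.n,
        }).to_csv(path, index=False)


@dataclass
class TrendResult:
    """OLS linear trend of a per-second trace."""

    slope: float
    intercept: float
    r2: float


@dataclass
class Baseline:
    """Mean diameter over the 50-s recording (mm)."""

    value_mm: float


def align_series(series: DiameterSeries, annotation: BreathAnnotation | None,
                 mode: Alignment = Alignment.RECORD_START) -> DiameterSeries:
    """Shift a series so t = 0 coincides with the first inspiration onset.

    ``record_start`` mode is the identity (used for spontaneous breathing).
    ``inspiration_onset`` mode drops the samples before the first detected
    onset; requires at least one onset.
    """
    mode = Alignment(mode)
    if mode is Alignment.RECORD_START:
        return series
    if annotation is None or annotation.n_breaths == 0:
        raise AlignmentError("inspiration-onset alignment requires >= 1 onset")
    k0 = int(round(annotation.inspiration_onsets_s[0]))
    if k0 == 0:
        return series
    if k0 >= len(series):
        raise AlignmentError(f"first onset at {k0} s is beyond the series")
    return DiameterSeries(series.values_mm[k0:],
                          participant_id=series.participant_id,
                          condition=series.condition,
                          repetition=series.repetition,
                          quality_flags=series.quality_flags[k0:])


def ensemble_average(series_list, alignment: Alignment = Alignment.RECORD_START
                     ) -> EnsembleResult:
    """Pointwise mean and SD over aligned recordings.

    Accepts DiameterSeries or plain arrays; shorter records contribute up to
    their own length and the per-point count ``n`` reports how many entered
    each time point.  SD uses the n-1 denominator and is 0 where n = 1.
    """
    arrays = [np.asarray(s.values_mm if isinstance(s, DiameterSeries) else s,
                         dtype=float) for s in series_list]
    if not arrays:
        raise ConfigError("need at least one series to ensemble-average")
    length = max(a.size for a in arrays)
    stack = np.full((len(arrays), length), np.nan)
    for i, a in enumerate(arrays):
        stack[i, :a.size] = a
    n = np.sum(~np.isnan(stack), axis=0)
    mean = np.nanmean(stack, axis=0)
    sd = np.zeros(length)
    multi = n > 1
    if multi.any():
        sd[multi] = np.nanstd(stack[:, multi], axis=0, ddof=1)
    return EnsembleResult(mean, sd, n, Alignment(alignment))


def linear_trend_r2(trace) -> TrendResult:
    """OLS of value on time (1-Hz index); r^2 = 1 - SSres/SStot.

    A constant trace has no explainable variance; its r^2 is defined as 0.
    """
    y = np.asarray(trace, dtype=float)
    if y.size < 3:
        raise ConfigError("need at least 3 points for a trend")
    t = np.arange(y.size, dtype=float)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return TrendResult(0.0, float(y.mean()), 0.0)
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (slope * t + intercept)
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot
    return TrendResult(float(slope), float(intercept), float(r2))


def baseline_mean(series: DiameterSeries) -> Baseline:
    """Arithmetic mean of the non-missing samples (the tonic baseline, mm)."""
    keep = np.array([f != FLAG_MISSING for f in series.quality_flags])
    if not keep.any():
        raise ConfigError("series has no valid samples")
    return Baseline(float(series.values_mm[keep].mean()))
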