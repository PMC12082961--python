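"""Maximum-entropy (Burg AR) spectral estimation of phasic modulation.

The phasic respiratory modulation of a 50-sample, 1-Hz diameter record is
quantified as the natural log of the power spectral density integrated over
a narrow band at the paced-breathing frequency: 0.099-0.101 Hz for 10-s
paced breathing and 0.332-0.334 Hz for 3-s paced breathing.  The PSD comes
from a seventh-order autoregressive model fitted with Burg's recursion
(forward-backward prediction-error minimisation with Levinson order
updates), the classical maximum-entropy method suited to such short records.

Sign convention: the AR denominator polynomial is 1 + sum_k a_k z^-k, i.e.
x_t = -sum_k a_k x_{t-k} + e_t, so an AR(1) process with lag-1 coefficient
0.6 yields a_1 = -0.6.  The one-sided PSD carries a factor 2 so its
integral over [0, Nyquist] matches the (detrended) series variance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, DegenerateSeriesError, UnsupportedConditionError
from .types import Condition, DiameterSeries

__all__ = ["ARModel", "Spectrum", "BandSpec", "BandLogPower",
           "BAND_PB10", "BAND_PB3", "band_for_condition",
           "fit_burg", "mem_psd", "band_logpower", "modulation_magnitude",
           "DEFAULT_AR_ORDER", "default_freq_grid"]

#: Model order of the maximum-entropy AR fit.
DEFAULT_AR_ORDER = 7

#: Default frequency-grid step (Hz); fine enough for the 0.002-Hz bands.
DEFAULT_FREQ_STEP_HZ = 1e-4


@dataclass
class ARModel:
    """Fitted AR model: denominator 1 + sum a_k z^-k, driving-noise variance."""

    order: int
    coefficients: np.ndarray      # a_1 ... a_p
    noise_variance: float
    dt_s: float = 1.0
    reflection: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.coefficients) != self.order:
            raise ConfigError("order must equal the number of coefficients")
        if self.noise_variance < 0:
            raise ConfigError("noise_variance must be non-negative")


@dataclass
class Spectrum:
    """One-sided PSD on a frequency grid over [0, Nyquist]."""

    freqs_hz: np.ndarray
    psd: np.ndarray

    def total_power(self) -> float:
        """Trapezoidal integral of the PSD over the grid."""
        return float(np.trapezoid(self.psd, self.freqs_hz))


@dataclass(frozen=True)
class BandSpec:
    """Integration band [lo, hi] Hz for one paced condition."""

    lo_hz: float
    hi_hz: float
    condition: Condition | None = None

    def __post_init__(self):
        if not (0.0 <= self.lo_hz < self.hi_hz):
            raise ConfigError("band must satisfy 0 <= lo < hi")


BAND_PB10 = BandSpec(0.099, 0.101, Condition.PB10)
BAND_PB3 = BandSpec(0.332, 0.334, Condition.PB3)


def band_for_condition(condition) -> BandSpec:
    condition = Condition.coerce(condition)
    if condition is Condition.PB10:
        return BAND_PB10
    if condition is Condition.PB3:
        return BAND_PB3
    raise UnsupportedConditionError(
        "spontaneous breathing has no defined paced-frequency band")


@dataclass
class BandLogPower:
    """ln(integrated in-band power); -inf flagged degenerate for zero power."""

    value: float
    band: BandSpec
    degenerate: bool = False

    def to_json(self, path=None, **extra) -> str:
        payload = json.dumps({
            "log_power": None if self.degenerate else float(self.value),
            "band_lo_hz": self.band.lo_hz,
            "band_hi_hz": self.band.hi_hz,
            "degenerate": self.degenerate,
            **extra,
        }, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def _detrend(x: np.ndarray, mode: str) -> np.ndarray:
    if mode == "mean":
        return x - x.mean()
    if mode == "linear":
        t = np.arange(x.size, dtype=float)
        slope, intercept = np.polyfit(t, x, 1)
        return x - (slope * t + intercept)
    raise ConfigError(f"unknown detrend mode {mode!r}")


def fit_burg(series, order: int = DEFAULT_AR_ORDER, dt_s: float = 1.0,
             detrend: str = "mean") -> ARModel:
    """Fit an AR model by Burg's maximum-entropy recursion.

    The sample mean is removed first (``detrend="linear"`` additionally
    removes an OLS line).  All reflection coefficients of a non-degenerate
    input have magnitude < 1, guaranteeing a stable model.
    """
    x = np.asarray(series.values_mm if isinstance(series, DiameterSeries)
                   else series, dtype=float)
    if x.ndim != 1:
        raise ConfigError("series must be one-dimensional")
    if order < 1:
        raise ConfigError("order must be >= 1")
    if x.size <= order:
        raise ConfigError(f"series length {x.size} must exceed order {order}")
    if np.ptp(x) == 0.0:
        raise DegenerateSeriesError("series is constant; variance is zero")
    x = _detrend(x, detrend)
    energy0 = float(np.dot(x, x))
    if energy0 <= (np.abs(x).max() * x.size) * np.finfo(float).tiny or \
            energy0 == 0.0:
        raise DegenerateSeriesError("series has zero variance after detrending")

    f = x.copy()
    b = x.copy()
    e = energy0 / x.size
    a = np.zeros(0)
    ks = []
    for m in range(order):
        fseg = f[m + 1:]
        bseg = b[m:-1]
        denom = float(np.dot(fseg, fseg) + np.dot(bseg, bseg))
        if denom <= energy0 * 1e-30:
            # prediction error exhausted; remaining orders contribute nothing
            k = 0.0
        else:
            k = -2.0 * float(np.dot(fseg, bseg)) / denom
        a = np.concatenate([a + k * a[::-1], [k]])
        f_new = fseg + k * bseg
        b_new = bseg + k * fseg
        f[m + 1:] = f_new
        b[m + 1:] = b_new
        e *= (1.0 - k * k)
        ks.append(k)
    return ARModel(order=order, coefficients=a, noise_variance=float(e),
                   dt_s=dt_s, reflection=np.asarray(ks))


def default_freq_grid(dt_s: float = 1.0,
                      step_hz: float = DEFAULT_FREQ_STEP_HZ) -> np.ndarray:
    nyquist = 1.0 / (2.0 * dt_s)
    n = int(round(nyquist / step_hz))
    return np.linspace(0.0, nyquist, n + 1)


def mem_psd(model: ARModel, freqs_hz: np.ndarray | None = None) -> Spectrum:
    """Maximum-entropy PSD of a fitted AR model.

    P(f) = 2 * sigma^2 * dt / |1 + sum_k a_k exp(-i 2 pi f k dt)|^2
    (one-sided convention; integral over [0, Nyquist] approximates the
    series variance).
    """
    freqs = default_freq_grid(model.dt_s) if freqs_hz is None \
        else np.asarray(freqs_hz, dtype=float)
    nyquist = 1.0 / (2.0 * model.dt_s)
    if freqs.min() < 0 or freqs.max() > nyquist + 1e-12:
        raise ConfigError(f"frequency grid must lie within [0, {nyquist}] Hz")
    k = np.arange(1, model.order + 1)
    phase = np.exp(-2j * np.pi * model.dt_s * np.outer(freqs, k))
    denom = np.abs(1.0 + phase @ model.coefficients) ** 2
    psd = 2.0 * model.noise_variance * model.dt_s / denom
    return Spectrum(freqs, psd)


def band_logpower(spectrum: Spectrum, band: BandSpec) -> BandLogPower:
    """Natural log of the trapezoidal PSD integral over [lo, hi] Hz."""
    freqs = spectrum.freqs_hz
    if band.lo_hz < freqs.min() - 1e-12 or band.hi_hz > freqs.max() + 1e-12:
        raise ConfigError(f"band {band} outside the spectrum grid")
    sel = (freqs >= band.lo_hz - 1e-12) & (freqs <= band.hi_hz + 1e-12)
    if sel.sum() < 2:
        raise ConfigError("grid too coarse across the band")
    steps = np.diff(freqs[sel])
    if steps.max() > 5e-4 + 1e-12:
        raise ConfigError("grid resolution must be <= 0.0005 Hz across the band")
    power = float(np.trapezoid(spectrum.psd[sel], freqs[sel]))
    if power <= 0.0:
        return BandLogPower(-np.inf, band, degenerate=True)
    return BandLogPower(float(np.log(power)), band)


def modulation_magnitude(series, condition, order: int = DEFAULT_AR_ORDER,
                         detrend: str = "mean",
                         freqs_hz: np.ndarray | None = None) -> BandLogPower:
    """Phasic modulation magnitude of one recording.

    Composes mean removal -> Burg AR(order) -> maximum-entropy PSD -> log
    band power at the condition's paced frequency.  Only the paced
    conditions have a defined band; spontaneous breathing raises
    ``UnsupportedConditionError``.
    """
    band = band_for_condition(condition)
    model = fit_burg(series, order=order, detrend=detrend)
    spectrum = mem_psd(model, freqs_hz)
    return band_logpower(spectrum, band)
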