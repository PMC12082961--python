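"""Synthetic study generator with known ground truth.

Emulates the study design this package analyses: 21 participants each perform
spontaneous breathing (SB), 3-s paced breathing (PB3) and 10-s paced breathing
(PB10), three 50-s repetitions per condition, while a short-axis B-mode view of
an elbow-fossa vein is recorded at 1 frame/s and nasal temperature at 100 Hz.

The vein diameter follows

    d(t) = d0 + slope * t + amp * cos(2 * pi * psi(t)) + eps(t)

where ``psi`` is the respiratory phase warped so the diameter minimum falls at
end-inspiration (the vein contracts while breathing in) and the maximum at
end-expiration, and ``eps`` is i.i.d. Gaussian measurement noise at 1 Hz.
Nasal temperature is maximal at inspiration onset and falls to a minimum at
the inspiration-to-expiration transition (inhaled air cools the sensor).

Default cohort parameters reproduce the study-scale statistical structure:
50-s baselines of 2.55 / 2.51 / 2.43 mm for SB / PB3 / PB10, a slow tonic
rise within each recording, and a phasic amplitude that doubles from PB3 to
PB10.  See docs/methods.md for the derivation of the slope defaults.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from skimage.draw import ellipse as draw_ellipse

from .errors import ConfigError
from .types import (Condition, DiameterSeries, ImageSequence, PACED_CYCLE_S,
                    RespirationTrace)

__all__ = [
    "BreathPattern",
    "GroundTruth",
    "SceneParams",
    "CohortDesign",
    "Recording",
    "Cohort",
    "make_breath_pattern",
    "make_respiration_trace",
    "make_diameter_series",
    "render_frames",
    "make_cohort",
    "sample_baseline_matrix",
]

#: Fraction of each breath cycle spent on inspiration (I:E = 1:1.5).
DEFAULT_INSP_FRAC = 0.4

#: Spontaneous cycle lengths: range printed as 2-8 s, mean approximately 3.9 s.
SB_CYCLE_RANGE_S = (2.0, 8.0)
SB_CYCLE_MEAN_S = 3.9

#: No spontaneous onset is placed in the final guard interval of the record:
#: a breath beginning at the window's edge leaves no countable temperature
#: peak inside it, so the ground-truth breath count would be ill-defined.
SB_END_GUARD_S = 1.5


def _child_seeds(*key: int, n: int = 1) -> list[int]:
    """Deterministic child seeds from an integer key tuple."""
    ss = np.random.SeedSequence([int(k) for k in key])
    return [int(s) for s in ss.generate_state(n)]


@dataclass
class BreathPattern:
    """Per-breath timing of one 50-s recording.

    ``inspiration_onsets_s`` are the onsets falling inside [0, duration).
    Paced recordings start exactly at an onset (first onset at t = 0).
    Spontaneous recordings start mid-breath: the segment before the first
    onset belongs to a virtual previous breath of length ``prev_cycle_s``
    (the recording window is not synchronized to the breathing).
    """

    condition: Condition
    cycle_lengths_s: np.ndarray
    inspiration_onsets_s: np.ndarray
    duration_s: float = 50.0
    prev_cycle_s: float | None = None

    def __post_init__(self):
        self.condition = Condition.coerce(self.condition)
        self.cycle_lengths_s = np.asarray(self.cycle_lengths_s, dtype=float)
        self.inspiration_onsets_s = np.asarray(self.inspiration_onsets_s, dtype=float)
        if len(self.cycle_lengths_s) == 0:
            raise ConfigError("breath pattern must contain at least one breath")
        d = np.diff(self.inspiration_onsets_s)
        if np.any(d <= 0):
            raise ConfigError("inspiration onsets must be strictly increasing")
        if not np.allclose(d, self.cycle_lengths_s[:-1]):
            raise ConfigError("onset spacing must equal cycle lengths")
        if self.inspiration_onsets_s[0] < 0:
            raise ConfigError("onsets must lie inside the recording")
        if self.inspiration_onsets_s[0] > 0 and self.prev_cycle_s is None:
            raise ConfigError("a pattern starting mid-breath needs prev_cycle_s")
        if self.prev_cycle_s is not None and self.prev_cycle_s <= 0:
            raise ConfigError("prev_cycle_s must be positive")
        end = self.inspiration_onsets_s[-1] + self.cycle_lengths_s[-1]
        if end < self.duration_s - 1e-9:
            raise ConfigError("cycles must cover the full recording duration")

    @property
    def n_breaths(self) -> int:
        return len(self.inspiration_onsets_s)

    def cycle_fraction(self, t: np.ndarray) -> np.ndarray:
        """Raw within-breath fraction u(t) in [0, 1); u = 0 at onset."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.inspiration_onsets_s, t, side="right") - 1
        idx_c = np.clip(idx, 0, self.n_breaths - 1)
        u = (t - self.inspiration_onsets_s[idx_c]) / self.cycle_lengths_s[idx_c]
        if self.inspiration_onsets_s[0] > 0:
            before = t < self.inspiration_onsets_s[0]
            u = np.where(before,
                         1.0 - (self.inspiration_onsets_s[0] - t) / self.prev_cycle_s,
                         u)
        return np.clip(u, 0.0, 1.0 - 1e-12)

    def phase(self, t: np.ndarray, insp_frac: float = DEFAULT_INSP_FRAC) -> np.ndarray:
        """Warped respiratory phase psi(t) in [0, 1).

        psi = 0 at inspiration onset, 0.5 at the inspiration-to-expiration
        transition (``insp_frac`` through the cycle) and -> 1 at the next
        onset, so ``cos(2 pi psi)`` peaks at end-expiration and bottoms out
        at end-inspiration.
        """
        u = self.cycle_fraction(t)
        f = insp_frac
        return np.where(u < f, 0.5 * u / f, 0.5 + 0.5 * (u - f) / (1.0 - f))


def make_breath_pattern(condition, duration_s: float = 50.0, seed: int | None = None,
                        sb_distribution: str = "beta",
                        sb_mode_s: float = 3.0) -> BreathPattern:
    """Draw the breath timing for one recording.

    Paced conditions are deterministic (fixed 3-s or 10-s cycles, first onset
    at t = 0).  Spontaneous cycles are i.i.d. on [2, 8] s; ``sb_distribution``
    selects ``"beta"`` (default; scaled Beta(2, 4.316) with mean 3.9 s),
    ``"uniform"``, or ``"triangular"`` with mode ``sb_mode_s``.  Spontaneous
    recordings start mid-breath, during the expiration of a virtual previous
    breath (40-90 % through its cycle), so cohort members are not phase-
    coherent at t = 0 the way an onset-synchronized start would make them.
    """
    condition = Condition.coerce(condition)
    if duration_s <= 0:
        raise ConfigError("duration_s must be positive")
    if condition in PACED_CYCLE_S:
        c = PACED_CYCLE_S[condition]
        n = int(np.ceil(duration_s / c))
        cycles = np.full(n, c)
        onsets = np.concatenate([[0.0], np.cumsum(cycles)[:-1]])
        keep = onsets < duration_s
        return BreathPattern(condition, cycles[keep], onsets[keep], duration_s)

    rng = np.random.default_rng(seed)
    lo, hi = SB_CYCLE_RANGE_S

    def draw_cycle() -> float:
        if sb_distribution == "beta":
            # mean of Beta(a, b) = a/(a+b); solved for mean 3.9 on [2, 8]
            mu = (SB_CYCLE_MEAN_S - lo) / (hi - lo)
            a = 2.0
            b = a * (1.0 - mu) / mu
            return lo + (hi - lo) * rng.beta(a, b)
        if sb_distribution == "uniform":
            return rng.uniform(lo, hi)
        if sb_distribution == "triangular":
            return rng.triangular(lo, sb_mode_s, hi)
        raise ConfigError(f"unknown sb_distribution {sb_distribution!r}")

    # spontaneous: recording opens partway through a previous breath,
    # during its expiration, so t = 0 is not phase-locked to an onset
    for _attempt in range(1000):
        prev_cycle = draw_cycle()
        u0 = rng.uniform(DEFAULT_INSP_FRAC, 0.9)  # expiration phase at t = 0
        t0 = (1.0 - u0) * prev_cycle
        cycles = []
        total = t0
        while total < duration_s:
            c = draw_cycle()
            cycles.append(c)
            total += c
        cycles = np.asarray(cycles)
        onsets = t0 + np.concatenate([[0.0], np.cumsum(cycles)[:-1]])
        keep = onsets < duration_s - SB_END_GUARD_S
        if np.any(onsets[keep.sum():] < duration_s):
            continue           # an onset fell inside the end guard; redraw
        return BreathPattern(condition, cycles[keep], onsets[keep], duration_s,
                             prev_cycle_s=prev_cycle)
    raise ConfigError("could not draw a spontaneous pattern (end guard)")


def make_respiration_trace(pattern: BreathPattern, fs_hz: float = 100.0,
                           temp_amp: float = 0.8, temp_baseline: float = 34.0,
                           noise_sd: float = 0.0, seed: int | None = None,
                           insp_frac: float = DEFAULT_INSP_FRAC) -> RespirationTrace:
    """Synthesize a nasal-temperature trace for a breath pattern.

    ``temp_amp`` is the noise-free peak-to-peak swing (degrees C).  Within
    each cycle the trace is a piecewise cosine: maximal at inspiration onset,
    minimal at the inspiration-to-expiration transition, back to maximal at
    the next onset.  Additive Gaussian noise with SD ``noise_sd``.
    """
    if fs_hz <= 0:
        raise ConfigError("fs_hz must be positive")
    if pattern is None or pattern.n_breaths == 0:
        raise ConfigError("breath pattern is empty")
    n = int(round(pattern.duration_s * fs_hz))
    t = np.arange(n) / fs_hz
    u = pattern.cycle_fraction(t)
    f = insp_frac
    half = temp_amp / 2.0
    shape = np.where(u < f,
                     np.cos(np.pi * u / f),
                     -np.cos(np.pi * (u - f) / (1.0 - f)))
    values = temp_baseline + half * shape
    if noise_sd > 0:
        values = values + np.random.default_rng(seed).normal(0.0, noise_sd, n)
    return RespirationTrace(values, fs_hz=fs_hz)


@dataclass
class GroundTruth:
    """True diameter-dynamics parameters of one recording.

    ``d0`` is the diameter at t = 0 (mm), ``slope`` the tonic linear drift
    (mm/s), ``amp`` the phasic half-amplitude (mm) and ``noise_sd_diameter``
    the SD of i.i.d. 1-Hz measurement noise (mm).  ``minimum_at_end_inspiration``
    records the sign convention: the vein contracts with inspiration and
    dilates with expiration.
    """

    d0: float
    slope: float = 0.0
    amp: float = 0.0
    noise_sd_diameter: float = 0.0
    minimum_at_end_inspiration: bool = True

    def validate(self, duration_s: float) -> None:
        if self.d0 <= 0:
            raise ConfigError("d0 must be positive")
        if self.amp < 0:
            raise ConfigError("amp must be non-negative")
        if self.d0 - self.amp - abs(self.slope) * duration_s <= 0:
            raise ConfigError("lumen would collapse: d0 - amp - |slope|*T <= 0")


def make_diameter_series(pattern: BreathPattern, truth: GroundTruth,
                         seed: int | None = None,
                         insp_frac: float = DEFAULT_INSP_FRAC,
                         **labels) -> DiameterSeries:
    """Ground-truth 1-Hz diameter series for one recording.

    d(t) = d0 + slope*t + amp*cos(2 pi psi(t)) + eps,  t = 0, 1, ..., T-1,
    with psi the warped respiratory phase of ``pattern`` (minimum of the
    cosine at end-inspiration) and eps ~ N(0, noise_sd^2) i.i.d.
    """
    truth.validate(pattern.duration_s)
    t = np.arange(int(round(pattern.duration_s)), dtype=float)
    psi = pattern.phase(t, insp_frac=insp_frac)
    d = truth.d0 + truth.slope * t + truth.amp * np.cos(2.0 * np.pi * psi)
    if truth.noise_sd_diameter > 0:
        d = d + np.random.default_rng(seed).normal(0.0, truth.noise_sd_diameter, t.size)
    return DiameterSeries(d, condition=pattern.condition, **labels)


@dataclass
class SceneParams:
    """Rendering geometry for the B-mode-like phantom frames.

    Default calibration maps the 20-mm image depth over 400 rows
    (0.05 mm/pixel).  The lumen is hypoechoic (dark, gray level below the
    segmentation threshold of 70) on an echogenic tissue background.
    """

    image_size_px: tuple[int, int] = (400, 400)
    pixel_spacing_mm: float = 0.05
    lumen_center_px: tuple[float, float] | None = None
    aspect_ratio: float = 1.4
    orientation_deg: float = 0.0
    lumen_intensity: float = 30.0
    background_intensity: float = 160.0
    speckle_sd: float = 10.0
    seed: int | None = None

    def __post_init__(self):
        if self.pixel_spacing_mm <= 0:
            raise ConfigError("pixel_spacing_mm must be positive")
        if not self.lumen_intensity < self.background_intensity:
            raise ConfigError("lumen must be darker than background")
        if self.aspect_ratio < 1.0:
            raise ConfigError("aspect_ratio is major/minor and must be >= 1")
        if self.lumen_center_px is None:
            self.lumen_center_px = (self.image_size_px[0] / 2.0,
                                    self.image_size_px[1] / 2.0)


def render_frames(series: DiameterSeries, scene: SceneParams) -> ImageSequence:
    """Render one frame per diameter sample.

    The lumen is a filled ellipse whose minor axis is ``d(t)`` converted to
    pixels (major axis = aspect_ratio x minor, rotated by orientation_deg),
    drawn at ``lumen_intensity`` on a ``background_intensity`` field; seeded
    additive Gaussian speckle is applied to the whole frame and intensities
    are clipped to 8-bit integers.
    """
    rows, cols = scene.image_size_px
    r0, c0 = scene.lumen_center_px
    rng = np.random.default_rng(scene.seed)
    frames = np.empty((len(series), rows, cols), dtype=np.uint8)
    for i, d_mm in enumerate(series.values_mm):
        minor_r = d_mm / (2.0 * scene.pixel_spacing_mm)
        major_r = scene.aspect_ratio * minor_r
        if (r0 - major_r < 0 or r0 + major_r > rows
                or c0 - major_r < 0 or c0 + major_r > cols):
            raise ConfigError(
                f"frame {i}: ellipse (major radius {major_r:.1f} px) exceeds "
                f"frame bounds {scene.image_size_px}")
        frame = np.full((rows, cols), scene.background_intensity, dtype=float)
        rr, cc = draw_ellipse(r0, c0, minor_r, major_r, shape=(rows, cols),
                              rotation=np.deg2rad(scene.orientation_deg))
        frame[rr, cc] = scene.lumen_intensity
        if scene.speckle_sd > 0:
            frame = frame + rng.normal(0.0, scene.speckle_sd, frame.shape)
        frames[i] = np.clip(np.rint(frame), 0, 255).astype(np.uint8)
    return ImageSequence(frames, scene.pixel_spacing_mm)


# --------------------------------------------------------------------------
# Cohort-level generation
# --------------------------------------------------------------------------

@dataclass
class CohortDesign:
    """Statistical structure of the synthetic cohort.

    ``baseline_mm`` gives the target 50-s mean diameter per condition; the
    generator back-computes d0 so the recording mean (d0 + slope * 24.5)
    lands on it.  ``slope_mm_s`` and ``amp_mm`` set the tonic drift and
    phasic half-amplitude per condition.  Between-subject scatter is applied
    to d0 once per participant; ``within_cell_sd_mm`` jitters d0 per
    repetition.
    """

    baseline_mm: dict = field(default_factory=lambda: {
        Condition.SB: 2.55, Condition.PB3: 2.51, Condition.PB10: 2.43})
    slope_mm_s: dict = field(default_factory=lambda: {
        Condition.SB: 0.00022, Condition.PB3: 0.0014, Condition.PB10: 0.0045})
    amp_mm: dict = field(default_factory=lambda: {
        Condition.SB: 0.02, Condition.PB3: 0.025, Condition.PB10: 0.05})
    between_subject_sd_mm: float = 0.046
    within_cell_sd_mm: float = 0.03
    noise_sd_mm: float = 0.02
    duration_s: float = 50.0
    insp_frac: float = DEFAULT_INSP_FRAC
    resp_fs_hz: float = 100.0
    resp_temp_amp: float = 0.8
    resp_noise_sd: float = 0.02

    def normalized(self) -> "CohortDesign":
        self.baseline_mm = {Condition.coerce(k): v for k, v in self.baseline_mm.items()}
        self.slope_mm_s = {Condition.coerce(k): v for k, v in self.slope_mm_s.items()}
        self.amp_mm = {Condition.coerce(k): v for k, v in self.amp_mm.items()}
        return self


@dataclass
class Recording:
    """One labelled 50-s recording with its ground truth."""

    participant_id: str
    condition: Condition
    repetition: int
    pattern: BreathPattern
    truth: GroundTruth
    series: DiameterSeries
    respiration: RespirationTrace | None
    seed_key: tuple[int, int, int, int]

    def manifest_row(self) -> dict:
        return {
            "participant": self.participant_id,
            "condition": self.condition.value,
            "repetition": self.repetition,
            "d0": self.truth.d0,
            "slope": self.truth.slope,
            "amp": self.truth.amp,
            "noise_sd": self.truth.noise_sd_diameter,
            "seed_key": list(self.seed_key),
        }


@dataclass
class Cohort:
    """A full synthetic cohort plus its ground-truth manifest."""

    recordings: list
    design: CohortDesign
    seed: int

    def manifest(self) -> list[dict]:
        return [r.manifest_row() for r in self.recordings]

    def manifest_json(self) -> str:
        return json.dumps({"seed": self.seed, "recordings": self.manifest()},
                          indent=2, sort_keys=True)

    def save(self, directory) -> None:
        """Write manifest JSON plus per-recording diameter/respiration CSVs."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "manifest.json").write_text(self.manifest_json())
        for r in self.recordings:
            stem = f"{r.participant_id}_{r.condition.value}_r{r.repetition}"
            r.series.to_csv(directory / f"{stem}_diameter.csv")
            if r.respiration is not None:
                r.respiration.to_csv(directory / f"{stem}_respiration.csv")


def make_cohort(n_participants: int = 21, conditions=None, n_reps: int = 3,
                design: CohortDesign | None = None, seed: int = 0,
                include_respiration: bool = True) -> Cohort:
    """Generate the full labelled cohort (default 21 x 3 conditions x 3 reps).

    Per-recording seeds are derived deterministically from the master seed
    and the (participant, condition, repetition) indices, so any subset can
    be regenerated independently.
    """
    if n_participants < 2:
        raise ConfigError("need at least 2 participants")
    if conditions is None:
        conditions = [Condition.SB, Condition.PB3, Condition.PB10]
    conditions = [Condition.coerce(c) for c in conditions]
    design = (design or CohortDesign()).normalized()

    # one baseline offset per participant, shared across conditions/reps
    subj_rng = np.random.default_rng(_child_seeds(seed, 10**6, n=1)[0])
    subj_offsets = subj_rng.normal(0.0, design.between_subject_sd_mm, n_participants)

    t_mean = (round(design.duration_s) - 1) / 2.0   # mean of t over 0..T-1
    recordings = []
    for p in range(n_participants):
        pid = f"P{p + 1:02d}"
        for ci, cond in enumerate(conditions):
            for rep in range(1, n_reps + 1):
                key = (seed, p, ci, rep)
                s_pattern, s_series, s_resp, s_cell = _child_seeds(*key, n=4)
                cell_rng = np.random.default_rng(s_cell)
                slope = design.slope_mm_s[cond]
                d0 = (design.baseline_mm[cond] - slope * t_mean
                      + subj_offsets[p]
                      + cell_rng.normal(0.0, design.within_cell_sd_mm))
                truth = GroundTruth(d0=d0, slope=slope, amp=design.amp_mm[cond],
                                    noise_sd_diameter=design.noise_sd_mm)
                pattern = make_breath_pattern(cond, design.duration_s, seed=s_pattern)
                series = make_diameter_series(pattern, truth, seed=s_series,
                                              insp_frac=design.insp_frac,
                                              participant_id=pid, repetition=rep)
                resp = None
                if include_respiration:
                    resp = make_respiration_trace(
                        pattern, fs_hz=design.resp_fs_hz,
                        temp_amp=design.resp_temp_amp,
                        noise_sd=design.resp_noise_sd, seed=s_resp,
                        insp_frac=design.insp_frac)
                recordings.append(Recording(pid, cond, rep, pattern, truth,
                                            series, resp, key))
    return Cohort(recordings, design, seed)


def sample_baseline_matrix(n_participants: int, condition_offsets,
                           between_subject_sd: float, cell_sd: float,
                           seed: int = 0, n_reps: int = 3,
                           grand_mean: float = 2.55) -> np.ndarray:
    """Draw a participants x conditions matrix of repetition-averaged baselines.

    This is the statistical level of the cohort generator: participant
    intercept ~ N(grand_mean, between_subject_sd), plus the per-condition
    offset, plus rep-averaged cell noise N(0, cell_sd^2 / n_reps).  With all
    offsets zero it provides the null cohorts used for type-I calibration of
    the repeated-measures ANOVA.
    """
    offsets = np.asarray(list(condition_offsets), dtype=float)
    rng = np.random.default_rng(seed)
    subj = rng.normal(grand_mean, between_subject_sd, size=(n_participants, 1))
    noise = rng.normal(0.0, cell_sd / np.sqrt(n_reps),
                       size=(n_participants, offsets.size))
    return subj + offsets[None, :] + noise
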