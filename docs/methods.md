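# Methods

This note documents the models, conventions and numerical choices behind
`veinmod`, in the spirit of a package methods appendix: what is simulated,
what is estimated, which defaults matter, and what the synthetic results do
and do not show about real recordings.

## Diameter model

Each 50-s recording is a 1-Hz series

d(t) = d₀ + s·t + A·cos(2π·ψ(t)) + ε(t),  t = 0, 1, …, 49 s,

with baseline-at-onset d₀ (mm), tonic slope s (mm/s), phasic half-amplitude
A (mm) and i.i.d. Gaussian measurement noise ε with SD σ_d. ψ is the
respiratory phase, piecewise-linearly warped so the cosine minimum falls at
the inspiration→expiration transition and the maximum at the next onset:
the vein **contracts while breathing in and dilates while breathing out**.
Inspiration occupies the first 40 % of each cycle (I:E ≈ 1:1.5; the true
ratio is not known, so it is a configurable parameter `insp_frac`).

Breath timing per condition:

* **PB10 / PB3** — fixed 10-s / 3-s cycles, first onset at t = 0 (the
  recording starts on the pacing cue): 5 and 17 onsets in 50 s.
* **SB** — i.i.d. cycle lengths on [2, 8] s. The default distribution is a
  scaled Beta(2, 4.316), which has mean 3.9 s on that support; a triangular
  distribution on [2, 8] cannot have mean 3.9 (it would need mode 1.7 < 2),
  so Beta is the default and `uniform` / `triangular` (with configurable
  mode) remain options. Two further SB conventions keep the emulation
  well-posed:
  * recordings start mid-breath, 40–90 % through a virtual previous breath
    (i.e. during its expiration). Starting every recording exactly at an
    onset would phase-lock the cohort at t = 0 and put a spurious coherent
    ripple into the SB ensemble, which should be nearly flat;
  * no onset is placed in the final 1.5 s of the window (rejection
    sampling). A breath beginning at the record edge leaves no countable
    temperature peak inside the window, so the ground-truth breath count
    would otherwise be ill-defined for detector validation.

The nasal-temperature trace is a piecewise cosine per breath — maximal at
inspiration onset, minimal at the inspiration→expiration transition —
sampled at 100 Hz with peak-to-peak swing `temp_amp` (default 0.8 °C around
34 °C) plus additive Gaussian noise.

## Cohort design (the generator's study conditions)

Defaults emulate the study-scale structure: 21 participants × 3 conditions
× 3 repetitions of 50 s.

| parameter | SB | PB3 | PB10 | note |
|---|---|---|---|---|
| 50-s baseline target (mm) | 2.55 | 2.51 | 2.43 | condition means |
| tonic slope s (mm/s) | 0.00022 | 0.0014 | 0.0045 | see below |
| phasic half-amplitude A (mm) | 0.02 | 0.025 | 0.05 | PB10 = 2 × PB3 |

d₀ is back-computed as baseline − s·24.5 so the 50-s mean hits the target
regardless of slope. Between-subject scatter of d₀ is N(0, 0.046²) mm —
from the reported baseline standard errors (~0.01 mm at n = 21,
SD = √21 × 0.01). Repetition-to-repetition jitter is N(0, 0.03²) mm and the
1-Hz measurement noise SD is 0.02 mm. The robustness simulations in the
acceptance suite deliberately use a much larger between-subject SD
(0.3 mm) with the same condition offsets (0, −0.04, −0.12 mm); the
within-subject tests are insensitive to the between-subject scale, which is
exactly what those simulations demonstrate.

The phasic amplitudes are not reported as numbers anywhere, so they were
chosen once: PB10 twice PB3 (the direction of the spectral comparison, and
a factor giving a 2·ln 2 log-power separation), SB slightly below PB3.

The slopes are calibrated so the ensemble-trend determination coefficients
come out near the study-scale values (r² ≈ 0.39/0.55/0.77). With the
ensemble of 63 recordings per condition, r² = s²·Var(t) / (s²·Var(t) + v)
where Var(t) = 208.25 s² and v is the residual variance of the ensemble
mean around the line: the phase-locked cosine variance for paced conditions
(A²/2, plus averaged noise), and for SB the measured residual of the
random-phase ensemble (≈1.6×10⁻⁵ mm²; the naive pointwise-independent
estimate underestimates it because the phase-mixture residual is a smooth
correlated process). Inverting that relation gives the table's slopes.
Realized r² still varies by cohort seed (SB roughly 0.25–0.35, PB10 ≈ 0.77).

Per-recording seeds derive deterministically from
(master seed, participant, condition, repetition) via `SeedSequence`, so
any recording can be regenerated in isolation and two runs with the same
master seed are identical.

## Rendering and segmentation

Frames are a two-level phantom: a dark elliptical lumen (gray 30) on a
bright tissue background (gray 160) with additive Gaussian speckle
(SD 10 gray levels), clipped to 8-bit. The minor axis lies along image rows
and equals d(t)/0.05 px at the default calibration (20 mm depth over 400
rows). This deliberately ignores point-spread functions, attenuation and
probe compression: it validates the *geometry* of the measurement chain,
not ultrasound physics, so segmentation accuracy on these phantoms is an
upper bound on real-image accuracy.

Segmentation thresholds strictly below 70 inside the ROI (lumen is
hypoechoic; the threshold's direction is fixed by that), keeps the largest
4-connected component, fills holes, and fits the moment ellipse. The axes
are rescaled to preserve area (π·(a/2)·(b/2) = pixel count), matching the
convention of common particle-analysis tools; since the short diameter "from
the ellipse's area" admits a second reading, an `equivalent_circle` mode
(2·√(area/π)) is available via `diameter_mode`. Frames where the fixed
threshold leaves < 5 pixels retry with Otsu's threshold inside the ROI
(flag `fallback_threshold`) — a deterministic stand-in for per-image manual
threshold optimization — and frames that still fail are flagged `missing`
and linearly interpolated between valid neighbours (edge hold at the
boundaries). On noise-free phantoms the round trip is accurate to well
under one pixel equivalent (≤ 0.02 mm observed, 0.05 mm bound).

## Breath detection

The 100-Hz trace is smoothed with a 0.5-s centered moving average
(truncated at the edges) — long enough to suppress sensor noise, short
enough to pass 2-s cycles — then local maxima are taken with prominence
≥ 20 % of the smoothed peak-to-peak swing and separation ≥ 1.5 s (below the
fastest 2-s spontaneous cycle). The trace is padded on the left so the
paced onset at t = 0 is detectable; the right edge is not padded, so a
temperature rise running into the end of the record (toward an onset beyond
it) is not counted. These parameters are exposed in the pipeline
configuration; they are a reproducible stand-in for whatever (possibly
visual) peak counting was used originally.

## Spectral estimation

Burg's recursion minimizes the summed forward and backward prediction error
with Levinson order updates; all reflection coefficients of a
non-degenerate input have |k| < 1, so the AR(7) model is stable. The sign
convention is the denominator polynomial 1 + Σ aₖ z⁻ᵏ (an AR(1) process
with lag coefficient 0.6 fits a₁ ≈ −0.6). Mean removal is the default
detrending — the within-recording drift is left in the series, mirroring
ensemble traces that retain it — and `detrend="linear"` is available for
sensitivity analysis. The one-sided PSD carries a factor 2 so its
trapezoidal integral over [0, 0.5] Hz matches the detrended sample variance
(Burg's energy recursion makes this nearly exact; 10 % is the contractual
bound). The default frequency grid is 0.1 mHz steps, ≥ 20 points across
each 2-mHz analysis band; band power is a trapezoidal integral and its log
is exactly equivariant under amplitude scaling (log power shifts by
2·ln k). Repetitions are averaged on the log scale, because the defined
magnitude *is* the log.

A 50-sample record is short; the AR(7) peak for a noise-free 0.1-Hz
sinusoid lands within ±5 mHz of the true frequency, which is why the
analysis bands are read as fixed 2-mHz windows rather than peak-tracking.

## Statistics

Paired t uses the n−1-denominator SD of the differences and the t
distribution with n−1 df; zero-variance differences raise a degenerate-test
error rather than returning t = ∞. The one-way repeated-measures ANOVA
decomposes SS_total = SS_subjects + SS_conditions + SS_error and refers
MS_cond/MS_error to F(k−1, (n−1)(k−1)); sphericity is assumed (no
Greenhouse–Geisser correction). Bonferroni adjustment multiplies each of
the k(k−1)/2 pairwise paired-t p-values by the number of comparisons,
capped at 1. Under null cohorts the ANOVA's type-I error is calibrated
(≈5 % at α = 0.05 over 2000 simulated cohorts). Baselines are summarised
as mean ± SE and log-powers as mean ± SD, the two figure conventions.

## Problem sizes

The simulation studies in the test suite use: 200 cohort seeds for each of
the phasic- and tonic-recovery power checks (21 participants each), 2000
seeds for the null ANOVA calibration (drawn at the baseline-matrix level of
the generator — the quantity under test is the ANOVA, not the renderer),
1000 noisy replicates for detector robustness, and 100 cohort seeds for
ensemble phase-cancellation. The acceptance script runs one full
21 × 3 × 3 cohort end to end, rendering and segmenting frames for one
participant's nine recordings as the imaging round-trip check.

## Known limitations

* The phantom renderer is geometric, not physical; segmentation results on
  it bound the pipeline's algorithmic error only.
* The SB cycle-length distribution, I:E ratio and phasic amplitudes are
  plausible choices, not measured quantities; they are all configurable.
* The breath detector cannot, in principle, count a breath whose onset
  falls within the last moments of the window; the generator's 1.5-s end
  guard makes the ground truth match what any trace-based counter can see.
* A single ROI and threshold serve all frames of a sequence; ROI drift,
  M-mode analysis and artery/vein discrimination are out of scope.
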