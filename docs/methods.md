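# Methods

`contrastnorm` models and analyzes the effect of divisive contrast
normalization on the amplitude *and* time-course of transient visual
interneuron responses, of the kind recorded with two-photon calcium imaging
in the *Drosophila* medulla (Mi1, Tm3, Tm1, Tm2; lamina neuron L1 as a
negative control). Because no real recordings ship with the package, every
analysis runs on synthetic data with known ground truth; this note explains
the model, the generator, the analysis chain, and what the passing checks
do and do not establish.

## The cascade model

A cell's response to a luminance step in its receptive-field (RF) center is
modelled as a three-stage cascade:

1. **Band-pass filter** — a first-order low-pass (τ_LP = 200 ms) followed
   by a first-order high-pass (τ_HP = 300 ms), producing the transient
   membrane response of a band-pass interneuron. Both stages use the exact
   exponential integrator `y ← y + (1 − e^(−Δt/τ))(x − y)`, which is
   unconditionally stable and insensitive to the simulation step. The
   stage order (LP then HP) is immaterial for linear time-invariant filters
   and fixed for reproducibility. First-order stages are an assumption; the
   qualitative conclusions do not depend on filter order.
2. **Divisive nonlinearity**, in one of two forms:
   - *static*: `y = x⁺ / (x⁺ + k)`, a memoryless saturation with
     half-saturation constant `k`;
   - *dynamic*: a conductance-based membrane update,

         V(t) = (x⁺(t−Δt)·E_exc + V(t−Δt)·C/Δt) / (x⁺(t−Δt) + k + C/Δt)

     with E_exc = 1, C/Δt = 100 and V(0) = 0. Here the drive `x⁺` is an
     excitatory conductance and `k` lumps the leak and the inhibitory
     conductance controlled by the visual surround (shunting inhibition:
     E_inh = E_leak = 0). Its fixed point under constant drive is the
     static form (`V* = x·E_exc/(x+k)`), but away from steady state `k`
     also sets the effective membrane time constant, ≈ (C/Δt)/(x⁺+k)
     simulation steps — strong normalization makes the response *faster*
     as well as smaller. With C/Δt → 0 the update degenerates to the
     static nonlinearity with a one-step lag.
   The drive is half-wave rectified before either nonlinearity: the
   band-pass output goes negative at pulse offset, the static form has a
   pole at x = −k, and a conductance cannot be negative.
3. **Calcium-indicator low-pass** (τ_Ca = 200 ms), standing in for GCaMP6f
   kinetics.

`k = 0.2` represents a static (gray or stationary-grating) surround,
`k = 1.0` a dynamic (moving-grating or stochastic-noise) surround. The
simulation step is Δt = 1 ms; C/Δt is specified as the ratio itself, so the
membrane time constant in *steps* is fixed by construction. The model is
never fitted to data.

Two model-level results anchor the package:

- **Static equivalence**: in static mode, scaling the input amplitude and
  `k` jointly leaves the response identical (to machine precision) —
  a static saturation cannot distinguish "weaker stimulus" from "stronger
  surround".
- **Dynamic non-equivalence**: in dynamic mode, *no* input amplitude under
  weak normalization reproduces the normalized response shape under strong
  normalization (max-abs mismatch > 0.02 over a 0.05–1.0 amplitude grid),
  and strong-normalization responses always decay to a lower end-of-pulse
  fraction of their peak. Response kinetics therefore diagnose the
  mechanism.

## Stimuli

The projection arena is approximated as a flat 180° × 105° degree grid of
64 × 52 pixels (azimuth pixels 2.81°, elevation pixels 2.02°; the grid and
extents force slightly anisotropic pixels). Only region membership and
temporal structure matter downstream, so no perspective or photometric
correction is applied.

- **RF-mapping noise**: independent per-pixel Gaussian luminance
  (mean 0.5, SD 0.25 — full range — clipped to [0, 1]) smoothed in time
  with a Gaussian of σ = 90 ms. The smoothing is divided out analytically
  so pixels stay independent with unit-variance statistics before scaling.
  A binarized variant is available; the Gaussian form is the default.
- **Center-step protocol** (6 s at 60 Hz by default): a circular 5° window
  at the RF center steps its luminance for 1 s (ON cells 0→amplitude, OFF
  cells 1→1−amplitude) between t = 3 s and 4 s; a 30° gray annulus (0.5)
  isolates the RF from the surround; beyond it one of four surrounds is
  shown from t = 0: uniform gray, a stationary full-contrast square-wave
  grating (20° wavelength), the same grating drifting at 1 Hz from
  t = 2 s, or binary pixel noise with a 10 Hz temporal cutoff (frozen
  until t = 2 s). All four have mean luminance 0.5 over a period; the
  center and annulus are bit-identical across conditions. The cutoff
  convention for binary noise generalizes the mapping stimulus'
  "90 ms σ per 1 Hz" correspondence. 60 Hz rendering (rather than the
  180 Hz of projector hardware) is ample for 200–300 ms filters and
  11.8 Hz acquisition.

## Synthetic recordings

Each simulated cell carries an archetype (polarity, per-condition `k`,
RF center and width, response gain ~2 ΔF/F per model unit) plus individual
lognormal variation: gain CV 0.1, `k` CV 0.25 (one factor per cell, applied
in every condition — a strongly normalizing cell is strong under every
surround), filter-τ CV 0.1. These CVs are test-power placeholders for
unreported biological variability, not measured values. RF widths follow
the reported FWHM of the modelled neurons (Mi1 29°, Tm3 12°, Tm1 27°,
Tm2 31°). The L1-like control uses the same `k` in all conditions.

A trial's raw trace is
`F = F₀·(1 + gain·response) + drift + noise`, resampled to the 11.8 Hz
acquisition rate, with F₀ = 100, Gaussian noise SD 5 (≈0.05 ΔF/F), and slow
drift (random-phase sinusoid plus a scaled random walk, amplitude ~2% of
baseline) to exercise the dynamic-baseline algorithm. A configurable
fraction of cells is "movement-corrupted": their trials each receive an
independent band-limited (<1 Hz) artifact of ~2 ΔF/F, producing the high
inter-trial variance the SNR criterion screens out. Three trials per
condition are simulated. All randomness derives from the run seed plus
stable per-(cell type, condition, cell, trial) labels, so any entity is
reproducible in isolation.

Mapping sessions project the noise movie's luminance deviation onto the
cell's spatial Gaussian RF (weights summing to 1), apply the calcium
low-pass and the same noise model (3 min at 11.8 Hz → 2124 samples).

What the generator does *not* emulate: raster-scan imaging frames, photon
shot noise, indicator nonlinearity beyond τ_Ca, response adaptation across
trials (presentation order is metadata only), and any nonlinear spatial
summation. The last point matters for RF mapping: under sum-normalized
linear pooling, a wide RF averages spatially independent noise toward
zero, so 3-minute sessions localize the narrow Tm3-like RF to within one
pixel but not the ~30°-FWHM archetypes — real wide-field cells are not
this pessimistic because their spatial summation is not linear.

## Analysis chain

- **ΔF/F**: F₀ is the 4-min-FWHM Gaussian smoothing of the 90 s sliding
  minimum of the 1 s-FWHM-smoothed raw trace; ΔF/F = (F − F₀)/F₀.
  Smoothing uses reflective padding with kernels truncated at ±4σ; windows
  longer than the trace clamp to its length (on a 6 s protocol trace the
  sliding minimum is effectively global, which is the intended degenerate
  behavior). Fluorescence must be strictly positive.
- **SNR criterion**: a recording (one cell × condition, ≥2 trials) passes
  if the SD over time of the trial-averaged ΔF/F is ≥115% of the
  time-averaged across-trial sample SD (ddof = 1 over the 3 trials). At
  default noise the clean pass rate is ~100%, fully corrupted populations
  are rejected ≥95% of the time.
- **RF estimation**: the kernel is the variance-normalized, mean-subtracted
  response-weighted average of stimulus deviations at lags 0–1 s (nearest-
  sample alignment of movie and response). The center is the half-max
  centroid of the peak-lag |kernel| map after a one-pixel Gaussian blur
  (raw STA maps are single-pixel-noise dominated; symmetric smoothing does
  not displace a symmetric field's centroid). FWHM = 2.355σ of a symmetric
  2-D Gaussian least-squares fit to the *unsmoothed* map (so an exact
  Gaussian map returns exactly 2.355σ), initialized from the centroid and
  half-max mass radius; fit failures fall back to the half-max-area radius
  and are logged.
- **Metrics**: per cell, trials are averaged and lightly smoothed
  (0.3 s-FWHM Gaussian) before metric extraction — the peak is a maximum
  statistic and would otherwise carry an upward noise bias; the noiseless
  reference passes through the identical chain, so shared attenuation
  cancels. Baseline is the mean over the 1 s preceding surround-dynamics
  onset (2–3 s) and is subtracted first. Peak amplitude is the maximum in
  the 3–4 s step window; relative peak is the cell's peak as a percentage
  of its gray-surround peak at full amplitude; decay level is the mean over
  0.9–1.1 s after step onset as a percentage of the condition's own peak
  (samples whose centers fall in the closed interval).
- **Statistics**: bootstrap 68% CIs of across-cell means (1,000 seeded
  resamples of cells, percentile method; measured coverage 68% ± 4% on
  Gaussian data at n = 30). Two-tailed Mann–Whitney U tests at α = 0.05
  compare each condition against the gray-surround reference, per cell
  type and metric; p-values are exact for min(n₁,n₂) ≤ 8 without ties,
  otherwise the normal approximation with tie and continuity corrections.
  Per-cell values are computed first and then averaged/tested (not grand-
  average traces), matching the across-cell degrees of freedom of the
  reported tests. No multiple-testing correction is applied.

## Parameter recovery and what passing shows

The recovery loop simulates 20-cell Tm3-like populations (3 trials,
default noise) under gray (k = 0.2) and moving-grating (k = 1.0) surrounds.
Across 50 seeded replicates the pipeline detects the headline pattern —
relative peak < 100%, faster decay under the dynamic surround, both
significant — in ≥90% of replicates (observed: 100%), and the L1-like
control shows no significant decay difference in ≥90% (observed: 100%).
For calibration, each noisy replicate is compared against its *own*
noise-free ground truth: the same seed regenerates the identical
heterogeneous cells without recording noise, and the measured
relative-peak and decay values of that clean population must fall inside
the noisy run's bootstrap 68% CIs (observed coverage ≈90–100%,
criterion ≥60%). The single nominal (un-jittered) cell is deliberately
not the recovery target: population means of nonlinear metrics differ
from the nominal cell's value by Jensen-type offsets that are properties
of heterogeneity, not estimator defects.

Passing these checks shows that the analysis chain is unbiased and
calibrated *under the generator's assumptions*. It does not validate the
cascade model against real recordings, and the simulated effect sizes
(relative peak ≈44%, decay ≈92% vs ≈65%) are model outputs, not the
measured percentages of any real cell type.

## Problem sizes and numerical choices

Replicate studies use 50 seeds; populations use 20 cells (14 for the L1
control, mirroring its reported sample size); model checks run at
Δt = 1 ms over 3 s windows; steady-state convergence is iterated for
40·(C/Δt)/(g+k) steps, which brings the slowest grid point below 1e−9.
Degenerate inputs are defined errors: non-positive fluorescence, empty
samples, all-zero kernels, zero-extent windows, and an all-zero
denominator in the membrane update all raise typed exceptions rather than
propagating NaNs. Normalization by a non-positive peak leaves a trace
unchanged (nothing to normalize); decay levels require a positive peak.

## Known limitations

- The flat-screen approximation ignores the arena's cylindrical geometry.
- The noise movie's [0, 1] clipping slightly distorts tails of the
  luminance distribution (≈2σ clip).
- RF FWHM estimates from noisy sessions are biased low by the noise floor
  of the STA map; only the exact-map closed form is asserted
  quantitatively.
- The real-data percentages of the modelled neurons are not reproduction
  targets anywhere in the package; all quantitative checks are against the
  package's own model and generator.
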