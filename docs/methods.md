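# Methods

This note documents the models, estimators and numerical choices behind
`phytosync`, and what the synthetic data generator does and does not
emulate.

## Signal model of the synthetic seedling

Each cell *j* carries a phase oscillator observed through

    B_j(t) = A_j · exp(−λ(t − t₀)) · (cos θ_j(t) + 1) + ε(t),
    dθ_j/dt = 2π/τ_j + (K/N_j) Σ_{k∈nbr(j)} sin(θ_k − θ_j) + √D · dW_t,

sampled on a uniform grid (default every 1.1 h from 29 h to 168 h of
constant light, matching a multi-day confocal movie that starts after
release from entrainment).  Parameters, with defaults and units:

| parameter | default | unit | meaning |
|---|---|---|---|
| τ_j | N(period_mean, period_sd²) per section | h | intrinsic period |
| anchor peak p_j | N(phase_mean, phase_sd²) per section | h | noise-free peak time; θ_j(p_j) ≡ 0 (mod 2π) |
| A_j | log-normal, mean 100, CV 0.3 | a.u. | single-cell amplitude |
| λ (damping_rate) | 0 | 1/h | single-cell amplitude decay |
| D (phase_diffusion) | 0 | rad²/h | Wiener phase jitter |
| K (coupling_K) | 0 | 1/h | sinusoidal coupling to neighbours within `neighbourhood_radius` |
| ε | N(0, 2²) | a.u. | additive measurement noise |

The default section panel (six sections, 642 cells) uses the cell counts
and 48–72 h peak-phase statistics of a wild-type seedling movie: root tip
n=242, 56.2 ± 5.0 h; lower root n=84, 58.0 ± 4.4 h; upper root n=46,
56.6 ± 4.5 h; lower hypocotyl n=114, 52.1 ± 1.5 h; upper hypocotyl n=53,
51.2 ± 1.1 h; cotyledon n=103, 55.6 ± 2.3 h.  Section period means follow
the spatial model (shoot 24 h, root 25.55 h, root tip 22.67 h).  Per-section
period SDs are not published at single-cell resolution; we default to 0.8 h
in the shoot and 1.5 h in the root/root tip, reflecting the observed higher
root variability.  Single-cell amplitude noise magnitudes are likewise free
parameters.

Two deliberate defaults:

- `phase_diffusion = 0`.  The per-section phase SDs already encode the
  observed *static* phase dispersion; adding Wiener jitter on top would
  double-count it.  Phase diffusion is the explicit dial for emulating
  progressive desynchronisation of the kind produced by low-molecule-number
  stochasticity in kinetic clock models (which are out of scope here); the
  generator's property suite verifies that the ensemble order parameter
  falls monotonically in D.
- In the uncoupled noise-free limit (K = D = σ_ε = 0) traces are *exact*
  sampled damped cosines (closed form, no integration), and pure Wiener
  jitter is added as exact Gaussian increments between sample times.  Only
  K > 0 requires Euler integration (default step 0.1 h).

**What the generator does not emulate:** molecular clock circuitry,
cell division and growth, optics (PSF, photon noise), tracking errors, and
any z-structure in periods.  Passing tests therefore validate the analysis
chain's correctness and statistical calibration, not its robustness to
those real-data artefacts.

The image-stack generator produces a root-shaped foreground (narrow root,
hypocotyl flare tapering by ≤ 1 px per side per row so that mask corners do
not mimic spikes under a 3×3 median) whose pixels oscillate with phase
delayed linearly along the root: a travelling wave with default speed
0.2 mm/h, chosen so the delay across the 3 mm root stays under one period
and per-row peak times do not wrap.  Hot pixels, uniform background and
Gaussian noise are added on top; the ground truth (mask, per-row peak time,
spike positions) is returned alongside.

## Rhythm metrics

Traces are linearly interpolated to a uniform grid (default 1 h) before
period analysis.  Two period estimators ship behind one contract:

1. **cosine-NLLS** — nonlinear least squares of the linearly detrended trace
   to `offset + a·cos(2πt/τ + φ)`, seeded by harmonic regression at the
   periodogram peak; goodness of fit is the relative RMS residual
   (0 = perfect).  Default acceptance threshold 1.0.
2. **Lomb–Scargle** — normalised periodogram peak on a dense period grid in
   the circadian band (15–35 h); goodness of fit is one minus the
   normalised peak power.  Default threshold 0.9.

The published analysis this mirrors used three estimators whose thresholds
are reported inconsistently between the methods text and the source-data
legends; the thresholds here are per-estimator configuration, with the
defaults above.  A cell is **rhythmic** iff every estimator passes *and*
the maximum pairwise period difference is ≤ 2.5 h (the consensus filter —
the contract at the heart of this module).  The reported consensus period
is the first-listed estimator's (the NLLS analogue).  Both estimators
recover a noiseless sinusoid's period to < 0.05 h over ≥ 4 cycles; the
contract asserted in tests is 0.5 h.

Peaks and troughs are detected on detrended data with `scipy.signal.
find_peaks` (minimum separation half the consensus period; prominence 10 %
of the range).  When sampling is ≤ 1.5 h the data are first smoothed by a
robust local *quadratic* regression (tricube weights, two bisquare
re-weighting passes over a ~6 h window) — hand-rolled because the available
lowess implementations are locally linear.  Amplitude is the mean of all
successive trough→peak and peak→trough excursions, reported only for cells
with ≥ 3 peaks whose peak and trough counts differ by at most one.

Period variability follows peak-interval definitions (the cited original
formulae are unpublished): within-cell = mean over cells of the SD of
successive peak-to-peak intervals; between-cell = SD over cells of the
per-cell mean interval.

Overlap de-duplication removes, in any spatial overlap of two imaged
sections' bounding boxes, the cells assigned to the section with the larger
origin (lexicographic (y₀, x₀) comparison; ties broken toward keeping).

Per-section phase statistics use each rhythmic cell's *earliest* detected
peak in a window (default 48–72 h).  Note a structural subtlety: when the
window is wider than a section's period (root tip: ~22.7 h < 24 h) peak
times fold modulo the period, so the recovered SD is a property of the
windowed statistic, not exactly the anchor SD; Monte-Carlo over seeds puts
the root-tip estimand at 5.07 ± 0.24 h for an injected 5.0 h.

## Synchrony and coupling

Phases are extracted by sliding a one-period window across the trace and
least-squares fitting an offset cosine of the cell's consensus period;
windows with coefficient of determination ≥ 0.7 contribute peak-time
candidates, candidates closer than τ/2 are averaged, and the unwrapped
phase grows linearly between consecutive peaks with θ(t_k) = 2πk.  The
per-cell integer offset k is immaterial downstream because the order
parameter uses θ modulo 2π.

For a spherical neighbourhood (closed ball, radius r) around a centroid
cell, R(t) is computed on the intersection of the members' time supports
(linear interpolation of unwrapped θ), the synchrony slope is the OLS slope
of R on t, and density is ρ = N/((4/3)πr³).  The synchronisation index is
returned as the square root of the printed variance ratio
Var(M)/mean_j Var(x_j) over a sliding 24 h window, so that identical traces
give 1 under either convention; the raw ratio is available via
`return_ratio=True`.

Coupling estimation simulates the all-to-all (1/N) Kuramoto model with
ω_j = 2π/τ_j and θ_j(0) read from the data at the common start, Euler step
0.1 h, increasing K geometrically (×1.25) from 0.002 until the simulated
R-slope reaches the observed slope (≥, so that a fully synchronised
ensemble with slope 0 terminates at the smallest K); the search fails
loudly at K_max = 10 carrying the last slope.  Two caveats the test suite
makes explicit:

- The method assumes each cell's estimated period is unaffected by its
  neighbours.  Under strong coupling this fails in an instructive way:
  periods refit from synchronising traces encode the catch-up drift, and a
  simulation seeded with them reproduces the observed synchronisation at
  *any* K.  The recovery oracle therefore runs in the weak-coupling regime
  (K* = 0.02 1/h ≈ the critical coupling for a 1 h period SD) and supplies
  the generator's drawn intrinsic periods; recovered K is within a factor
  of two of truth (geometric mean over 10 ensembles, ratio ≈ 1.2).
- The simulated slope is monotone in K only before saturation (once R → 1
  within the window, larger K lowers the regression slope); slopes are
  therefore measured over an early window (48 h in the oracle) and the
  search stops at the *first* crossing.

## Spatial wave model

A symmetric occupancy grid (default 60 rows × 10 columns; root tip rows
0–5, shoot the top 14 rows, root between; root 4 cells wide, shoot 10)
carries one oscillator per occupied cell with the section's intrinsic
frequency and Moore-neighbourhood coupling — the plain sum over the 8
occupied neighbours, no normalisation, no wraparound, K = 1.  Integration
is Euler with dt = 0.05 h (halving dt changes R(t) by < 10⁻²); initial
phases default to zero (release from entrainment), with a seeded-random
option.  Bioluminescence is B = cos θ + 1; the space-time plot sums B per
row and normalises each row to its own maximum.  Released from uniform
phase, the fast root tip pulls its neighbourhood early and the long-period
mid-root lags both ends: the latest first-cycle peak falls strictly inside
the root (row ~16 of 60 in the default run) — the bow wave.

## Image pipeline

Stages run in the order: 3×3 median despike per frame (reflective edges) →
per-frame mean-grey-level segmentation (strictly above the mean; ties to
background; constant frames yield an empty mask with a warning) →
per-pixel zero-phase Butterworth low-pass (3rd order, 15 % of Nyquist,
`filtfilt` with even-reflection padding of 3×(order+1) samples; DC gain 1,
and the forward–backward pass squares the −3 dB point so a sinusoid at the
cutoff emerges at exactly half amplitude) → per-pixel amplitude de-trending
(mean removed, then the moving peak-to-trough range over one dominant
period divided out; the envelope is held constant over the first and last
period, where a sliding window sees less than a full cycle; series without
a pronounced spectral peak spanning ≥ 2 cycles are returned mean-centred
with a warning) → per-row maximum over in-mask pixels per frame, rows
normalised to their own peak.  De-trending before the max-projection is the
default (mirroring the order the measures are described in); a flag selects
the alternative.  Manual curation steps of real movies (ROI cropping,
removal of intruding cotyledons) are explicit inputs, never guessed.

Peak timing is read from each row's *first local maximum after one full
period*: zero-phase filtering reflects the signal at t = 0, which merges
first-cycle peaks with their mirror image, while later cycles are clean.
With this convention the end-to-end pipeline recovers an injected wave's
direction and speed with per-row peak errors under one frame interval, in
both directions.

## Problem sizes

Defaults were chosen at desk scale: 642-cell seedlings (seconds through the
rhythm pipeline), 10-cell coupling ensembles over 120 h, a 600-cell
template over 200 h, and 96-frame 80×40 px stacks.  The full test suite
runs in well under a minute of CPU apart from the stochastic recovery
checks (a few minutes total).

## Known limitations

- The consensus filter's verdict on marginal cells depends on the
  configured GOF thresholds; the published thresholds are internally
  inconsistent, so ours are configuration with documented defaults.
- Coupling estimates are only meaningful in the weak-coupling regime (see
  above); in strongly coupled ensembles the method returns its floor.
- The variability statistics are peak-interval definitions and may differ
  numerically from published figures computed with the original
  (unpublished) estimator.
- The image pipeline assumes a vertically oriented seedling in a fixed ROI;
  there is no automatic seedling detection, growth correction or photon
  physics.
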