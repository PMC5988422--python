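# phytosync

Single-cell circadian rhythm, synchrony and spatial-wave analysis for plant
seedlings — with a synthetic-seedling data generator so that every stage of
the pipeline can be exercised and validated without microscopy data.

## The problem

Whole-plant measurements of clock-gene reporters (e.g. *CCA1*) in constant
light show damped oscillations, yet individual cells keep oscillating
robustly.  The damping arises from *desynchronisation*: cells in different
parts of the seedling run at different intrinsic periods and peak at
different phases, producing two travelling waves of clock gene expression —
one moving down the root from the shoot, one up from the fast root tip —
that meet mid-root as a "bow wave".  `phytosync` implements the analysis
chain used to quantify this behaviour from single-cell fluorescence traces
and luciferase movies, plus the phase-oscillator model that reproduces it:

- **Rhythm metrics** — per-cell period estimation with a *consensus*
  rhythmicity filter: a cell is rhythmic only if every configured estimator
  (a cosine nonlinear-least-squares fit and a Lomb–Scargle spectral
  estimator ship by default) finds a circadian period with acceptable
  goodness of fit and all estimates agree pairwise within 2.5 h.  Amplitude
  (mean of successive trough→peak / peak→trough excursions, requiring ≥ 3
  peaks), within/between-cell period variability, spatial-overlap
  de-duplication, and per-section peak-phase statistics in a 48–72 h window.
- **Synchrony** — phase extraction by sliding cosine fits
  (θ_j(t) = 2πk + 2π·(t−t_k)/(t_{k+1}−t_k) between detected peaks), the
  Kuramoto order parameter R(t) = |⟨e^{−iθ_j}⟩|, a model-free windowed
  synchronisation index R² = Var(M)/mean_j Var(x_j), spherical-neighbourhood
  synchrony curves with cell density ρ = N/(4/3 πr³), and coupling-strength
  estimation: simulate dθ_j/dt = ω_j + (K/N)Σ_k sin(θ_k−θ_j) from
  data-derived ω_j, θ_j(0) at slowly increasing K (from 0.002, Euler
  dt = 0.1 h) until the simulated slope of R(t) reaches the observed one.
- **Spatial wave model** — a 2-D seedling template of Kuramoto oscillators
  with Moore-neighbourhood coupling (K = 1), section periods 24 h (shoot),
  25.55 h (root), 22.67 h (root tip); bioluminescence B = cos θ + 1 and
  per-row peak-normalised space-time plots.
- **Luciferase image pipeline** — per-frame mean-grey segmentation, 3×3
  median despiking, zero-phase 3rd-order Butterworth low-pass at 15 % of
  Nyquist, amplitude de-trending by envelope division, and the
  max-per-longitudinal-section space-time plot.
- **Synthetic seedling generator** — cell layouts, phase/period-structured
  cosine traces B_j(t) = A_j e^{−λt}(cos θ_j(t) + 1) + ε with optional phase
  diffusion, damping and cell-to-cell coupling, and a root-shaped image
  stack carrying a travelling wave of known speed with hot-pixel spikes.

## Worked example

```python
from phytosync import (GeneratorConfig, default_sections, generate_layout,
                       generate_traces, assess_rhythmicity, interpolate_trace,
                       section_phase_stats)

sections = [s for s in default_sections()
            if s.section_name in ("upper_hypocotyl", "root_tip")]
cfg = GeneratorConfig(sections=sections, rng_seed=1)
traces = generate_traces(generate_layout(cfg), cfg)
results = [assess_rhythmicity(interpolate_trace(t)) for t in traces]
print(section_phase_stats(results))
```

prints (run as `examples/02_rhythm_analysis.py`):

```
295/295 cells pass the consensus rhythmicity filter
  root_tip         peak phase 56.8 +/- 5.2 h (n=242, 48-72 h window)
  upper_hypocotyl  peak phase 51.2 +/- 1.0 h (n=53, 48-72 h window)
```

The pipeline recovers the generator's section parameters: the upper
hypocotyl peaks early and tightly (51.2 ± 1.1 h injected), the root tip
late and broadly (56.2 ± 5.0 h injected) — the phase dispersion that damps
the mean root signal.  The `examples/` directory holds one short script per
capability (trace generation, rhythm analysis, synchrony and coupling
estimation, the spatial wave model, the image pipeline), each printing the
quantities it computes.

A thin CLI wraps the pipeline driver:

```sh
phytosync all --seed 1 --out run/          # simulate → rhythm → synchrony → model → space-time
phytosync rhythm --traces traces.csv --out results.csv
```

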