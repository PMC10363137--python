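# Methods

## Tissue model

Membrane potential `u` (dimensionless: rest ≈ 0, peak ≈ 1.3) obeys the
monodomain reaction–diffusion equation with isotropic diffusion
`D = 0.25 cm²/s` (0.025 mm²/ms internally; both study scenarios use this
value).  The ionic term is the three-current Fenton–Karma formulation:

```
J_fi = −v·θ(u−u_c)·(1−u)(u−u_c)/τ_d          fast inward
J_so =  u·θ(u_c−u)/τ_0 + θ(u−u_c)/τ_r        slow outward
J_si = −w·(1+tanh(k(u−u_csi)))/(2τ_si)       slow inward
dv/dt = θ(u_c−u)(1−v)/τ_v−(u) − θ(u−u_c)·v/τ_v+
dw/dt = θ(u_c−u)(1−w)/τ_w−    − θ(u−u_c)·w/τ_w+
```

with `τ_v−(u)` switching between two constants at `u_v`.  Three published
parameter fits are bundled (`fk1998-br`, `fk2002-set4`, `fk2002-set8`);
`set4` supports long-lived spirals that pin spatially, `set8` supports
spiral breakup, which is how the arrhythmia classes below are realised.
Single-cell action potentials last ≈ 250 ms (`set4`) and ≈ 180 ms (`set8`);
plane-wave conduction velocity is ≈ 0.16 mm/ms at the default diffusion.

**Numerics.** Forward Euler with a masked 5-point Laplacian.  Missing or
damaged neighbours contribute zero flux, which implements the no-flux
condition at the sheet border and at every healthy/damaged interface;
damaged nodes are held at rest.  The explicit stability bound
`Δt ≤ Δx²/(4D)` is enforced at configuration time.  Grids/steps follow the
study conditions: Δx = 0.25 mm, Δt = 0.1 ms for the large paced sheet;
Δx = 0.2 mm, Δt = 0.05 ms for the atrium-sized scarred sheets.  The
slow-inward gating factor is evaluated from an 8192-knot linear
interpolation table over `u ∈ [−1, 3]` (max absolute error < 5·10⁻⁸, orders
of magnitude below the Euler discretisation error); this removes the
dominating transcendental call from the inner loop.  Halving Δt changes a
500 ms paced trace by < 2% RMS (tested).

**Scar construction.**  Two concentric circles; nodes inside the inner
radius are damaged with probability `p`, within the ring with probability
decaying linearly from `p` to 0 at the outer radius.  Masks are drawn from a
seeded generator and are bit-reproducible.

**Stimulation.**  Pulses are rectangular in space and time, possibly
periodic.  The rapidly paced scenario drives a 3×3 mm central patch at a
31 ms period with amplitude 0.3/ms for 2 ms: at this extreme rate the patch
acts as a relaxation oscillator that emits waves at its own recovery-limited
rate (~180–380 ms); stronger pulses (0.8/ms × 2 ms) hold the patch
permanently depolarised and extinguish propagation, which is why the gentler
default was chosen.  Re-entry in the scarred scenario is induced by an S1–S2
cross-field protocol (plane wave from the left edge, then a half-domain
pulse inside the vulnerable window; default S2 at 280 ms for `set4`, 235 ms
for `set8`, jittered ±6 ms by seed so repeated seeds sample genuinely
different dynamics).

## Study scenarios

**Scenario 1 (paced sheet).**  Default 12.5×12.5 cm (the methods-text size;
the figure-caption size 12×12 cm is configurable).  The reduced 6×6 cm sheet
used by the test suite and the acceptance script produces regular rapid
target-wave activation rather than the full-size mixture of rotors and
wavebreak; the bulk property analysed on it — recurrence determinism DET
above 0.9 essentially everywhere — is insensitive to this scale reduction.

**Scenario 2 (scarred atrium-sized sheets).**  4×4 cm.  Four arrhythmia
classes are provided as curated (parameter set, scar, S2 timing, analysis
window) combinations, because the class is a property of the dynamics
*within the analysed second* (exactly as class labels are assigned by
inspecting activation movies):

| class | recipe | verified phenotype |
|---|---|---|
| `anchored_rotor` | `set4`, dense central scar (r 2.5/4.5 mm), window 1–2 s | one spatially fixed phase singularity (pinned fraction ≈ 0.95), regular re-entrant activation dominating the sheet |
| `meandering_rotor` | `set8`, no scar, window 0.3–1.3 s | a single free spiral whose tip wanders (pinned fraction ≈ 0.1–0.35) |
| `fibrillation` | `set8`, no scar, window 2.4–3.4 s | the same tissue after fragmentation: 8–12 transient singularities |
| `fibrillation_with_anchored_rotor` | `set4` scarred tissue, window 2.4–3.4 s | the pinned rotor persists while wavebreak floods distal tissue |

Scanning scar severities (damage probability and radius, as in a
damage-magnitude sweep) produced either full stabilisation or full
fibrillation and only rarely the coexistence class, consistent with the
known rarity of rotor-driven fibrillation; anchoring the analysis windows to
the natural temporal evolution of two robust configurations proved far more
reproducible across seeds.  Class labels are verified by a
phase-singularity tracking heuristic (Hilbert-transform phase, ±2π winding
number on 2×2 plaquettes, spatial visit histogram); this tracker is
auxiliary scaffolding, not part of the RQA method itself.

## Trace analysis

All metrics are computed from 1000-sample, 1000 Hz membrane-potential
traces.

* **Delay embedding.**  Lag = first non-positive sample-autocorrelation lag
  (capped at N/4 with a warning flag); dimension = Cao's method, scanning
  E1(m) = E(m+1)/E(m) until |E1(m+1) − E1(m)| < 0.05 (m_max = 10).  E(m) is
  evaluated lazily and the scan stops at saturation.  Nearest-neighbour
  distances below 10⁻⁸ × trace range are treated as the "zero distances" of
  the original formulation — noise-free periodic traces repeat exactly up to
  float rounding, and without this guard the E1 curve is dominated by
  rounding noise.  Embedding parameters are estimated per site.
* **Recurrence plots.**  Euclidean norm, strict inequality
  (θ(x) = 0 for x ≤ 0), ε = 3% of the scalar trace range.  The line of
  identity (LOI) is excluded from the recurrence rate and all diagonal
  statistics (otherwise L_max ≡ N and threshold rules on it would be
  vacuous); vertical statistics are computed on the raw matrix with
  numerator and denominator drawn from the same point set, so LAM ∈ [0, 1].
  Minimum line lengths l_min = v_min = 2; ENTR is the natural-log Shannon
  entropy of the diagonal length distribution (l ≥ l_min); no Theiler window
  beyond the LOI.  Eigenvalues are the two algebraically largest of the raw
  0/1 matrix (LOI included), computed densely below N = 200 and by sparse
  Lanczos above.
* **Entropies.**  ApEn per Pincus (self-matches included), SampEn per
  Richman–Moorman (−ln(A/B), self-matches excluded, undefined counts
  reported as missing), both with m = 2, r = 0.2·SD, Chebyshev distance.
* **Organization index.**  Mean-removed Hann periodogram restricted to
  0.5–40 Hz (wide enough to contain every physiologic activation rate seen
  in the simulations); peaks are local maxima; each peak integrates power
  within ±1 Hz of its frequency — about the taper's main-lobe width at 1-s
  records, so a pure in-band tone concentrates ≥ 95% of band power in one
  peak.  OI_n sums the n top peaks over a union of bins (never counting a
  bin twice), hence OI_n ≤ 1 and non-decreasing in n.  Harmonics are *not*
  grouped with their fundamental.

**Site validity.**  Sites are excluded when the trace is constant, too short
to embed, or — physiologically — when its peak-to-peak range stays below 0.1
dimensionless units: such a site saw no action potential, only sub-threshold
electrotonic leakage (typically islands shielded inside a scar border zone),
and recurrence analysis of rounding-scale wiggles is meaningless.

## Spatial analysis

Metric maps are built on every `stride`-th simulation node per axis
(stride 2 on the 0.2 mm grid = the 0.4 mm fine-analysis spacing; the bundled
tests use 2 mm grids to keep runtimes practical and the class separations
hold there).  Moran's I uses binary Moore-neighbourhood weights (8
surrounding cells, `w_ii = 0`), restricted to valid sites, and is computed
on *unsmoothed* maps (the 3×3 masked-mean smoothing is a visualisation aid;
a config flag applies it first if desired).  Constant maps make Moran's I
undefined (reported missing, never coerced to 0).

## Rotor detection and classification

A site belongs to the pinned-rotor mask when `L_max ≥ 800` samples **and**
`L_mean > 15` (both config-exposed; units are RP samples ≙ ms at 1000 Hz).
Components are 8-connected, consistent with the Moore neighbourhood used
elsewhere.  Near a spatially fixed rotor the membrane potential repeats
almost perfectly for most of the analysis window, which only such rotors
achieve — regular paced regions fail the L_mean bound, transient rotors fail
the L_max bound.

Per-simulation feature vectors hold the spatial mean and Moran's I of each
requested metric.  On the curated fixtures (three seeds per class, 2 mm site
grids) the Moran's I of DET orders anchored (≈ 0.39–0.43) >
fibrillation-with-anchored-rotor (≈ 0.19–0.27) > fibrillation (≈ 0.00–0.06),
and the anchored class is separable from every other class in the
(mean DET, Moran's I of DET) plane; both behaviours are asserted by the test
suite, which also checks that the separation survives coarsening the site
spacing to 1.2 mm.  k-means clustering (z-scored features, fixed seed,
Hungarian matching against known labels for scoring) is provided for
automatic classification experiments.

## Problem sizes used by the bundled checks

The test suite and acceptance script run reduced problems chosen as the
smallest sizes at which each scientific property is stable: a 6×6 cm paced
sheet with a 20×20 site grid for the bulk-DET property; 4×4 cm class
fixtures at three seeds per class with 2 mm feature grids; 1 mm grids for
rotor detection; 1.2 mm and 4 mm grids for the resolution study.  The
paper-scale settings (12.5 cm sheet, 0.4 mm site spacing) remain the library
defaults for real studies.

## Known limitations

* Traces are noise-free; measurement noise would depress DET and the other
  determinism measures, and no noise-robust RQA variants are included.
* Isotropic homogeneous conduction, phenomenological ionic model, square
  sheets: none of the anatomical/electrophysiological heterogeneity of real
  atria.
* The reduced-scale paced sheet shows regular target waves only; the
  coexisting-rotor picture requires the full 12.5 cm domain.
* Exact Fenton–Karma parameter values are taken from published fits whose
  behaviour (stable pinned spirals vs. breakup) was verified in this solver;
  other discretisations may shift class boundaries (S2 timing, scar radii).
* Phase-singularity tracking assumes the Hilbert phase is meaningful at
  every active site; it is a labelling heuristic, not a validated tip
  detector, and purely anatomical re-entry around a large obstacle produces
  no free singularity at all.
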