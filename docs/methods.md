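# Methods

## Stimulus timing model

Every analysis in the package is locked to a periodic stimulus, so
protocols are stored as a timing skeleton only: ordered constant-speed
epochs, a cycle count, and the acquisition rate. Grating cycles have
exactly two epochs — slow then fast (still-fast 0→50 °/s with 6 s + 2 s
epochs at 30 Hz; slow-fast 10→50 °/s likewise; the two-photon variants use
50 + 50 frames at 267.27 ms/frame over 21 cycles). The analysis frequency
is 1/cycle (0.125 Hz for the 8-s widefield cycle). Durations given in
seconds are canonicalised to frames by round-to-nearest at the acquisition
rate. Frame indexing is 0-based; the cycle opens with the slow epoch, so
the speed-up (SU) transition sits at the first fast-epoch frame and the
slow-down (SD) transition at the cycle wrap (frame 0). Within a
steady-state periodic analysis this phase convention is arbitrary; it only
has to be applied consistently, and it is. The random-dot kinematogram is
represented solely by its 6-s-moving / 2-s-stationary envelope — dot motion
is never rendered because no stage consumes it.

## ISOI spectral analysis

Raw 12-bit frames at 30 Hz are binned 4× temporally and 2×2 spatially by
**summation**: 16 samples of ≤4095 reach at most 65520, exactly filling a
16-bit container, which is why summing (not averaging) is the default.
Each binned pixel's mean-subtracted time course is reduced to the discrete
Fourier coefficient at the bin nearest the stimulus frequency (at least two
whole cycles are required). Magnitude is reported as the single-sided
fractional modulation (2|c|/T)/mean, so a pure cosine of fractional
amplitude *a* yields exactly *a* — this makes ΔR/R dimensionless and
gain-invariant. Phase is arg c under the forward (e^{−iωt}) transform and
is used only relatively (retinotopy), so the sign convention is free but
fixed. Mean subtraction is the default detrend; an optional linear detrend
is available for drifting baselines. No hemodynamic-delay correction is
applied, so absolute retinotopic positions carry a common phase offset —
a known limitation that does not affect field-sign borders.

## Field-sign segmentation

Area borders appear as reversals of the retinotopic progression. The
visual field sign is computed per pixel as sign[∂φ_az/∂x·∂φ_el/∂y −
∂φ_az/∂y·∂φ_el/∂x]. Two numerical choices matter:

* **Wrapped-phase gradients.** Phase maps are lifted to the unit circle,
  weighted by response magnitude, Gaussian-smoothed there (default
  σ = 2 binned px), and the gradient of the argument is recovered as
  Im(z̄·∇z)/|z|². This avoids explicit unwrapping and its branch cuts, and
  the magnitude weighting stops meaningless background phase from bleeding
  into area rims (without it, rim artifacts can form spurious sign
  components large enough to derail labeling).
* **Support threshold.** Sign is only assigned where both maps' magnitude
  reaches 30 % of their in-map 95th percentile (and is strictly positive).
  The threshold and σ are configuration keys: the delineation step they
  automate is traditionally manual, so no published quantitative criterion
  exists and these defaults are engineering choices.

Connected components of constant sign (4-connectivity, ≥ 30 binned px) are
named by the stereotyped layout of mouse visual cortex: the largest
component is V1; the rest are ordered by distance from V1's centroid along
the anterolateral direction and named LM, AL, RL, with extras reported as
AREA_k. AM, PM and LI are deliberately not auto-labeled (they are not
reliably delineated by phase reversals). Manual label images can always be
loaded instead and take precedence, mirroring actual practice.

## Magnitude quantification

A duplicate of the magnitude map is filtered with a truncated Gaussian of
total width 5 px (σ = 5/4 px — the width is conventionally specified, the
σ is not, so it is a config key) and thresholded into a binary responsive
mask; the mask, never the filtered values, is applied to the original map.
The default threshold is 25 % of the filtered map's 99th percentile —
scale-free and robust to outlier pixels — and is recorded in every output.
Per-area means over (area ∩ mask) are divided by V1's mean; normalised
responses are emitted both as ratios and ×100 as percent, since published
values are quoted in % of V1 (e.g. 217 % ⇔ 2.17) without a stated
convention. Full-resolution manual ROIs are downsampled to binned geometry
by majority vote.

## Two-photon cellular analysis

Raw ROI traces are mean pixel values over each cell mask. ΔF/F uses
F0 = the 10th percentile of the raw trace by default (slow-epoch mean and
global mean are alternatives; the baseline definition is not standardised,
and the modulation statistics are invariant to additive ΔF/F offsets, so
the choice is benign). The first stimulus presentation is discarded
(21 → 20 retained cycles). Responsiveness is a one-way ANOVA between the
20 slow-epoch means and 20 fast-epoch means; with two groups F = t², so
this is exactly an unpaired two-tailed t test, and the null false-positive
rate calibrates to α. Cells failing the test are excluded, not
zero-filled. SU/SD modulation is computed on the cycle-averaged trace in
25-frame bins; by linearity this equals the per-cycle difference averaged
over cycles (the identity is tested). Useful exact identities: a
square-wave cycle gives su = −sd = the epoch difference; any
pure-fundamental cycle gives su + sd = 0; in quarter-cycle bin means
B1..B4, su = B3 − B2 and sd = B1 − B4. No neuropil subtraction, motion
correction or spike inference is performed.

## Synthetic data generator

The generator provides ground truth, not realism beyond what the analysis
assumes.

**Cortical scene.** A 128×128 canvas (kept small so the full pipeline runs
in seconds) holds elliptical areas V1 (posterior-medial, largest), LM, AL
and RL with linear retinotopic maps spanning 0–90° azimuth and 0–60°
elevation; mirror parity flips the azimuth gradient, so field sign
alternates +1/−1/+1/−1 along the V1→LM→AL→RL chain. Default fractional
modulation amplitudes are 0.010/0.007/0.008/0.004 (V1/LM/AL/RL) — ΔR/R of
order 1 % with HVAs below V1, typical of widefield recordings. Baseline
reflectance is 2000 counts on the 12-bit range.

**Widefield stacks.** The neural drive is the fast-epoch (or
moving-epoch) indicator convolved with a gamma-shaped hemodynamic kernel
(unit area, peak 2 s; only the stimulus-frequency Fourier coefficient
matters downstream, so any smooth causal kernel works and it is
configurable). The steady-state cycle is obtained by circular convolution
and normalised so its fundamental has single-sided amplitude 1 — an area
simulated with amplitude *a* therefore produces a magnitude of exactly
*a*, which makes recovery tests parameter-direct. Bar sweeps place a
wrapped-Gaussian response bump at the time the bar crosses each pixel's
mapped coordinate. Noise is i.i.d. Gaussian shot noise (sd 5 counts) plus
a low-rank spatially correlated 1/f field (8 global pink time courses ×
smooth random maps, amplitude 2 counts) emulating shared slow hemodynamic
drifts; per-pixel-independent pink noise is deliberately not modelled.
Frames are rounded and clipped to 12 bits by default; `quantize=False`
yields float stacks for analytic-precision tests, since 12-bit rounding
alone contributes ~10⁻³ rad of phase noise at these amplitudes. Vascular
and motion artifacts, bleaching and optical PSF are out of scope, so
passing tests say nothing about robustness to those.

**Calcium traces.** Each cell has a rate drive in ΔF/F units (a sustained
level r produces a fluorescence plateau of r after the unit-area kernel
settles): baseline 0.5, plus per-epoch steps, plus exponential transients
(τ = 1 s) launched at the transitions. The transients are essential: a
two-level piecewise-constant drive forces su ≈ −sd and cannot express
asymmetric patterns such as an SD-locked surge. The calcium kernel is a
difference of exponentials (rise 0.2 s, decay 1.8 s — GCaMP6s-like;
configurable). Gaussian mode adds noise (sd 0.1 ΔF/F per frame) to the
deterministic convolution; Poisson mode draws discrete events (0.2 ΔF/F
each) at the equivalent rate, with identical expectation. Negative drives
are truncated at zero with a warning. The four default effect profiles
(WT-like/AS-like × excitatory/inhibitory) were obtained by solving the
linear map from (fast-epoch step, SD transient) to measured (SU, SD)
modulation for representative published AL effect sizes — WT excitatory
(+0.044, −0.012), AS excitatory (−0.016, +0.022), WT inhibitory
(−0.044, +0.090), AS inhibitory (+0.0073, −0.0073) ΔF/F — so the
generator's clean traces land on those values by construction.
Populations add Gaussian jitter (sd 0.15 ΔF/F) to each cell's steps: a
unimodal simplification of the bimodal single-cell distributions seen in
vivo, adequate for population means but not for distribution-shape
analyses. Default population size is 300 cells per group, matching the
per-genotype cell counts of the cellular comparisons this emulates.

## Statistics layer

Student (pooled-variance) two-tailed t tests are the default — pooled df
(n₁ + n₂ − 2) is what reproduces printed degrees of freedom such as df = 20
for 11 vs 11 and df = 18 for 11 vs 9 — with Welch optional.
`t_from_summary` reconstructs t from printed mean ± SEM/n (SD = SEM·√n);
agreement with printed statistics is limited by input rounding, roughly 1 %
here. Two-way ANOVA uses statsmodels OLS: sequential sums of squares when
balanced (all types coincide), Type III with sum-to-zero contrasts when
not, the convention of the commercial package such analyses are usually
run in; the choice is logged in the result. Tukey HSD uses the
studentized-range distribution on cell means with pooled within-group
variance; Bonferroni multiplies by the number of comparisons actually
made. Zero-variance degeneracies return flagged, defined results (t = 0,
p = 1 for identical samples; p → 0 for a pure shift) rather than NaN. The
speed-curve design treats the four speed conditions as independent groups
(residual df = 80 for 2×4×11), although the same animals contribute to
all speeds — reproduced as printed, but a repeated-measures caveat worth
knowing; mixed-effects models are out of scope.

## Problem sizes and determinism

All generators are pure functions of (parameters, seed). Tests and the
acceptance script use 4-cycle widefield records (960 frames at 30 Hz,
128×128), 4-cycle bar sweeps per axis, 20-seed recovery loops for
segmentation/quantification, 2000 null cells for the α calibration, and
10–20 seeds × 4 populations × 300 cells for the effect-recovery loop —
sizes chosen so the full suite completes in a few minutes while leaving
Monte-Carlo margins well away from the pass thresholds. Deviations worth
restating: noiseless analytic checks use unquantized float stacks; strict
(fully interior) downsampling of ground-truth masks is used for
amplitude-recovery references so border-diluted binned pixels do not bias
the comparison.

## Known limitations

* Absolute retinotopy is phase-offset by the uncorrected hemodynamic
  delay; only relative phase (borders, field sign) is validated.
* Segmentation support/smoothing defaults are engineering choices, not
  derived from a published criterion; real maps with weak HVAs may need
  manual ROIs, which always take precedence.
* The synthetic RDK drive reuses the generic on/off envelope; whether real
  RDK responses follow that envelope is untested here.
* The ΔF/F peak-amplitude comparison between groups depends on the F0
  convention and is not part of the validated surface.
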