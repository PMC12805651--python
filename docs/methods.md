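# Methods

This note documents the models behind `xvlung`, the conventions and
defaults that shape its numbers, and what the synthetic phantoms do and do
not establish about real data.

## Specific ventilation and the scalar panel

Specific ventilation (SV) is the change in a lung voxel's volume across a
breath divided by its volume at the start of the breath (peak exhalation).
A phase series stores cumulative expansion relative to phase 0, so phase k
holds the expansion accumulated from peak exhalation up to phase k, and the
final phase is the full-breath SV on which the scalar panel is defined.

- **MSV** is the arithmetic mean of SV over the lung mask.
- **V_T** = Σ SV·v_voxel, reported in ml (mm³ × 10⁻³). This treats each
  voxel's fractional expansion times its resting volume as its air-volume
  contribution; it is a definition internal to this package rather than a
  property of any scanner.
- **VDP** counts voxels strictly below `threshold_fraction × reference_MSV`
  (default fraction 0.6). One operation covers both variants: with the
  animal's own MSV as reference it is VDP; with the control-population mean
  MSV it is nVDP. The control summary used for nVDP is the arithmetic mean
  of the control animals' MSVs.
- **VH** = IQR(SV)/MSV. Quantiles use linear interpolation between order
  statistics — the default of the major scientific computing environments —
  and the convention is configurable because VH depends on it. The same
  convention is used by the boxplot summaries so the two agree.

### Spatial-scale split

VH_SS and VH_LS separate intra-lobe texture from inter-lobe trends. The
field is smoothed with a Gaussian low-pass of standard deviation
`cutoff_mm` (default 2.0 mm, roughly the lobe scale of a mouse lung; the
boundary between "small" and "large" is a modeling choice, not a measured
constant). The smoothing is a *masked, renormalized* convolution:
numerator and denominator are Gaussian-filtered `field × mask` and `mask`,
so out-of-mask voxels carry zero weight and never leak into in-mask
averages. The high-pass component is the residual, making the
decomposition complementary by construction (low + high = original on the
mask to round-off).

VH_LS is the VH of the low-pass field. The high-pass residual has
approximately zero mean, so IQR/own-mean is unusable there; VH_SS is
therefore defined as IQR(high-pass)/mean(original). Both variants inherit
VH's invariance to positive rescaling of the field.

### ROI curves and coordinates

Voxel `(i, j, k)` occupies the half-open cell `[i·s, (i+1)·s)` per axis
with its center at `origin + (i + 0.5)·s`. ROI boxes are specified in mm
as half-open intervals; a voxel belongs to the ROI iff its center lies
inside. The ROI curve is the mean ± SD of SV over (mask ∩ ROI) at each
phase; with the whole-lung bounding box it reproduces the whole-lung
inflation curve exactly.

Degenerate inputs — empty masks, zero-mean fields, ROIs that miss the
lung, sub-voxel filter cutoffs, non-positive reference MSVs — raise errors
rather than returning sentinels.

## Lung mechanics

Commercial ventilator platforms do not publish their fitting internals, so
the package implements the literature-standard forms:

- **Single compartment**: `P = R·V̇ + V/C + P₀`, fitted by ordinary least
  squares of pressure on flow and volume. The simulator drives a sinusoidal
  volume waveform at 150 breaths/min (V_T 0.25 ml, PEEP 3 cmH₂O — typical
  settings for a ~25 g mouse) and optionally adds Gaussian pressure noise.
- **Constant phase**: `Z(f) = R_n + i·2πf·I + (G − iH)/(2πf)^α` with the
  standard tissue constraint `α = (2/π)·arctan(H/G)`, fitted by
  trust-region nonlinear least squares over (R_n, I, G, H) on stacked
  real/imaginary residuals, initialized from linearized estimates (R_n
  from the high-frequency real part, H from the low-frequency reactance).
  Default spectra use 13 log-spaced frequencies over 1–20.5 Hz, the usual
  mouse forced-oscillation band.
- **Pressure–volume**: the Salazar–Knowles exponential `V = A − B·e^(−K·P)`
  on the deflation limb, initialized by a log-linear fit. Static compliance
  is reported as C_st = B·K, the model slope at P = 0; K is the curvature.
  The K→0 limit is a flat valley in (A, B), so the iteration cap is
  generous (the well-determined product B·K converges long before A and B
  individually). Loop area is the shoelace polygon area of the closed PV
  loop, returned as a magnitude.
- **NPFE**: FVC is the trapezoidal integral of expiratory flow; FEV0.05
  integrates to exactly t = 0.05 s with linear interpolation at the
  boundary; FEF0.05 is the interpolated flow there. No body-temperature
  correction is applied.
- **Deep inflation**: IC = max volume − PEEP-baseline volume.

Every regression reports a coefficient of determination clipped to [0, 1]
(computed on stacked real+imaginary parts for the spectrum fit). Replicate
averaging excludes a parameter's replicate when its governing fit has
CoD < 0.9; the threshold itself passes. IC, loop area and the NPFE
quantities are direct measurements without a regression, so no CoD gate
applies to them. If all replicates of a parameter are excluded it is
missing (NaN), never zero, and missingness propagates through the study
table into pairwise-deleted statistics.

## Synthetic phantoms and cohorts

The generator targets the *statistical structure* the analysis assumes,
not biophysical fidelity — no airway tree, no tissue finite elements, no
projection physics.

- **Geometry**: two ellipsoidal lung fields with a midline gap on a
  32×18×40 grid of 0.4 mm voxels (~6000 lung voxels), semi-axes jittered a
  few percent per seed.
- **Dynamics**: healthy inflation follows
  `f(t) = (1 − e^(−3t))/(1 − e^(−3))` over normalized phase t — concave,
  rising fastest early in the breath and plateauing near peak inspiration,
  over ten phase points per breath by default. Voxel noise is multiplicative
  lognormal (σ = 0.25, unit mean), fixed per voxel across phases, which
  keeps SV positive with occasional near-zero voxels.
- **Tumor foci**: spheres (radius 0.4–1.0 mm) placed by rejection sampling
  on in-mask voxels, requiring at least half of each sphere inside the
  lung. Foci suppress SV amplitude (default ×0.3 of healthy), fill with a
  one-phase delay, and carry an early dip in which regional SV decreases
  between the first two post-baseline phases before recovering. Overlapping
  foci merge for burden accounting (unique voxels) but each planted sphere
  counts as one focus — histology counts discrete foci, and the generator
  mirrors that convention. CT gray is 200 in lung and 600 in foci
  (arbitrary scanner units, not calibrated HU) plus Gaussian noise.
- **Severity coupling**: a scalar in [0, 1] scales compliance-like
  parameters (C, C_st via B, IC, FVC) by `1 − λ·severity` and resistance/
  elastance-like parameters (R, R_n, G, H) by `1 + λ·severity`, λ = 0.5 by
  default. Severity also suppresses the *global* ventilation amplitude by
  `1 − 0.3·severity`: advanced disease stiffens tissue beyond the visible
  foci, and focal burden of a few percent alone cannot produce a
  whole-lung ventilation deficit. Default cohorts are 2 control / 3
  two-week / 3 three-week animals with severities 0, U(0.1, 0.3) and
  U(0.5, 0.9) and foci counts 0, 3–8 and 15–25 respectively; an optional
  flag drops one 3-week animal's mechanics to emulate an equipment
  failure.
- **Determinism**: one cohort seed; per-animal seeds derived via
  `SeedSequence`. The same (config, seed) reproduces byte-identical
  tables.

**What passing tests show — and don't.** The phantoms establish that the
metrics measure what they claim (oracle equivalence), that the fits
recover known parameters at realistic noise, and that the pipeline
recovers planted disease *directions* (ventilation and compliance down, CT
density and elastance up, negative compliance-vs-burden correlation).
They do not validate behavior on real reconstructions: registration
artifacts, cardiac motion, segmentation error, scanner calibration and
biological covariance between ventilation and mechanics are all absent.
One known divergence: planted patchy foci *raise* large-scale
heterogeneity in the phantom, whereas late-stage disease in vivo can
homogenize whole-lung motion and lower it; the phantom models focal
defects, not global remodeling of inflation dynamics.

## Statistics

The one-way group model is solved in closed form (in a single-factor
indicator design the OLS coefficients are exactly the group sample means
and the residual variance pools within-group squares); the test suite
cross-checks it against an independent OLS/Tukey implementation. Marginal
means carry t-based CIs on the pooled residual variance. Pairwise
contrasts use Tukey's HSD via the studentized-range distribution by
default (Bonferroni and unadjusted are available, and the method used is
always reported). With zero residual degrees of freedom, estimates are
returned and inference is marked unavailable.

t-tests are Welch (unequal variances). If both samples are constant, p is
1 when means agree and 0 otherwise — with no within-group variability the
difference is observed without sampling error; this degenerate-case policy
is documented rather than raising.

Correlations against tumor count use log10 counts. Animals with zero
tumors are excluded by default (log10(0) is undefined and controls are a
different population for this question); a `log1p` option keeps them via
log10(count + 1). Missing parameter values are deleted pairwise per
analysis throughout, so one animal's missing mechanics never removes its
imaging metrics from other analyses.

## Problem sizes

Defaults were chosen so a full study simulates in well under a second:
~23k-voxel grids, ten phases, 13-frequency spectra, 11-point PV limbs,
three replicates per maneuver. The acceptance script runs one full cohort,
20 repeated cohorts for directional recovery, and the three round-trip
fits — a few seconds end to end on one core.
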