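# Methods

`neurohcs` re-implements, as a tested library, the quantification chain of a
semi-high-content immunocytochemistry (ICC) experiment on rat primary
hippocampal and cortical cultures treated with an IRAP inhibitor: image
metrics from multi-channel 16-bit site images, efficiency-corrected qPCR
relative quantification, plate-reader viability normalization, and the
blocked ANOVA + Dunnett statistical plan.  Because no raw data from such
experiments are distributed with the package, every stage is validated on
synthetic plates with exact planted ground truth.  This note records the
models, the defaults, and the choices that were genuinely open.

## Study design encoded in the data model

One plate is one primary culture and one statistical unit (*n* = culture).
The default `PlateLayout` is the acquisition design: six treatment groups
(vehicle = 0.1% v/v DMSO plus 10⁻⁹…10⁻⁵ M inhibitor), three wells per
group, nine imaged sites per well — 27 sites per group per culture.  Sites
are technical replicates and are always averaged within (culture, group)
before any test.

## Image quantification

All intensities are raw camera grey levels; there is no background
subtraction, flat-fielding or rescaling anywhere, and every integrated
intensity (sum of grey values in an ROI) is accumulated in exact integer
arithmetic.

1. **Threshold calibration.** One grey-level threshold per channel role is
   calibrated per culture from a seeded random sample of sites (default 4)
   by pooling the per-role 16-bit histograms and maximising the
   between-class variance over all 65 536 candidate levels (exhaustive
   Otsu; foreground is `pixel >= t`, ties resolve to the lowest level).  A
   fixed-value override exists for manual calibration.
2. **Nuclei.** The DAPI channel is binarised and 8-connected components are
   filtered by area (default 30–500 px at the simulated 10x scale) and
   circularity 4πA/P² (default ≥ 0.3), then relabelled contiguously; the
   label count is the cell count.
3. **Soma-ROIs.** Each nucleus label grows by a disk (default radius 8 px;
   the desk-scale experiments use the generator's own radius).  Where
   dilations collide, each contested pixel goes to the *nearest original
   label*, ties to the lower id.  This rule is order-independent, unlike
   the sequential delete-after-measure behaviour of the original macro; a
   sequential fidelity mode (`dilate_labels_sequential`) reproduces
   overlapping ROIs, and the measurement step then counts shared pixels
   once, in the lower label, so the conservation identity below holds in
   both modes.
4. **MAP2 gating.** A cell is a neuron iff the fraction of its soma-ROI
   pixels at or above the MAP2 threshold exceeds 0.25.  "Low MAP2
   intensity" has no published definition; fraction-above-threshold was
   chosen over mean intensity because it is robust to MAP2 texture, and
   0.25 tolerates partially covered ROIs.  Both knobs are config-exposed.
5. **Drebrin partition.** `total` is the integrated intensity of the whole
   drebrin channel; soma-ROIs of gated neurons are measured in ascending
   label order with deletion after measurement; `axonal = total − soma`
   exactly (integer identity, checked on every input).  Axonal drebrin
   therefore includes background and glial signal, faithfully to the
   procedure it reproduces.
6. **Cell-type metrics.** MAP2 and GFAP thresholded pixel areas, their
   ratio (flagged missing when the GFAP area is zero, never infinite),
   neuron percentage = 100 x MAP2⁺ cells / all cells, GLUT4 overlay
   intensities inside each mask with per-pixel-area normalization, and
   thresholded per-cell intensities for vGluT1 / synapsin I / calcein
   (total above-threshold intensity divided by the nucleus count).
   Overlapping MAP2/GFAP pixels contribute to both overlays — the two
   masks are independent ROIs, not a partition.
7. **QC.** Sites are dropped when any channel has more than 1% saturated
   pixels or an Otsu-foreground fraction above 0.8 (an automated surrogate
   for the manual removal of debris-contaminated images, which had no
   published criterion).

## Synthetic plates

The generator emulates the *statistical* structure of the assay, not
microscope optics.  Cells are placed by rejection sampling with a minimum
centre separation; nuclei are disks (radius 4–6 px), neuron somata are the
morphological dilation of the nucleus mask (disk radius
`soma_dilation_px`, default 4), neurites are random-walk polylines 1–3 px
wide, astrocytes are multi-lobed blobs, and "other" cells carry DAPI only
(the MAP2⁻/GFAP⁻ population).  Structures are painted additively with
integer per-pixel intensities onto a flat background, then Gaussian-blurred
(PSF), then degraded by Poisson shot noise plus additive Gaussian read
noise, then clipped to 16 bits.  The ground truth records the pre-noise
scene: per-cell masks, per-structure painted intensities, per-channel
foreground areas, and the noiseless integrated intensity over the union of
true soma masks.

Two choices deserve emphasis:

* **Soma = dilated nucleus.**  Defining the true soma as the same
  morphological operation the pipeline applies makes "dilation radius
  matched to the generator" an exactly attainable condition, so zero-noise
  recovery of soma drebrin can be asserted tightly instead of "roughly".
* **Soma-ROI truth includes background.**  The pipeline's soma measurement
  deliberately includes background and crossing neurites (no background
  correction exists anywhere); the truth therefore also records the full
  noiseless scene integral over the soma union, which is the correct
  oracle for that measurement.

Region defaults encode the observed composition contrast: hippocampal
scenes use neuron fraction 0.35 (neurons a minority), cortical 0.60
(neurons a majority); astrocyte fractions 0.25 and 0.15.  These reproduce
the *direction* of the regional difference, not any particular magnitude.
Cell-type counts are rounded deterministically from the fractions so that
composition recovery can be asserted exactly.

Treatment effects are planted as per-group multiplicative factors on scene
parameters (`EffectModel`); vehicle factors must equal 1.  The canned
demo/power experiment plants a 1.5x factor on soma drebrin intensity at
1 µM.

**Desk-scale conditions.**  Simulation-heavy validation (effect-recovery
power, conservation sweeps, the demo) runs on 96 x 96 px sites with ~10
cells, one well x three sites per group, chosen so whole multi-culture
experiments remain interactive while every pipeline stage is exercised;
full-scale 256 x 256 scenes and the 27-site layout remain the defaults of
`SceneSpec` and `PlateLayout`.  What the synthetic plates do *not* model —
uneven illumination, focus drift, clumped or overlapping nuclei, real
marker texture, spine-scale morphology (drebrin is intensity only, matching
the intensity-proxy readout) — bounds what passing tests show: they verify
the measurement chain and the statistics, not segmentation robustness on
real micrographs.

## qPCR

Replicate Cq values are arithmetic-averaged per sample (duplicates by
default).  Relative quantity uses the efficiency-corrected model
RQ = E^(Cq_cal − Cq_sample) with the per-culture vehicle sample as
calibrator, making percent-of-control culture-paired, consistent with
culture being a factor in the statistical plan.  The normalization factor
is the geometric mean of the reference-gene RQs (Actb, Rplp0, Rpl19;
references are taken as given, no stability ranking).  Percent of control
is reported as across-culture mean ± SD; the control row is 100 ± 0 by
construction and a single culture reports SD as missing.

Amplification efficiency comes from a window-of-linearity fit on raw
curves: baseline (mean of the first 5 cycles) is subtracted, and among all
windows of 5 consecutive cycles the one maximising the R² of
log₁₀(fluorescence) vs cycle gives E = 10^slope.  Two validity filters
keep the window in the exponential phase: values must exceed 5 baseline
standard deviations (below that, chance linearity in the noise wins the R²
contest) and stay under 8% of the curve's corrected maximum (above that,
plateau saturation compresses the slope and biases E low).  Estimates
outside (1, 2.2] are clamped and flagged.  Per-curve accuracy degrades
roughly linearly in the baseline noise; at 10⁻⁴ of the plateau a single
curve is reliable to ±0.05, and the per-gene estimator
(`estimate_gene_efficiency`) averages across a primer set's reactions,
which is how the estimate is used for quantification.  A small systematic
underestimate (~0.02) remains on strongly saturating curves; it is
inherent to placing a straight-line window on a logistic curve.

## Viability assays

MTT (570 nm) and LDH (492 nm) absorbance tables are normalised per culture
to the vehicle-group mean well absorbance; the output is invariant to any
positive per-culture gain.  Blank subtraction is off by default (the
protocol mentions no blank wells) but available.  Triton-X 100 wells are
carried as labelled controls — near-zero for MTT, high for LDH — and
excluded from group statistics; they anchor assay direction in tests.

## Statistics

Raw (non-percentage) metrics: additive two-way fixed-effects ANOVA with
treatment and culture as factors on the culture means.  With one
aggregated observation per (treatment, culture) cell the design is a
randomized complete block; an interaction term would consume the residual,
so none is fitted, and culture enters as a fixed block (whether the
original analysis treated it as random is unknowable; the choice is named
in the output metadata).  Cultures missing a group for a metric are
dropped (complete-block policy), mirroring the varying *n* per readout.
Sums of squares come from an OLS fit; they satisfy the exact decomposition
identity and are cross-checked against explicit-sum hand computations in
the tests.

A significant treatment F is followed by Dunnett's two-sided many-to-one
comparisons against vehicle, using the ANOVA residual mean square:
t_i = (ȳ_i − ȳ_0) / sqrt(MS_res (1/n_i + 1/n_0)).  Family-wise adjusted
p-values are P(max_j |T_j| ≥ |t_i|) for an equicorrelated multivariate t
(correlation 1/2 in balanced designs), evaluated by deterministic
quadrature: Gauss–Hermite (64 nodes) over the shared normal factor and
Gauss–Legendre (64 nodes) over the quantile-transformed chi mixing
variable — accurate to ~10⁻⁴, verified against an independent Monte-Carlo
oracle and a reference implementation.  Unbalanced designs fall back to a
seeded 100 000-draw Monte-Carlo evaluation of the same max-|T| law under
the product correlation ρ_ij = λ_i λ_j, λ_i = sqrt(n_i/(n_i+n_0)).
Adjusted p is floored at the unadjusted p.  Percentage data use one-way
ANOVA with the pooled within-group mean square and the same post-hoc;
two-group data use the classic pooled-variance unpaired t-test.  α = 0.05
throughout; stars follow the usual 0.05/0.01/0.001/0.0001 convention.

Degenerate inputs are errors, not NaNs: zero residual degrees of freedom,
zero within-group variance, fewer than two complete cultures, or a
(culture, group) cell with every site QC-flagged.

## Numerical and reproducibility notes

* All randomness flows from `numpy.random.SeedSequence`; plate generation
  spawns one child seed per site, so any site can be regenerated in
  isolation, and identical seeds give byte-identical CSV outputs.
* Integer accumulation (`int64`) makes intensity sums exact up to
  2⁶³ ≈ 9·10¹⁸, far above any 16-bit image total; the soma/axon identity
  is asserted, not rounded.
* Euclidean dilation by radius r via the exact distance transform equals
  morphological dilation with the closed-disk footprint, because sqrt of a
  perfect square is exact in IEEE arithmetic; the tie rule (lower label)
  is enforced by strict-inequality updates in ascending label order.
* The run manifest echoes every parameter, threshold and seed, so any
  output number is recomputable from the manifest alone.

## Known limitations

* The nearest-label collision rule deviates from the order-dependent
  sequential macro; the fidelity mode exists for comparison but the
  order-independent rule is the default and the documented behaviour.
* The QC debris criterion is a surrogate with its own thresholds; no claim
  is made that it matches any manual curation.
* Window-of-linearity efficiencies on strongly saturating, noisy curves
  carry the bias noted above; use the per-gene average.
* The two-way ANOVA treats culture as a fixed block; with many cultures
  and heterogeneous variances a mixed model would differ.
* Synthetic scenes do not contain touching nuclei, so the absence of a
  watershed split is untested against that failure mode (the original
  macro had none either).
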