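# Methods

This note documents the models, conventions and numerical choices behind
`nirscal`, in the order the pipeline applies them.

## Scope and data model

The package calibrates wet-chemistry constituents of ground forage straw
(moisture, crude protein, NDF, ADF, ADL and hemicellulose = NDF − ADF,
all % of dry matter) against near-infrared absorbance spectra,
log10(1/R) over 850–2500 nm at 0.5 nm steps (3301 points). Spectra and
reference tables travel as plain delimited text; replicate scans are
averaged in absorbance space before any processing. Wavelength grids are
validated (strictly increasing, uniform step to 1e-9 nm) and a grid
mismatch between two spectra sets is always an error, never an implicit
interpolation.

## Synthetic data generator

No public spectra exist for this problem at desk scale, so the generator
produces datasets with the statistical structure the analysis assumes:

- **Compositions.** Each species is described by a profile of
  per-constituent mean, SD and admissible range. Moisture, CP, ADF, ADL
  and hemicellulose are drawn from truncated normal distributions; NDF is
  *derived* as ADF + hemicellulose so the fiber identity holds exactly,
  and ADL > ADF triggers an ADL redraw. The parent normal of each
  truncated distribution is moment-matched numerically so that the
  realized (post-truncation) mean and SD equal the profile values —
  parameterizing the parent directly would shrink the realized SD by
  several percent under the default ranges. The shipped corn-stover and
  wheat-straw profiles use the calibration-set descriptive statistics of
  the two straw populations the package emulates.
- **Spectra.** Beer–Lambert forward model: each constituent has a fixed
  non-negative absorptivity curve (a sum of Gaussian bands centred near
  the main absorption features of air-dried straw: 1450, 1900, 2100,
  2300 and 2450 nm — the last band is placed at 2450 rather than the
  scan boundary at 2500 so the full Gaussian fits the grid), scaled by
  concentration and summed. Each sample is then distorted by a
  multiplicative factor ~ N(1, 0.1), an additive offset ~ N(0, 0.05), a
  linear baseline tilt ~ N(0, 0.02) across the grid, and white noise of
  SD 0.002 absorbance units. These magnitudes are package constants,
  overridable per profile, chosen to produce scatter clearly visible
  against band structure while leaving the chemistry recoverable — the
  regime scatter-correcting pretreatments exist for.
- **Determinism.** All randomness flows from one profile seed through a
  per-sample substream (`SeedSequence([seed, stream, i])`), so enlarging
  a dataset never perturbs previously generated samples.

What the generator does **not** emulate: reference-method (wet
chemistry) error in the targets, correlated detector noise, instrument
line-shape and temperature/humidity effects, and nonlinear
concentration–absorbance relationships. Two consequences matter when
reading test results. First, synthetic targets are noise-free, so
calibration statistics run higher than any real straw study. Second, the
noise is white at 0.5 nm spacing, which penalizes gap derivatives (they
difference nearly pure noise); on this simulator the identity math
treatment usually wins the grid search, whereas real instruments with
correlated noise favour derivatives. Passing tests therefore validate
the machinery and its algebra, not field performance.

## Pretreatments

A pretreatment is a scatter correction plus a four-numeral math
treatment "derivative, gap, smooth, smooth2", serialized e.g. as
`1,4,4,1+SNV`. Scatter correction is applied **before** the math
treatment (the conventional order in calibration software; the pairing
itself carries no order).

- **SNV**: per-spectrum standardization to mean 0, population SD 1.
- **Detrend**: subtraction of the least-squares polynomial baseline in
  wavelength (degree 2 for the stand-alone correction), computed against
  an orthonormalized basis on a [-1, 1]-scaled axis for conditioning.
- **MSC**: each spectrum is regressed on the calibration-set mean with
  intercept and returned as (x − a)/b; |b| < 1e-12 is an error. The
  state (mean spectrum, and weights for the weighted variant) is fitted
  on calibration samples only and replayed unchanged on validation
  samples. *Weighted MSC* uses per-wavelength weights
  1/max(residual variance about the mean, 1e-8); this weighting is an
  interpretation — the originating commercial software does not document
  its scheme — and is isolated behind the scatter label.
- **Scale linear/quadratic**: division of each spectrum by its own mean
  followed by detrend of degree 1 or 2. This reading of the labels is
  likewise an interpretation and is confined to one function.
- **Math treatment**: first smooth (boxcar running average), then a
  symmetric gap difference — order 1: y(i+h) − y(i−h) with
  h = ceil(gap/2); order 2: y(i+g) − 2y(i) + y(i−g) with g = gap; order
  0: no-op — then the secondary smooth. Differences are not divided by
  the wavelength step; the scale is absorbed by the regression. Gap and
  smoothing counts index data points (0.5 nm each), not nm. Edges are
  trimmed, never padded; the trimmed grid travels with the output so
  downstream wavelength counts stay honest. Savitzky–Golay filtering is
  deliberately not used: the four-numeral notation describes the
  gap-and-running-average convention, and matching it keeps the
  pretreatment strings meaningful.

## Modified PLS

The regression core is NIPALS PLS1 with one modification: after each
factor is extracted and deflated, every wavelength's residual column is
divided by its SD (floored at 1e-12), and the scale vector is stored so
prediction replays it. The first factor is therefore identical to plain
PLS1, and with standardization off the procedure *is* plain PLS1 (this
is tested against an independent implementation and against the OLS
saturation limit). Because the per-factor scaling is a fixed diagonal
map, the fitted model stays linear in the input spectrum; the composed
coefficient vector is available and reproduces factor-by-factor
prediction to 1e-8.

Factor count is chosen by grouped cross-validation: samples are
assigned to groups (default 4) by seeded shuffle then round-robin, so a
value-sorted calibration set does not confound folds with concentration;
SECV(k) = sqrt(Σ e_cv² / n); the chosen count is the smallest k with
SECV(k) ≤ 1.02 × min SECV. The 2% parsimony tolerance (configurable)
avoids the factor-count overfitting of a strict argmin on small n.
`max_factors` defaults to 16 and is truncated with a logged warning when
the data rank is exhausted.

## Outlier screening

- **Spectral (GH).** PCA on centered spectra; the smallest component
  count explaining ≥ 99% variance is retained (capped at 20 and n − 1);
  GH is the Mahalanobis distance in standardized score space divided by
  the component count, so mean GH = 1 by construction. Samples with
  GH > 3.0 (default) are excluded before splitting. Threshold and
  variance fraction are config keys.
- **Compositional (3×SECV).** On the calibration set, cross-validate,
  flag samples whose |cross-validated error| exceeds 3 × SECV, drop
  them, and repeat for at most 2 passes (both configurable); a final
  cross-validation on the survivors picks the factor count of the
  returned model. The kept set only shrinks. Screening runs per
  constituent, so each constituent's calibration n differs — as it does
  in practice.

## Splitting and model selection

Samples are sorted by reference value (ties by id) and divided
~4/5 : 1/5: within each consecutive block of `fold` (default 5) samples
the one at the middle position goes to validation, keeping the extreme
minimum and maximum in the calibration set. Splitting is per
constituent, since missingness and screening differ per constituent.

The default pretreatment grid is the Cartesian product of five math
treatments {0,0,1,1; 1,4,4,1; 2,4,4,1; 1,8,8,1; 2,8,8,1} and six scatter
corrections {none, SNV, detrend, standard MSC, weighted MSC, scale
linear} — 30 candidates. Each candidate runs the full protocol
(pretreat, compositional screen, fit, cross-validate). Ranking collapses
the four classical criteria (low SEC/SECV, high RSQ_C/1-VR) onto the
honest, cross-validated pair: primary key 1-VR descending, ties by SECV
ascending; SEC and RSQ_C are in-sample and reward overfitting, so they
are reported but never rank. A failing pretreatment (e.g. derivative
window exceeding the grid) is recorded as failed, not fatal.

## Statistics and quality bands

With e = predicted − reference: SEC = sqrt(Σe²/(n−1−k)) (factors consume
degrees of freedom), SECV and SEP use divisor n, SEP(C) (bias-corrected)
uses n−1; bias is the mean of e; the slope is the regression of the
laboratory value on the prediction; RSQ_V is the squared Pearson
correlation; RPD = SD of the validation reference values / SEP. These
divisor and sign conventions are stated because the field's software
leaves them implicit; the identity SEP² = bias² + SEP(C)²·(n−1)/n holds
to 1e-9 and is tested.

Quality bands (after Malley), lower-bound-inclusive and requiring both
conditions: excellent (RSQ ≥ 0.95, RPD ≥ 4.0), successful (0.90, 3.0),
moderately successful (0.80, 2.25), moderately useful (0.70, 1.75),
otherwise screening-only. Whether calibration or validation RSQ feeds
the band is the caller's explicit choice; the pipeline uses RSQ_C and
records that.

## Pipeline and reproducibility

The per-species workflow is GH screen → per-constituent split → grid
search → external validation of the winner → classification, with every
artifact written (config copy, GH report, split plan, grid report, model
JSON, reference-vs-predicted pairs, stats table). The combined workflow
pools all species and reruns the same protocol, then tabulates
single-species vs combined RPDs together with each calibration set's SD
— pooling species whose means differ widens the calibration SD, the
mechanism by which combined calibrations raise RPD.

One global seed fans out via named substreams (simulation, CV, per
constituent), so any stage can be re-seeded independently and a rerun
from the written config copy reproduces every CSV byte-for-byte.

Problem sizes used in the shipped checks: unit and property tests run on
reduced grids (hundreds of wavelengths, tens of samples); the
determinism check runs the full pipeline twice at 2 species × 40 samples
× 2 constituents × a 2×2 grid; parameter-recovery checks use 120
samples/species on the full 3301-point grid; `scripts/acceptance.py`
runs the complete study design (156 + 135 samples, all six constituents,
the 30-pretreatment grid, single-species and combined workflows), which
takes about two and a half minutes on one CPU.

## Known limitations

- The exact deflation/scaling order of the commercial MPLS
  implementation is proprietary; this package implements the published
  description literally (deflate, then scale, replayed at prediction)
  and documents it as such. Absolute agreement with WinISI outputs is
  not claimed.
- Reflectance-to-absorbance conversion, resampling between grids, and
  instrument binary formats are out of scope; inputs must already be
  log10(1/R) on a uniform grid.
- The classification bands leave gaps by construction (e.g. RSQ 0.93
  with RPD 4.5 is "successful", not "excellent"); monotonicity is
  guaranteed, exhaustiveness of the upper bands is not.
- Synthetic-data results overstate real-world accuracy for the reasons
  given above; the generator is a test harness, not an instrument model.
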