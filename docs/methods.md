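# Methods

This note records the models behind each biomarker arm, the defaults and
numerical choices, what the synthetic phantoms do and do not emulate,
and the known limitations.

## Measurement protocol

All quantities are ROI statistics on single-slice 2-D magnitude images.
The protocol places elliptical ROIs: three in the liver (Couinaud
segments IV, VIII, VII), one in each paravertebral muscle, one in the
spleen, one in abdominal fat and one in image background ("noise").
A pixel belongs to an ellipse when its centre satisfies
`((r−r0)/a)² + ((c−c0)/b)² ≤ 1` (boundary included), in 0-based
row/column coordinates.  Within-ROI dispersion is the sample SD (n−1);
a single-pixel ROI reports SD 0.  ROI placement is user input: the
package does not segment organs or exclude vessels automatically.

The liver value of record is the unweighted mean of the three liver ROI
means, reported with the sample SD across those three means.  Published
per-subject "±" dispersions for this protocol are not, in our hands,
reproducible as the sample SD of the printed per-ROI means (they are an
order of magnitude smaller than it); the package therefore reports the
sample SD across ROI means and makes no claim of matching any other
dispersion convention.

## Fibrosis arm: T1 vs HSA calibration

Model: ordinary least squares of phantom T1 (ms, response) on HSA
concentration (%, regressor), `scipy.stats.linregress` underneath.  The
reported `r` is the Pearson correlation (carrying the slope's sign) and
`R² = r²`.  A valid albumin calibration has negative slope: higher
protein concentration, shorter T1.  The design must contain at least
three distinct concentrations; anything less raises a degenerate-design
error.

Inverse prediction solves the fitted line, `HSA = (T1 − b)/a`, rather
than regressing concentration on T1; estimates outside the calibrated
0–20 % range are returned with an out-of-range flag.  No fat or iron
correction of T1 is applied; instead the report layer flags
`T1_AFFECTED_BY_FAT_IRON` whenever the same subject's FF or LIC exceeds
its grade-0 threshold.  There is no validated mapping from T1 or
HSA-equivalent concentration to a fibrosis stage, so the inverse
prediction is exposed as an exploratory biomarker only; subject-level
use is a direct comparison of mean liver T1 values.

## Steatosis arm: two-point Dixon

Water and fat protons precess at different frequencies; at even
multiples of the base echo spacing (2.4 ms at 1.5 T, 1.2 ms at 3 T)
their magnetisations add (in-phase), at odd multiples they oppose.
Phase classification tolerates ±0.1 ms of header rounding.
Reconstruction uses the half-sum/half-difference convention
`fat = (IP − OOP)/2`, `water = (IP + OOP)/2`, which makes
`fat + water = IP` an exact identity pre-clipping; the ½ is a pure
rescaling and cancels in the fat fraction.  Negative fat-only pixels
(noise) are clipped to zero after reconstruction.

`FF = 100·S_F/(S_F + S_W)` is computed per liver ROI and averaged over
the three ROIs.  Grade boundaries (defaults, centralised in
`qliver.config.Thresholds`): none < 6.4 %, mild [6.4, 17.4), moderate
[17.4, 22.1], severe > 22.1 %.  Boundaries are left-closed except the
severe bound, which is strictly exclusive as stated by its source.

SIR is the mean of the liver ROI means over the mean of the two muscle
ROI means, measured on the fat-only image (where steatosis makes the
liver hyperintense against the fat-free muscle reference).  Muscle
carries essentially no fat, so on a low-noise fat-only image its signal
can clip entirely to zero; in that degenerate case the SIR falls back to
the in-phase frame.

Limitations inherent to magnitude two-point Dixon:

* fat fractions above 50 % are indistinguishable from their mirror
  below (fat–water swap); per-ROI estimates above 50 % are reported at
  50 % with a dominance-ambiguity flag;
* the liver signal decays between the OOP and IP echo times, which
  biases FF downward by roughly 1–3 percentage points at tissue T2*
  (~30 ms) and 1.5 T echo spacing — visibly more when iron shortens
  T2*.  No T2* correction or multi-peak fat model is applied; the
  `IRON_AFFECTS_FF` / `OMIT_FF` warnings surface the severe cases.

## Iron arm: offset-exponential T2* and LIC

Model: `S(TE) = S0·exp(−TE/T2*) + C` fitted to the per-echo liver
signal (mean of the three liver ROI means) by bounded trust-region
least squares (`scipy.optimize.least_squares`, analytic Jacobian,
relative tolerances 1e-8, ≤600 function evaluations) — deterministic
given inputs.  Initialisation is a log-linear regression of the
floor-subtracted signal.

Noise-floor handling, two complementary mechanisms:

* **truncation** — echoes whose signal is at or below the measured
  background level (NOISE-ROI mean) are excluded before fitting; at
  least four usable echoes must remain.  Below the floor the magnitude
  curve flattens towards background rather than decaying, which biases
  T2* upward and under-calls iron;
* **offset** — `C` absorbs the residual floor among retained echoes.
  It is initialised at the measured floor and bounded in
  `[0, max(2·floor, 0.5·min(signal))]`: generous enough to move, tight
  enough not to trade off against `S0` on short series.

A fit whose T2* exceeds 50× the last echo time is rejected as "no
measurable decay" (constant signal), and non-convergence raises an
error with the optimizer's diagnostics rather than returning a value.

For fatty livers the interleaved OOP echoes oscillate below the IP
decay envelope; when the subject's FF exceeds the steatosis threshold
the report layer refits using in-phase echoes only (falling back to all
echoes if too few IP echoes clear the floor).

Conversion: `R2* = 1000/T2*` (1/s); at 3 T
`LIC = 0.314·R2* − 0.96` µmol/g dry weight.  At 1.5 T the decay is
mapped to its 3 T equivalent by halving T2* (doubling R2*) first.  This
halving rule is an approximation, not a field-specific calibration: it
reproduces published 1.5 T worked values only to within a few µmol/g
(34.9 vs a printed 34 in a no-overload case; ~100 vs a printed 95 in a
severe case), so every 1.5 T LIC carries an `approximate` flag.  Raw
LIC is a float; the report layer also prints the half-up integer
rounding.  Negative raw values (very long T2*) clamp to 0 with a flag.
Grades: none < 36, mild [36, 80], severe > 80 µmol/g.

The muscle reference comparison (`tissue_decay_comparison`) reports the
iron pattern — liver T2* below muscle T2* — since paravertebral muscle
stores no iron.

## Synthetic phantoms

The generator emulates the acquisition designs the pipeline expects:

* **HSA vial phantom** — circular vials on a uniform background, pixel
  values = `intercept + slope·concentration` + Gaussian noise.
  Defaults: 7 vials at {0, 2.5, 5, 8, 11, 16, 20} %, slope −30 ms/%,
  intercept 1500 ms, spanning a 600 ms dynamic range representative of
  tissue-like albumin solutions at 3 T.  Vial overlap is rejected.
* **abdominal phantom** — non-overlapping ellipses for three liver
  segments, two paravertebral muscles, spleen and abdominal fat on a
  128×128 matrix (the multi-echo matrix size).  Defaults: liver proton
  density 1000 a.u.; muscle 700 a.u., T2* 25 ms; spleen 900 a.u.,
  T2* 60 ms; subcutaneous fat at 95 % fat fraction.  Per-region signal
  follows the two-point model `|W±F|·exp(−TE/T2*)` with
  `W = pd·(1−ff/100)`, `F = pd·ff/100`; `T2* = ∞` disables decay.
* **multi-echo series** — echoes at `k·spacing` (defaults 10×2.4 ms at
  1.5 T, 12×1.2 ms at 3 T), alternating OOP/IP starting opposed-phase.

Noise is Gaussian added to the magnitude and clipped at 0 (adequate
above SNR ≈ 10) or exact Rician on request; ROI-level conclusions are
insensitive to the difference except at the decay tail, where the
Rician option is used for T2* stress tests.  A fixed seed gives
bit-identical images.

Not emulated: anatomy, motion, B1 inhomogeneity, continuous fat
chemical-shift evolution (only the IP/OOP dichotomy), multi-slice
geometry, vendor DICOM quirks.  Passing recovery tests on these
phantoms therefore demonstrates correctness of the estimators under the
stated signal model, not robustness to everything a patient scan can
contain.

## Test problem sizes

Recovery tests use the sizes at which the estimators' statistical
claims are stated: 1000 seeded 7-point calibrations for the slope-sign
rate; 200 simulated 10-echo series at SNR 50 (Rician noise, T2* drawn
uniformly from 3–30 ms) for the median-T2*-error bound, with the first
10 series cross-checked against an exhaustive (T2*, C) grid search with
the amplitude solved in closed form; four Dixon phantoms at FF
{3, 10, 17, 25} % and 2 % noise for fat-fraction recovery.  The whole
suite runs in well under a minute on one CPU.

## Known limitations

* Single-slice, ROI-level analysis only; no pixel-wise T2* or FF maps.
* The 1.5 T LIC path is approximate by construction (see above).
* Two-point Dixon biases (T2* decay between echoes, >50 % ambiguity)
  are flagged, not corrected.
* The fibrosis arm is a calibration plus comparison, not a staging
  model; no T1→stage thresholds exist in this package.
* DICOM support targets well-formed single-frame MR series with
  `EchoTime` and `MagneticFieldStrength` present; vendor private tags
  are ignored, and missing metadata is a hard error naming the file.
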