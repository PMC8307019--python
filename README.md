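# qliver

Non-invasive liver biomarkers from magnitude MR images: a tested Python
pipeline for the three quantities radiologists read off a single
abdominal MR protocol in place of a biopsy —

* **fibrosis (exploratory)** — liver T1 (ms) summarised over three
  elliptical ROIs in Couinaud segments IV, VIII and VII, calibrated
  against human-serum-albumin (HSA) phantoms.  HSA is synthesised
  exclusively by the liver and falls in advanced fibrosis, and the T1 of
  albumin solutions falls linearly as concentration rises, so an OLS fit
  of phantom T1 on concentration, `T1 = a·HSA% + b` (slope `a < 0`), can
  be inverted to express a measured liver T1 as an HSA-equivalent
  concentration;
* **steatosis** — two-point Dixon fat–water separation.  From in-phase
  (IP) and opposed-phase (OOP) magnitude images,
  `fat = (IP − OOP)/2`, `water = (IP + OOP)/2`, and the liver fat
  fraction `FF = S_F/(S_F + S_W) × 100` grades steatosis at
  6.4 / 17.4 / 22.1 %; the liver-to-paravertebral-muscle signal
  intensity ratio `SIR = S_liver/S_muscle` is the reference-tissue check;
* **iron overload** — multi-echo gradient-echo T2* relaxometry.  The
  liver ROI mean across echoes follows
  `S(TE) = S0·exp(−TE/T2*) + C`, with echoes at or below the measured
  background noise floor excluded before fitting; the liver iron
  concentration follows Gandon's conversion
  `LIC [µmol/g] = 0.314·R2* − 0.96` with `R2* = 1000/T2*` (1/s) at 3 T,
  and at 1.5 T via the approximate halving rule (T2* at 3 T is about
  half its 1.5 T value), graded at 36 / 80 µmol/g.

Because fat and iron disturb each other's estimates (and T1), the report
layer emits reproducible cross-contamination warnings whenever the
numeric fields cross the grade thresholds.

A synthetic phantom generator (`qliver.synth`) renders every input the
pipeline reads — HSA vial T1 maps, Dixon pairs and multi-echo series of
an abdominal phantom — with known ground truth, so the whole pipeline is
testable without scanner data.

## Worked example

Simulate a 1.5 T subject with a fatty liver (true FF 17.5 %, liver
T2* 30 ms) and run the full report:

```sh
qliver simulate --out demo --field 1.5 --seed 7 --liver-ff 17.5 \
       --liver-t2star 30 --noise-sd 10
qliver report --multiecho demo/multiecho.nii --ip demo/dixon_ip.nii \
       --oop demo/dixon_oop.nii --rois demo/rois.json --field 1.5 --out out
```

which prints

```
Subject subject  (1.5 T)
----------------------------------------
fat fraction       14.81 %  (SD 0.08) -> MILD
SIR                1.474
T2*                29.95 ms  (R2* 33.4 1/s)
LIC                 20.0 µmol/g (~20) -> NONE
warnings: FAT_AFFECTS_T2STAR, LIC_1P5T_APPROXIMATE
```

Reading the numbers: T2* is recovered at 29.95 ms against a true 30 ms
and converts to ~20 µmol/g — no iron overload.  The fat fraction comes
back at 14.8 % against a true 17.5 %: uncorrected two-point Dixon
carries a small negative bias because the liver signal decays between
the OOP (2.4 ms) and IP (4.8 ms) echoes (see `docs/methods.md`), and
near a grade boundary that bias can shift the grade.  The fat arm being
above the 6.4 % threshold raises `FAT_AFFECTS_T2STAR`; every 1.5 T LIC
carries `LIC_1P5T_APPROXIMATE` because the field conversion is a rule of
thumb, not a calibration.  `out/` contains `report.json`, per-ROI and
per-echo CSV tables, and the decay-fit plot.

The same analyses are available as library calls (`T1Calibration(...).fit()`,
`T2StarDecay(...).fit()`, `steatosis_arm`, `iron_arm`, `build_report`);
the fitted objects expose `summary()`, `predict...` and `plot` in the
usual estimator style.

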