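# nirscal

Calibration workflows for near-infrared reflectance spectroscopy (NIRS)
of forage straw. Given absorbance spectra (log 1/R, 850–2500 nm) and
wet-chemistry reference values (% DM) for constituents such as moisture,
crude protein (CP), NDF, ADF, ADL and hemicellulose (= NDF − ADF),
`nirscal` builds and evaluates prediction equations the way forage
laboratories do:

- **Modified PLS (MPLS)** — NIPALS PLS1 in which the spectral residuals
  at every wavelength are divided by their SD after each factor, with
  factor count chosen by grouped cross-validation (SECV with a 2%
  parsimony rule);
- **spectral pretreatments** — SNV, detrend, standard/weighted MSC,
  mean-scaling, and four-numeral math treatments
  ("derivative, gap, smooth, smooth2", e.g. `1,4,4,1`), searched over a
  30-candidate grid and ranked by cross-validated criteria (1-VR, SECV);
- **outlier screening** — Mahalanobis GH distance in PCA score space
  (GH > 3 excluded) before calibration, and removal of samples whose
  cross-validated error exceeds 3 × SECV during calibration;
- **evaluation** — SEC, SECV, RSQ_C, 1-VR on the calibration side; bias,
  SEP, SEP(C), slope, RSQ_V and RPD = SD/SEP on an external
  rank-stratified validation set, with the Malley quality bands
  (excellent ⇔ RSQ ≥ 0.95 and RPD ≥ 4.0, down to screening-only);
- **a synthetic straw generator** — truncated-normal compositions per
  species plus a Beer–Lambert band mixture with multiplicative scatter,
  baseline tilt and noise, so the entire pipeline is testable without
  instrument data. Shipped profiles emulate corn-stover and wheat-straw
  populations, and a combined-species workflow quantifies how pooling
  species widens the calibration range and raises RPD.

The audience is chemometricians and animal-nutrition researchers who
want a scriptable, reproducible version of this workflow; the package is
used from Python (see `examples/`), with a thin `nirscal` CLI for the
common end-to-end runs. Details of every model and convention are in
[docs/methods.md](docs/methods.md).

## Worked example

`examples/04_combined_vs_single_species.py` simulates 80 corn-stover and
80 wheat-straw samples, calibrates CP and ADL per species and on the
pooled set, and prints:

```
== corn_stover
constituent pretreatment  factors  rsq_c  one_minus_vr   rpd                 class
         cp 0,0,1,1+none        6 0.9610        0.8603 2.755 moderately_successful
        adl  0,0,1,1+SNV        5 0.9887        0.9643 6.901             excellent
== wheat_straw
constituent pretreatment  factors  rsq_c  one_minus_vr   rpd      class
         cp 0,0,1,1+none        7 0.9728        0.7206 3.071 successful
        adl  0,0,1,1+SNV        4 0.9603        0.9066 3.020 successful
== combined
constituent pretreatment  factors  rsq_c  one_minus_vr   rpd     class
         cp   0,0,1,1+DT        5 0.9716        0.9446 5.160 excellent
        adl 0,0,1,1+none        7 0.9816        0.9729 5.438 excellent

Combined vs single-species RPD (and calibration-set SDs):
constituent  rpd_corn_stover  sd_cal_corn_stover  rpd_wheat_straw  sd_cal_wheat_straw  rpd_combined  sd_cal_combined
         cp            2.755              1.2948            3.071              0.7537         5.160           1.5611
        adl            6.901              1.4546            3.020              1.5660         5.438           2.4571
```

Each row is one calibration: the winning pretreatment string
(math treatment + scatter code), the cross-validated factor count, the
in-sample R² (`rsq_c`), the cross-validated R² (`1-VR`), the external
validation RPD, and its quality band. The comparison table shows the
pooling effect: the combined CP calibration set is wider
(SD 1.56 vs 1.29/0.75 % DM) because the species' CP means differ, and the
pooled model's RPD (5.16) beats both single-species models — the case
for combined straw calibrations.

The other examples cover simulation (`01`), pretreatment + MPLS
mechanics (`02`), and outlier screening + grid search (`03`). The same
workflows are available from the shell:

```
nirscal -v combined --seed 1 -o runs/demo
```

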