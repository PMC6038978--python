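# mibgquant

Three-dimensional quantification of myocardial ¹²³I-MIBG uptake for the
discrimination of Lewy body disease (LBD — Parkinson's disease and dementia
with Lewy bodies) from non-LBD parkinsonism, exercised end to end on
digital phantoms with known ground truth.

¹²³I-MIBG is a norepinephrine analogue: cardiac sympathetic denervation in
LBD reduces its myocardial uptake. The conventional metric, the planar
heart-to-mediastinum count ratio (H/M), uses low mediastinal counts as its
reference and its LBD / non-LBD ranges overlap. This package implements a
calibrated, non-invasive *uptake index* that normalizes a myocardial count
measure by a per-subject input function, in three variants of increasing
dimensionality, plus the statistical machinery to compare their diagnostic
accuracy.

## The model

**Input function.** A first-pass bolus of activity through the pulmonary
artery is captured on a dynamic planar chest series (120 × 1 s frames,
128×128, 3.3 mm pixels). A 3-pixel-diameter ROI is auto-detected on the
bolus focus, its time-activity curve's first peak is fitted with a gamma
variate

    g(t) = K (t − t₀)^α e^{−(t − t₀)/β},

and the input function is its analytic integral

    AUC = K β^{α+1} Γ(α+1),

which is proportional to the administered dose. Recirculation is excluded
by fitting only from 10% of peak (upslope) to 30% of peak or the first
post-peak rise (downslope).

**Output functions and indices.** From the 5-min static planar image
(256×256) and the SPECT study (60 views/360°, 64×64, OSEM with 4 subsets ×
30 iterations, no scatter/attenuation correction):

- `H/M` — mean heart ROI counts / mean upper-mediastinal ROI counts;
- `planar uptake index` = scale × (heart mean counts) / AUC;
- `SPECT uptake index` = scale × C_myo / (CF × AUC), where C_myo is the
  myocardial polar-map count measure (per sector: maximum over radius of
  the running mean of three consecutive radial samples) and CF is the
  2D–3D count-conversion factor, calibrated by regressing SPECT polar-map
  counts on planar heart counts through the origin.

Diagnostic accuracy is evaluated with empirical ROC curves, Youden-index
criterion thresholds (disease-positive = index **below** threshold),
sensitivity/specificity/PPV/NPV/accuracy, exact Fisher and Mann-Whitney
tests, Spearman correlation, and a paired structural-components (DeLong)
test for AUC differences.

Because no patient data ship with the package, a phantom module generates
all three acquisition geometries per synthetic subject — bolus dynamics
with recirculation, organ compartments with configurable uptake ratios,
an ellipsoidal myocardial shell with optional perfusion defects, a
matched parallel-beam projector, and Poisson counting noise — so every
stage is testable against ground truth.

## Worked example

```python
from mibgquant.pipeline import RunConfig, run_cohort

cfg = RunConfig(n_lbd=10, n_nonlbd=10, seed=42)
table, report, calibration = run_cohort(cfg)
print("cf =", round(calibration.cf, 4), " r =", round(calibration.r, 3))
print(report.to_frame().round(3).to_string(index=False))
```

prints

```
cf = 0.0756  r = 0.999
      method  auc  sensitivity  specificity  criterion  ppv  npv  accuracy
          hm  1.0          1.0          1.0      2.896  1.0  1.0       1.0
planar_index  1.0          1.0          1.0      1.060  1.0  1.0       1.0
 spect_index  1.0          1.0          1.0      1.086  1.0  1.0       1.0
```

`cf` is the calibrated 2D–3D conversion factor and `r` the correlation of
planar versus SPECT count measures across subjects. Each row is one
method's empirical ROC area, the Youden criterion threshold (an index
below it calls LBD), and the resulting accuracy metrics. On this small,
well-separated noisy cohort all three methods classify perfectly; the
group medians (LBD 0.69, non-LBD 1.78 here) sit near the generating group
laws because index scales are auto-normalized so that a unit-concentration
reference phantom scores 1.0.

The same pipeline is scriptable from the shell:

```sh
mibgquant simulate --n-lbd 2 --n-nonlbd 2 --seed 1 --out scratch/demo
mibgquant input-fn --dynamic scratch/demo/L000_dyn.nii.gz --out scratch/demo/if
mibgquant report --n-lbd 5 --n-nonlbd 5 --seed 1 --out scratch/demo/report
```

## Layout

- `mibgquant.phantom` — synthetic subjects: dynamic series, planar image,
  activity volume, projections, two-group cohorts.
- `mibgquant.projector` — matched parallel-beam forward/backprojector.
- `mibgquant.input_function` — PA ROI detection, TAC, gamma-variate fit, AUC.
- `mibgquant.planar_quant` — heart/mediastinum ROIs, H/M, planar index.
- `mibgquant.spect_quant` — OSEM, short-axis reorientation, polar map, CF
  calibration, SPECT index.
- `mibgquant.diagnostics` — summaries, ROC/Youden, exact tests, DeLong.
- `mibgquant.pipeline` / `mibgquant.cli` — orchestration and the
  `mibgquant` command.

See `docs/methods.md` for modeling assumptions, parameter defaults, and
known limitations.
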