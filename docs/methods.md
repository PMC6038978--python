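# Methods

This note records the models, conventions and numerical choices behind
`mibgquant`, and what validation on digital phantoms does and does not
establish.

## Input function

The first-pass bolus through the pulmonary artery is modeled as a gamma
variate `g(t) = K (t−t₀)^α exp(−(t−t₀)/β)` plus one delayed, scaled
recirculation copy `κ·g(t−Δ)`. Defaults: α = 3 (dimensionless), β = 1.5 s,
t₀ = 8 s, κ = 0.3, Δ = 12 s; K is set by the injected-dose scale. These
are typical first-pass shape values for an antecubital bolus at 1 s
framing; the single delayed copy is the simplest shape that produces a
distinct recirculation shoulder after the first peak.

Fitting conventions:

- ROI aggregation is the **sum** over the 9 pixels whose centers lie
  within 1.5 px of the 3-px-diameter ROI center. A mean would only rescale
  K and AUC and cancels in every index; the sum is fixed so counts are
  bit-reproducible.
- Frame time stamps are frame midpoints. The AUC is the analytic integral
  of the fitted curve, `K β^{α+1} Γ(α+1)`, not a sample sum, so frame
  discretization does not bias it.
- The first-peak window runs from the last pre-peak sample below 10% of
  peak to the first post-peak sample below 30% of peak or the first
  post-peak rise, whichever is earlier — standard gamma-variate practice
  that excludes recirculation.
- Nonlinear least squares is initialized from the log-linearization
  `ln C = ln K + α ln(t−t₀) − (t−t₀)/β`, solved over a grid of candidate
  t₀ (every 0.5 s from 0 to the peak); the three best initializations are
  polished with bounded Levenberg-Marquardt and the lowest-SSE fit wins.
- A TAC with no detectable peak (max ≤ 5× the pre-bolus baseline) or no
  downslope raises `FitFailed` rather than returning a bad fit.

With a 500-count peak and Poisson noise, the median AUC error over 200
replicates is ≈1.4%, well inside the 5% the pipeline tolerates.

## Phantom

Anatomy is deliberately geometric — ellipses in 2D, ellipsoids in 3D —
with hand-set, anatomically plausible defaults stored in the
configuration so tests can substitute degenerate shapes. The cardiac
silhouette displaces lung in both planar views. The pulmonary-artery
disk *overrides* underlying organs so its pixel trace equals the bolus
model exactly; all other organs follow slow mono-exponential uptake
curves (time constant 60 s) scaled relative to the bolus peak.

Activity units are arbitrary but consistent across the dynamic, planar
and SPECT channels of one subject, and every channel scales with the
injected-dose scale — this is what makes dose-invariance of the indices a
meaningful (and enforced) property. Count levels at unit dose are set to
realistic magnitudes: ≈450 counts/s at the bolus peak pixel, ≈300
counts/pixel per unit concentration on the 5-min planar image, and tens
of counts per projection bin.

The myocardium is an ellipsoidal shell (outer semi-axes 14×10×10 voxels,
inner 10×6×6, 6.6 mm voxels), optionally tilted and optionally carrying
an angular defect that scales shell activity by 1−depth. Shell painting
uses 2× supersampled partial volumes by default (binary with
`supersample=1`); the ground-truth mask contains only voxels fully inside
the shell.

The projector is rotation-based parallel-beam with bilinear
interpolation, assembled as a sparse matrix per view so the backprojector
is the exact adjoint. No attenuation, scatter or depth-dependent blur is
modeled, matching a reconstruction protocol without those corrections.
Noiseless projections conserve total counts to <0.1% for sources inside
the inscribed circle. Poisson noise is applied wherever a seed requests
it; all generators are bit-reproducible under a fixed seed.

Cohorts draw per-subject true myocardial concentration from log-normal
laws matched by median and IQR — LBD median 0.63 (IQR 0.52–0.82),
non-LBD 1.70 (1.53–2.03) — the reported uptake-index distributions of
the clinical population this package emulates. Only medians/IQRs are
published for that population, so a two-parameter positive law matched to
them is the natural choice.

## SPECT chain

OSEM uses 4 interleaved subsets (view v in subset v mod 4), 30
iterations, uniform initialization at one, a 1e-12 zero-sensitivity
guard, and holds zero-sensitivity voxels at zero; nonnegativity is
preserved by construction. On consistent data the reconstruction
reprojects to the measured totals to ≈0.01%.

Short-axis reorientation estimates the long axis as the
intensity-weighted principal axis of voxels above 50% of a robust (99th
percentile) myocardial maximum inside a search box around the expected
cardiac position; the robust maximum keeps hot noise voxels from
collapsing the mask. Eigenvalue ratio < 1.1 (isotropic mask) or an empty
mask raises `AxisUndetermined`, falling back to a template geometry with
the *virtual* flag set when one is supplied — the low-uptake situation.
Resampling is trilinear on an isotropic grid at the original voxel size.
The apex-to-base slice range is taken from the estimated myocardial
component itself (not the whole-volume profile, which bright liver
activity would stretch) and extended symmetrically to at least the
polar-map ring count.

The polar map is 10 rings × 36 sectors (the ring/sector counts are this
package's choice; only the per-sector rule is canonical): apex-to-base
slices are split into contiguous ring groups, and each sector's value is
the maximum over radius of the running mean of three consecutive 1-voxel
radial samples. The output function C_myo is the **mean** of all sector
values; the total is exposed as an option (`mode="total"`) since the two
differ only by the fixed factor rings×sectors and cancel in any
calibrated comparison.

CF is the least-squares slope through the origin of SPECT polar-map
counts on planar heart counts (proportionality is the model's premise; a
with-intercept fit is available behind a flag). The SPECT index divides
polar-map counts by CF before AUC normalization, which the dose-invariance
requirement fixes uniquely.

## Index scale

The conversion constants that give the clinical index its absolute scale
are facility-specific and never published, so the absolute scale is a
convention. `planar_uptake_index` defaults to scale 1000, which puts
phantom indices in the low single digits. The pipeline's cohort runner
instead uses `scale="auto"`: both indices are normalized against a
noiseless unit-concentration reference phantom processed through the
identical chain, so an index value reads directly as a concentration in
phantom units and cohort medians land near the generating group medians.
Residual bias remains at the extremes (≈+7% at concentration 0.4 from
extra-cardiac bleed-through, ≈−5 to −9% at high concentration from
partial-volume and noise effects on the max-of-3 statistic); ROC-based
accuracy is unaffected because the indices are strictly monotone in
concentration.

## Diagnostics

- Disease-positive (LBD) is expected *lower*, so a positive call is an
  index below threshold, and the ROC AUC is P(non-LBD > LBD) with ties
  counted ½ (the Mann-Whitney identity).
- The Youden criterion is the threshold maximizing J = sens + spec − 1;
  candidate cuts are midpoints between adjacent distinct scores (plus
  cuts below/above all scores); among ties the lowest cut is reported.
- Quartiles use linear interpolation; variance uses the n−1 denominator;
  the median CI is the binomial order-statistic interval (the published
  "95% CI" values bracket the medians, which this reading matches).
- Mann-Whitney: statistic min(U₁,U₂); for n ≤ 20 the two-sided p is exact
  by full enumeration of rank splits (symmetric-deviation convention,
  tie-aware — equal to the classical 2·P(U ≤ U_obs) when there are no
  ties); larger samples use the normal approximation with tie correction.
- Fisher's exact test is two-sided by the sum-of-smaller-probabilities
  convention (the one that reproduces p = 0.821 on a 17/20 vs 20/20 sex
  split); scipy implements exactly this convention and is used directly,
  with a hypergeometric enumeration oracle in the tests.
- AUC comparison between paired methods uses the structural-components
  (DeLong) variance. A quasi-maximum-likelihood binormal ROC fit and the
  multi-reader Dorfman-Berbaum-Metz procedure are deliberately not
  reproduced: they are tied to a specific legacy software package and a
  multi-reader design; the empirical ROC plus a paired nonparametric test
  is the standard modern substitute for a single-reader paired design.

## Pipeline conventions

- Processing follows the acquisition order (dynamic → planar → SPECT);
  per-subject results are independent of processing order.
- CF is pooled over all subjects by default, with an option to estimate
  it on a designated calibration fraction to avoid leakage in simulation
  studies.
- A subject whose gamma fit fails is excluded from diagnostics and listed
  in the report.
- Every report embeds the seed and a configuration hash.

## Problem sizes

Default study conditions are used throughout: 120-frame 128×128 dynamics,
256×256 planar, 64³ volumes, 60-view 64×64 projections, OSEM 4×30, and a
37/40 cohort. Property tests that don't depend on the acquisition
geometry (projector conservation, OSEM convergence shape) use smaller
grids where that changes nothing about the claim.

## What phantom validation does not show

The phantom has no attenuation, scatter, septal penetration (relevant
for ¹²³I's high-energy photons), detector blur, cardiac or respiratory
motion, and its anatomy is geometric. Passing tests therefore establish
the *internal* correctness and invariances of the measurement chain — not
clinical accuracy on patients. The near-perfect cohort AUCs reflect the
generating group laws plus counting noise only; real populations add
anatomical and physiological variability that widens the overlap.
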