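# Methods

## Model

A cumulative DVH on a common dose grid is treated as a vector. The
population of training DVHs for one structure is decomposed by principal
component analysis: any curve is the population mean plus a weighted sum
of orthonormal component shapes plus a residual,

    v(d) ≈ m(d) + Σ_j s_j · c_j(d).

The first component maximizes the explained training variance, each
further component accounts for residual variance. The same decomposition
is applied to the geometry-based expected dose (GED) curves, and the DVH
component scores are coupled to geometry through ordinary least squares:

    s_j = β_j0 + Σ_k β_jk x_k + ε_j,

with predictors x = (GED PC scores, target volume, structure volume,
in-field volume fraction, number of arcs), standardized before fitting so
coefficient standard errors are comparable. This regression governs only
the **in-field** region of the curve (grid points above a partition
dose); the low-dose remainder is modeled by the pointwise mean and
standard deviation of the training curves. A new patient's prediction is
the regression curve above the partition, the mean curve below, a linear
cross-fade of 5 grid points between them, and a pointwise band: the
component shapes scaled by their regression residual standard errors and
added in quadrature in-field, ±1 SD out-of-field. Optimization
objectives are placed below the band's lower limit by a per-structure
template (dose margin: 2% of prescription; priorities are template
data, not code).

Assumptions worth stating: linearity of scores in the predictors;
homoscedastic, roughly Gaussian score residuals (the chi-square
diagnostic tests exactly this); and that the retained components span
the clinically relevant curve variation.

## GED

The vendor fall-off law is not public. Here each sub-volume at signed
distance r (mm) from the target surface receives

    inside target (r ≤ 0):  Rx
    in-field:               Rx · exp(−k_in · r),    k_in  = 0.05 /mm
    out-of-field:           Rx · f_out · exp(−k_out · r),  k_out = 0.15 /mm, f_out = 0.3

and the structure's GED curve is the cumulative histogram of these doses
over its distance histogram, with the in-field/out-of-field kernels
weighted by the structure's in-field volume fraction. The kernels
reproduce the qualitative in-field/out-of-field dichotomy the model
needs while staying analytically checkable; all parameters are
configuration. The in-field partition threshold is 0.2 × prescription,
applied on the dose axis of the model grid at the mean training
prescription — the partition mechanics are an implementation choice, as
is the 5-point cross-fade.

## Dose grid and metrics

Model curves live on a 100-point uniform grid from 0 to 110% of the
largest prescription (66 Gy for a 60 Gy ceiling); sample-based DVHs
default to 0.05 Gy bins, finer than any reported metric's sensitivity.
D_x / V_x use linear interpolation in both axes with ties broken toward
the lower dose; mean dose is the trapezoidal integral of the cumulative
curve. HI = (D5 − D95)/mean. CI = (body volume receiving ≥ 95% of
prescription) / (target volume); the body V95 volume is an explicit
input because CI is not computable from the target DVH alone. Metric
values are reproducible only to interpolation tolerance, since the
source system's binning is unknown.

## Training diagnostics

- **Goodness of estimation**: 10-fold cross-validation (fold assignment
  is a seeded shuffle of the patient-id order, so it is reproducible and
  independent of case ordering); reported as the mean squared error
  between held-out curves and predictions in fractional volume units.
- **Average chi-square**: per component, the least-squares residual
  variance divided by a robust (MAD-based, degrees-of-freedom-adjusted)
  estimate of the same residuals' variance, averaged over components.
  For well-behaved Gaussian residuals this is ≈ 1; heavy-tailed
  residuals — a few cases planned very differently from the rest —
  inflate it. The vendor's definition is undisclosed; this is our
  operationalization of "closer to one is better".
- **Model fit**: pooled R² over the component regressions (≤ 1).
- **Outliers**: Cook's distance D_i = (r_i²/(p·s²))·h_ii/(1−h_ii)²
  with reporting threshold 4 (as in the reference system) and externally
  studentized residuals with default threshold |t| ≥ 3 (no published
  value; chosen as a conventional 3-sigma rule). Exact-leverage points
  (h_ii = 1) are reported with infinite influence rather than crashing.
  Outliers are reported, never removed. A structure needs ≥ 20 cases for
  a model; the report recommends 5 × (number of regression parameters)
  cases and prints the recommendation only when the cohort is smaller.

## Synthetic cohorts

The generator emulates the reference population: log-normal target
volumes matched to mean 596 / SD 538 cm³, rejection-sampled into
54–2188 cm³; prescriptions at representative levels 60/42/36 Gy with
proportions 55/40/5 (the source proportions sum to 110% — an evident
misprint — and are normalized); 2–4 arcs; non-coplanar fraction 40/45.
Six OARs get per-organ shifted-gamma distance histograms (declared
assumptions — no OAR-level geometric statistics are published) whose
scale couples weakly to target size.

DVHs embed an exactly linear ground truth. GED curves are drawn first
and decomposed with the same PCA the model uses; each OAR DVH is then

    organ mean curve + Σ_j t_j · c_j + iid grid noise,  t = B·z,

with z the standardized GED PC scores (clamped to ±4), B the
configurable `true_beta`, c_j two smooth orthonormal half-/full-sine
shapes supported above the partition dose, followed by projection onto
the monotone cone. Design choices that make the truth identifiable:

- Organ mean curves are strictly decreasing with enough slope headroom
  that mean + t·c is monotone for every admissible t — so with zero
  noise the projection is the identity and curves reconstruct exactly
  from their recorded latent scores.
- The default B is diagonal over the two GED scores. Because PCA scores
  are orthogonal in-sample, the latent score covariance is then exactly
  diagonal and the generating shapes are exactly the population
  eigenvectors: fitted components equal them up to noise, without
  rotation ambiguity, which is what makes confidence-interval coverage
  of `true_beta` a meaningful check.
- Curve-level noise defaults to SD 0.003 (fractional volume). It
  represents residual curve noise beyond the latent linear structure,
  kept small enough that the monotone projection is almost surely
  inactive; the injected noise floor σ² is then also the realized one,
  so cross-validated goodness, the chi-square calibration and the ±1 SD
  out-of-field coverage (≈ 68% of grid points, excluding the degenerate
  0 Gy point and the cross-fade window) all calibrate against their
  nominal values.

PTV coverage curves come from a sigmoid family around the prescription
and are *not* part of the linear truth.

What passing these tests does not show: real plan libraries carry
non-linear inter-patient variability, contouring heterogeneity and
dosimetric trade-offs that no latent linear model captures — which is
why the synthetic model fit is ≈ 0.999 while clinical training reports
sit near 0.85, and why synthetic OAR curves (which plateau at a nonzero
tail by design) violate clinical endpoints at rates no clinical cohort
would. The synthetic cohort validates the estimator's mechanics
(recovery, calibration, diagnostics), not clinical performance.

## Problem sizes

Default study sizes, chosen to exercise the method at the scale of the
reference study while keeping every check desk-scale: 45 training / 25
validation patients for workflow runs; 200 patients × 50 replicates for
coefficient-recovery coverage; 500 patients for chi-square calibration
and band coverage; 1000 randomized draws for band-ordering property
checks.

## Known limitations

- The GED kernel is a stand-in for an undisclosed vendor construction;
  only its qualitative behavior (distance fall-off, in/out-of-field
  dichotomy) is matched.
- The in/out-of-field partition is dose-axis-based at a cohort-level
  reference prescription; a per-case partition would shift the blend
  region for atypical prescriptions.
- Chi-square and model-fit are interpretations of loosely documented
  vendor metrics; their absolute values are not comparable across
  implementations.
- Open-loop audits use the published denominator of 224 analyzed points
  when reproducing printed percentages, although 25 patients × 8
  endpoints = 200; the discrepancy is logged whenever it applies.
- No plan optimizer is included: generated objectives are emitted, never
  consumed.
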