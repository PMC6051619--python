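# Methods

## Signal model and phantom

Every voxel follows the mono-exponential decay `S(b) = S0 exp(−b · ADC)`
with ADC in 10⁻³ mm²/sec. The phantom rasterizes spherical nodules into a
voxel grid (voxel-center-inside test) over a normal-thyroid background;
the default grid uses 0.68 × 0.68 × 3.3 mm voxels (175 mm field of view
over a 174 matrix in-plane; 3 mm slices plus a 0.3 mm gap) and b = 0, 800,
2000 sec/mm².

Noise is Rician: the magnitude of the complex signal after adding two
independent zero-mean Gaussians of standard deviation σ. At zero signal
this reduces to a Rayleigh floor with mean σ√(π/2); at high b it inflates
the measured signal and biases ADC downward, which the tests verify grows
with σ. Because the acquisition averages 4 excitations at b = 2000 (1
elsewhere), the effective σ of that volume is divided by √4 = 2 by
default; `model_averaging=False` disables this.

Default tissue parameters place nodule S0 relative to normal tissue
(S0 = 100) so that noiseless b = 0 ratios equal the class-mean SIR_b0, and
use the class-mean three-point ADC as the decay rate: benign (S0 201,
ADC 1.40), PTC (132, 0.89), PTMC (117, 0.90). The background decay rate
1.17 is an *effective* rate — chosen so the noiseless SIR pattern
reproduces the observed one (benign SIR falls with b to ≈ 1.23 at b=2000,
carcinoma rises to ≈ 2.29) — and absorbs T2/perfusion effects; it is not a
literature thyroid ADC. Nodules are homogeneous: no within-nodule
heterogeneity model is published for these indicators, so none is
invented.

## Cohort generator

`generate_cohort` draws the six indicators independently per nodule from
normals truncated at zero (indicator values are physically positive), with
class means/SDs and sizes (62 benign, 52 PTC, 33 PTMC) fixed to the
published group summaries. Two consequences matter for interpretation:

* Truncation shifts the mean upward for indicators whose mean/SD ratio is
  small (benign SIR_b2000, 1.23 ± 1.03, shifts by ≈ +0.23). The
  moment-recovery tests therefore use the ADC indicators, which sit ≥ 5
  SDs above zero, where the shift is ≪ sampling error. Simulated AUCs for
  the SIR indicators are correspondingly approximate.
* Indicators are drawn independently, whereas real nodules have strongly
  correlated indicators. Paired ROC comparisons (DeLong z) on generated
  cohorts are therefore checked only for their qualitative ordering (ADC
  subsets far from the SIRs, the two high-b ADCs close together), not for
  printed p-values.

The location-pair generator draws four margin distances per nodule,
scales the counterpart by (1 − shrinkage) — isotropic, matching the
10–15% in-vitro thyroid shrinkage, default 0.12 — and jitters each
distance multiplicatively by a uniform factor 1 ± jitter (default 0.05,
a plausible measurement error; jitter is the only mechanism that breaks
ratio matches, since ratios are scale invariant).

## ADC mapping

Maps are computed voxelwise with no smoothing or filtering. Two-point
subsets use the closed-form log-ratio; three points use unweighted OLS on
log-signals (the standard scanner-console reconstruction; a weighted
nonlinear fit would change noisy-data estimates but not noiseless ones).
Voxels with any non-positive signal are flagged invalid and stored as NaN
— never clamped or zeroed — because silent repair would amount to noise
filtering. The invalidity threshold (S ≤ 0) is the default; callers can
exclude sub-noise-floor voxels at measurement time instead.

## ROI measurement

Signal means are arithmetic means over single-slice ROIs; non-positive
voxels can be excluded (the pipeline does so, and the count of exclusions
is implicit in the validity masks). The normal-tissue reference ROI is the
≈ 1 cm² of background nearest the nodule on the same slice, emulating
adjacent placement. MTD is the maximum Feret diameter: largest
center-to-center voxel distance plus one in-plane voxel, matching a
physical caliper across voxel extents; a single-voxel ROI reports its
diagonal. Far-outside values use Q3 + 3·IQR / Q1 − 3·IQR with type-7
(linear interpolation) quartiles by default and Tukey hinges as an option
— the rule names no estimator, so the most common software default was
chosen. IQ (1–4 image-quality score) is a reader annotation, not computed
from images; records with IQ 1 or any unmeasurability flag are removed by
`apply_exclusions`, which counts each removal once under its first reason.

## Co-localization

Deviations are computed as the ratio difference against *both* sides'
denominators (four percentages per pair) and compared as absolute values;
signed values are retained in reports for diagnostics. Thresholds default
to 10% (ultrasound) and 20% (specimen) but are configuration keys, since
reported matched deviations occasionally exceed the nominal band.
Multi-nodule assignment is greedy on total absolute deviation among
eligible pairs — deterministic and auditable, standing in for the
manual consensus matching that cannot be computed.

## Diagnostics

* **AUC**: Mann–Whitney pair counting, ties ½. Direction auto-detection
  picks the orientation with AUC ≥ 0.5.
* **Youden cutoff**: exhaustive search over observed values; rule
  "score ≤ c" for positive-if-low, "score > c" for positive-if-high, so
  printed cutoffs are observed values (the midpoint to the adjacent value
  is also reported). Ties on J break toward higher sensitivity, then the
  more extreme threshold.
* **CIs**: sensitivity/specificity use exact Clopper–Pearson (beta
  quantiles); AUC uses the DeLong structural-component variance with a
  normal interval truncated to [0, 1].
* **DeLong test**: placement-value covariance of the paired indicators,
  each oriented by its own direction first; z = ΔAUC/SE, two-sided normal
  p. Identical inputs give z = 0, p = 1 exactly.
* **t test**: implemented from (mean, SD, n) summaries (raw arrays are
  reduced to summaries; results equal scipy's), so published group rows
  can be re-tested directly. "auto" selects Welch when a two-sided F test
  rejects variance equality at 0.05.
* **KS normality**: distance to a normal with the sample moments;
  asymptotic p by default, Lilliefors correction (statsmodels) as option
  since the parameters are estimated.
* **ICC**: two-way single-measure absolute-agreement, ICC(A,1), with the
  McGraw–Wong F-based interval; chosen because agreement (not mere
  consistency) is what repeated nodule measurements require. Verified
  against pingouin and a hand ANOVA.
* **Sample size**: `N = ⌈z²p(1−p)/δ²⌉`, floored at 1.
* No multiple-testing correction is applied to pairwise ROC comparisons
  (raw p-values are the convention in this literature); a Bonferroni
  adjustment is a one-liner for users who need it.

`evaluate_indicator` treats PTMC as a subset of PTC when selecting the
diseased group: "PTC" compares benign against all carcinomas, "PTMC"
against microcarcinomas only.

## Problem sizes and tolerances

Test simulations use sizes chosen to make Monte-Carlo error a small
fraction of the tested effect: 2 × 10⁵ draws for noise-floor moments,
1000 cohort replicates (each 62 + 52) for the headline AUC (MC error
≈ 0.001, tolerance ± 0.02 around the reported 0.944; the binormal
expectation for the given summaries is Φ(0.51/√(0.27² + 0.16²)) ≈ 0.948),
500 replicates for the ROC-comparison ordering, 10⁴ paired bootstrap
resamples for the DeLong variance cross-check (relative tolerance 40%,
dominated by small-sample bootstrap bias at n = 15–20 per class), and
exact pmf enumeration (no simulation) for Clopper–Pearson coverage.
Noiseless round-trips are asserted at 10⁻⁹ (closed form) and 10⁻⁶ (OLS).

## Known limitations

* The phantom has no susceptibility artifacts, distortion, partial
  volume, or k-space simulation; "image quality" is an annotation.
* Independent indicator draws understate the correlation structure of
  real cohorts (see above); patient-level AUC/ICC/t values from the real
  study are not reproducible from summaries and are not targeted.
* Only isotropic shrinkage is modelled between MR and specimen; real
  specimens deform anisotropically.
* The ultrasound arm enters only as printed confusion tables; no TI-RADS
  model is included.
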