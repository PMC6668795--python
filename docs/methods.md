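# Methods

`cathdose` implements an automated patient-dose and radiation-risk pipeline
for paediatric cardiac catheterization: per-event exposure records are
aggregated into procedures, normalized into diagnostic-reference-level (DRL)
parameters, converted into organ and effective doses through regression
conversion factors, and finally into lifetime attributable risk (LAR) of
cancer incidence and mortality. This note records the models, the
assumptions behind them, and the numerical choices made where the design was
genuinely open.

## Dose quantities and units

All dose-area product (DAP, strictly air kerma–area product) values are
canonical cGy·cm² internally; air kerma at the interventional reference
point is mGy; durations are seconds. Reader dialects (Gy·m², µGy·m²,
Gy·cm², ...) are converted once at ingestion and exported headers spell the
units out. Fluoroscopy time enters DAP_BWxFT in minutes, giving the
conventional cGy·cm²·kg⁻¹·min⁻¹ scale; it is stored in seconds and converted
only at that boundary.

## DRL statistics

A DRL is the 75th percentile of a cohort distribution — a threshold for
flagging unusually high exposures, not a dose limit. Supported parameters:
DAP, air kerma, fluoroscopy time, cine frame count, DAP normalized to body
weight (DAP_BW), and DAP normalized to body weight × fluoroscopy time
(DAP_BWxFT). Grouping is per procedure type, per paediatric weight band
(<5, 5–<15, 15–<30, 30–<50, 50–<80, ≥80 kg; half-open intervals, so 15.0 kg
falls in 15–<30), or pooled.

Numerical choices:

* **Percentile convention.** Linear interpolation between order statistics
  at rank h = (n−1)p + 1 (numpy's `"linear"`), the common
  statistics-package default. At the small n of per-type groups the P75
  shifts between conventions, so the method tag is recorded in every
  emitted table and is configurable.
* **Small samples.** Groups with fewer than 20 procedures are flagged,
  following the European paediatric DRL guidance that reference levels need
  at least 20 cases per procedure type.
* **Alerts.** Exceedance is strict (`value > DRL`); equality does not
  trigger. Cine-only procedures have no DAP_BWxFT (undefined, not zero);
  alerts for them fall back to DAP_BW. Secondary parameters (fluoroscopy
  time, frames, kerma) above their own P75 are attached as candidate causes.

## Group comparison suite

The statistical validation behind the choice of DRL parameter:

* Kruskal–Wallis H across procedure types (tie-corrected, chi-square
  p-value), via `scipy.stats.kruskal`.
* Dunn's rank-based pairwise post-hoc, written in-package: z is the
  mean-rank difference over `sqrt((N(N+1)/12 − Σ(t³−t)/(12(N−1)))(1/nᵢ+1/nⱼ))`,
  with Bonferroni-adjusted two-sided normal p-values (α = 0.05 default).
  With nine procedure types this yields 36 pairs.
* OLS regressions (statsmodels) with 95% t-intervals of the slope; the R²
  of DAP on BW×FT versus DAP on BW alone is the comparison that motivates
  the time-normalized parameter.
* CI95/med: the percentile-bootstrap 95% CI of the median (B = 2000,
  seeded), expressed as a percentage of the median — a sample-size
  diagnostic for DRL parameters. The metric is cited in the DRL literature
  without a construction; the bootstrap is this package's choice and the
  replicate count and seed are echoed in the output.

## Conversion-factor dose engine

Organ doses (mGy) and effective dose (mSv) are linear in weight-normalized
DAP:

    dose = CF(target, weight band, plane) × DAP_BW,   DAP_BW in Gy·cm²·kg⁻¹

The shipped table carries published slopes per weight band for thirteen
organ targets and effective dose (ICRP 103 weighting), each for a combined
biplane/total factor and separate frontal and lateral C-arm factors.
Internally DAP_BW arrives in cGy·cm²/kg and is divided by 100 at exactly one
boundary point. Per-plane mode applies the frontal and lateral factors to
their DAP shares and sums — the more accurate option on biplane systems.
Patients above the table's weight range use the ≥80 kg band. Effective dose
can also be recomposed from organ doses as ED = Σ w_T·H_T under ICRP 103 or
ICRP 60 tissue weights; tissues without a dose count as zero with a warning.

**Deriving new tables.** `derive_cf_table` regresses reference doses
(Monte Carlo output, or the synthetic generator's ground truth) on the
matching plane's DAP_BW per weight band, keeping an intercept and reporting
the slope as the conversion factor. The fit is **variance-weighted with
weights 1/x²**: dose scatter about the conversion line is multiplicative,
so the response variance grows as the square of DAP_BW. An unweighted OLS
slope is dominated by the few highest-dose procedures and its homoscedastic
confidence interval is badly anticonservative under this error structure
(empirically ~30% coverage at band sizes around 30; heteroscedasticity-robust
HC3 intervals reach only ~85%), whereas the 1/x² weighting is the
correctly-specified generalized least squares for a multiplicative error
and achieves near-nominal coverage. Lateral factors are fitted only on
procedures with nonzero lateral DAP; bands with fewer than three procedures
are omitted. A through-origin mode exists because the usage
`dose = CF × DAP_BW` implies a zero intercept; the mode is recorded in the
output.

## Phantom geometry and focal-spot-to-skin distance

For each irradiation event a simulation-job descriptor is built the way a
Monte Carlo dosimetry chain would consume it: reference phantom class,
patient scaling, C-arm pose, beam quality, and the focal-spot-to-skin
distance (FSD).

* **Phantom selection.** Six reference classes (newborn, 1, 5, 10, 15 y,
  adult) from the hermaphrodite mathematical-phantom series; the class with
  the nearest nominal age wins, ties breaking toward the older class (a
  3-year-old gets the 5 y phantom). Reference dimensions ship as an
  editable CSV — they are configuration, not hard-coded physics.
* **Scaling.** Height scales the longitudinal axis
  (s_h = height/reference); the transverse scale follows from mass
  conservation under uniform density, s_t = sqrt((weight/ref_weight)/s_h),
  so ref_weight·s_h·s_t² equals the patient weight exactly.
* **FSD.** The trunk is an elliptical cylinder at heart level and the heart
  sits at the C-arm isocenter (offset configurable, default on the trunk
  axis). The central ray from the heart toward the source pierces the
  ellipse at a closed-form distance d (line–ellipse intersection);
  FSD = source-to-isocenter distance − d. Cranio-caudal angulation is
  handled by projecting onto the transverse plane and dividing by
  cos(secondary angle) — exact for a cylinder, an approximation for a real
  trunk; angulations beyond ±90° are rejected. Correctness is established
  against a numeric ray-marching oracle to <0.1 mm, not against published
  phantom tables. Beam area at the skin is approximated as DAP/kerma when
  both are reported.

Angle conventions are RAO−/LAO+ (primary) and CAU−/CRA+ (secondary); the
lateral C-arm of a biplane system acquires near-LAO-90 projections.

## Lifetime attributable risk

Risk coefficients give cases (or deaths) per 100,000 persons exposed to
0.1 Gy, by cancer site, sex and age at exposure, at a native DDREF of 1.5.
LAR scales linearly in dose:

    LAR = dose_Gy/0.1 × coefficient × 1.5/DDREF

* **Age interpolation** is linear between the grid ages (0, 5, ..., 30, 40,
  ..., 80), clamping beyond the ends; interpolated values are bounded by
  their bracketing cells.
* **DDREF.** The ICRP-recommended DDREF of 2 multiplies by exactly 0.75.
  Internal values stay unrounded; report formatting rounds to whole cases
  per 100,000, and the conventional DDREF-2 report figure rescales the
  already-rounded DDREF-1.5 figure (33 → 24.75 → 25), mirroring how such
  chains are printed in practice.
* **Site map.** A user-editable map assigns each cancer site its dosimetric
  organ (lung←lungs, leukaemia←active bone marrow, "other"←sex-specific
  remainder, ...); the all-cancer LAR is the sum of mapped per-site LARs.
  Sex-specific sites (breast, ovary, uterus, prostate) contribute zero for
  the other sex, and sites absent from a table kind (e.g. thyroid has no
  mortality row) are skipped rather than invented.
* **Fixture fidelity.** The packaged coefficient CSV is a transcription of
  the public BEIR VII Phase 2 lifetime-risk tables covering the sites used
  here. Users applying the package beyond the anchor cells exercised by the
  test suite should verify the transcription against the report and can
  drop in their own CSV (`RiskCoefficientTable.from_csv`).

## Synthetic cohorts

The generator emulates the case stream of a single paediatric
catheterization centre so that every pipeline stage and every
parameter-recovery test runs without clinical data:

* Procedure-type mix proportional to a realistic single-centre count vector
  (diagnostic plus eight interventional types).
* Age log-normal with median 4.3 y and log-sd 2.0, clipped to
  [0.005, 70] y — newborns through adult congenital patients. Weight and
  height follow log-linear growth anchors with log-normal noise
  (sd 0.15 / 0.04); these are simple parametric curves sufficient for
  structure, not population-reference demographics.
* DAP model: DAP = k_type × BW × FT × exp(ε), ε ~ N(0, 0.8²). The
  multiplicative form makes DAP_BWxFT log-normal around k_type and
  reproduces the heavy right skew of real DAP distributions; k_type values
  are back-solved so each type's P75 of DAP_BWxFT lands at a plausible
  clinical magnitude (pooled ≈ 2 cGy·cm²·kg⁻¹·min⁻¹). σ = 0.8 matches the
  order-of-magnitude interquartile spans seen in practice.
* Fluoroscopy contributes a Beta-distributed share of DAP (median 0.91
  interventional / 0.77 diagnostic); biplane usage is Bernoulli (0.73 /
  0.85); lateral DAP share is Beta with mean 0.35. Events per procedure are
  Poisson with mean 63, split across the fluoro/cine × frontal/lateral
  cells by Dirichlet weights so the event stream aggregates back to the
  summaries exactly.
* Ground-truth doses are CF × DAP_BW per plane, each plane's reference
  generated from its own slope so parameter recovery has a single
  well-defined truth; `attach_reference_doses` multiplies by exp(η),
  η ~ N(0, noise_sd²), as a stand-in for per-procedure Monte Carlo output.

What passing tests on these cohorts show: the estimators recover the
parameters the generator encodes, under the generator's error model. What
they cannot show: robustness to vendor-specific export quirks, real growth
curves, correlated per-event physics (kVp/filtration/field size), or
centre-to-centre practice differences.

## Problem sizes in the test suite

Unit and property tests use cohorts of 50–500 procedures; the
conversion-factor recovery check runs 100 replicates of 400-procedure
cohorts with reference-dose noise sd 0.1 and requires ≥90% CI coverage of
the generating lung slope in the 30–<50 kg band, alongside the
R²(DAP~BW×FT) > R²(DAP~BW) ordering in every replicate. The FSD oracle grid
covers primary angles −180°..180° in 20° steps, three cranio-caudal angles
and four trunk geometries. These sizes were chosen to make the statistical
assertions stable across seeds while keeping the suite quick.

## Known limitations

* No photon transport: the dose engine is conversion-factor based; a Monte
  Carlo engine can be plugged in by consuming the per-event job files.
* Rotational angiography events are excluded at validation (their exports
  lack the information needed for simulation), as is standard for this
  pipeline class.
* Effective dose and LAR are population-level constructs; per-patient risk
  communication is out of scope by design.
* ICRP 60 effective-dose conversion factors are not shipped; ICRP 60 is
  available only through the organ-dose recomposition path.
* The trunk surface model is a scaled elliptical cylinder; skin-dose
  mapping and organ-boundary geometry beyond the trunk are out of scope.
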