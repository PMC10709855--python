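# Methods

This note documents the models, algorithms and design choices behind
`bfgrowth`, in the spirit of a statistical software methods appendix.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Scope

The package builds weight-for-age and height-for-age centile standards
for exclusively breastfed infants aged 0–182 days from survey
microdata. Real survey files (e.g. MICS round-6 province files) are
consumed as a canonical CSV via a variable map; the package also ships
a synthetic-survey generator with known ground truth, which is what the
test suite and the acceptance script run on. Survey-design weights are
not used for chart fitting, and the upstream derivation of the
singleton/full-term/birth-order/non-smoking flags from birth-history
files is out of scope — they enter as booleans.

## Case selection

Three indicators are derived from raw items; all other criteria are
direct field comparisons.

* **Exclusive breastfeeding (EBF).** With Z the still-breastfed flag,
  X the sum of nine binary liquid-recall items and Y the sum of
  fifteen binary food-recall items (24-hour recall):
  `EBF = 1 iff Z = 1 and X + Y = 0`.
* **Severe illness.** With L1–L4 the two-week recall of diarrhea,
  fever, cough and breathing difficulty:
  `L = 1 iff L1 = 1 and (L2 = 1 or L3 = 1 or L4 = 1)`.
* **Household congestion.** Adults per sleeping room
  `C = (C1 − C2 − C3)/C4` from household members, under-5 count,
  5–17 count and sleeping-room count; non-congested means `C ≤ 2`
  (the boundary value 2.0 passes).

Inclusion requires: age ≤ 182 days, singleton, full term, birth order
≤ 4 (inclusive), non-smoking mother, EBF = 1, no severe illness, and a
non-congested household. Each criterion is a pure per-record
predicate, so the chain is idempotent and order-invariant; the
selection report verifies order-invariance on every run.

**Missingness** is a value, not an error. Under the default `exclude`
policy a child with missing Z or feeding items cannot be certified
exclusively breastfed and is *undetermined* (dropped); severe illness
is undetermined when L1 is missing, or L1 = 1 with all companion
symptoms missing; congestion is undetermined when the room count is
missing or zero, or when the computed adult count is negative (treated
as a data error, not clipped). `treat_missing_as_zero` is available
for sensitivity analysis. Survey don't-know codes (8/9) in binary
items are read as missing, never as "No".

## Cleaning

Weight and height are cleaned as independent analysis files, so a
record can contribute to one chart and not the other. Stage 1 drops
records with missing sex, missing or non-positive measurements, or
ages outside the window. Stage 2 applies a hard plausibility window
(defaults 0.5–15 kg, 35–95 cm) and then a per-sex provisional fit on
the normal scale — a df-3 penalized-spline mean curve with an
age-varying spread estimated from absolute residuals (scaled by
√(π/2)) — flagging |z| > 4. Groups under 50 records per sex skip
stage 2 with a warning; a spread floor guards degenerate zero-variance
groups. No published cleaning rule exists for the motivating survey
analysis, so these thresholds are configurable and the post-cleaning
counts of any particular external dataset should not be expected to
reproduce exactly.

## Distribution families

All three families are built on the Box-Cox z-transform
`z = ((y/μ)^ν − 1)/(νσ)` (log form at ν = 0, computed via `expm1` so
the two branches agree to machine precision), followed by a symmetric
kernel: standard normal (BCCG), power-exponential with power τ scaled
to unit variance (BCPE), or Student-t with τ df (BCT). The truncation
constant for `y > 0` — the kernel cdf at `1/(σ|ν|)` — is included
exactly rather than approximated, because σ is not small for infant
weight (≈ 0.19 here). Kernels are implemented on `scipy.special`
primitives (`ndtr`, `gammainc`, `stdtr` and inverses) for speed inside
the fitting loop; the power-exponential kernel is verified against
`scipy.stats.gennorm` in the tests, and normalization of all three
families is checked by an independent quadrature oracle over a
parameter lattice. cdf and quantile use the truncated-kernel closed
forms, so `quantile∘cdf` is an identity to ~1e-8 over the central
99.8% of the distribution (outside it the cdf saturates in double
precision). `lms_centile` provides the familiar LMS back-transform
`y = M(1 + L·S·z_p)^{1/L}` with the kernel quantile as `z_p`.

One numerical caveat: for the heaviest kernels (BCT with τ ≤ 1.5 at
ν = 0) a non-negligible tail mass lies beyond float-representable `y`;
the normalization test therefore closes the quadrature with the cdf
tail mass, which simultaneously checks pdf/cdf consistency.

## Smoothers and degrees of freedom

* `ps` — Eilers–Marx P-spline: cubic B-splines on a uniform knot grid
  (20 interior knots) extended past the boundaries, second-order
  difference penalty. The uniform grid puts straight lines exactly in
  the penalty null space, so linear trends are never shrunk.
* `cs` — natural cubic smoothing spline: natural-spline basis on 20
  equally spaced knots with the exact integrated-squared-second-
  derivative penalty (Simpson per interval, exact for the piecewise-
  linear second derivatives).
* `poly` — unpenalized monomials.

Ages are rescaled to [0, 1] internally for conditioning; evaluation
beyond the fitted range extends the curve linearly with a warning.

**df convention.** A smoother's df counts effective degrees of freedom
beyond the intercept: df = 0 is a constant, df = 1 a straight line,
and df ≥ 2 resolves the penalty by monotone bisection so the
smoother-matrix trace equals df + 1 (to 1e-3). This convention makes
the selected triple (L = 0, M = 1, S = 0) a meaningful model — median
linear in age on the log-link scale, constant σ and ν — and matches
the grid semantics in which a polynomial with df = 0 anywhere is
declared non-convergent (NA).

## Fitting algorithm

RS-type backfitting over (μ, σ, ν, τ): each parameter's linear
predictor is updated by one penalized weighted least-squares step on
the working variable `z = η + u/w`, with score `u` and curvature `w`
obtained by central differences of the family log-likelihood on the
link scale (log links for μ, σ, τ; identity for ν; step h = 1e-3).
Numerical differentiation was chosen over hand-coded derivatives for
uniformity across the three families; it is validated against direct
MLE on constant-parameter data in the tests.

Two safeguards matter in practice. First, the pointwise observed
curvature can be negative or near zero; such values are replaced by
the median positive curvature. Steps are *not* clipped: since
`w·(u/w) = u`, flooring weights leaves the aggregate update aligned
with the total score, whereas clipping silently discards score mass
and can reverse the update direction. Second, every accepted step is
deviance-guarded with step-halving (up to 8 halvings, else revert), so
the global deviance is non-increasing across cycles by construction.
Convergence is declared when the deviance changes by < 1e-4 in a full
cycle (cap 200 cycles); non-convergence is reported as a flag and
enters selection grids as NA, not as an exception. τ is modeled as a
constant on the log scale — the published procedure reports a single
τ per curve and searches df only over L, M, S. Initialization: μ from
a weighted fit to log y, σ from the residual sd of log y, ν = 1,
τ = 2 (BCPE) or 10 (BCT).

Model complexity is the summed smoother-matrix trace;
AIC = deviance + 2·edf, BIC = deviance + ln(n)·edf.

## Model selection and validation

Stage 1 fixes the family to the LMS baseline (BCCG) and smoother to
`ps` and minimizes BIC over the exhaustive 4×4×4 df grid (ties: lower
total df, then lexicographic on M, L, S — the procedure's source
reports no ties, so the tie-break is this package's convention).
Stage 2 fits the 3 family × 3 smoother grid at the chosen df and
minimizes AIC (ties: BCCG < BCPE < BCT, then ps < cs < poly).
Note that under the df convention above, df specifications of only 0s
and 1s make the ps and cs fits coincide exactly (both reduce to
constants/lines), so their AICs tie and the ps cell is chosen by
order — consistent with the published preference for ps at those df.

Validation is a week-stratified (week = ⌊days/7⌋) 70:30 split: fit on
the 70%, report held-out global deviance and the empirical fraction of
held-out observations falling below the fitted 3rd/50th/97th centiles.
The validation metric pair is this package's choice; the motivating
procedure names the split but not the metric.

## Synthetic-data generator

The generator emulates an under-six-months extract of a MICS-like
survey. Defaults are fixed at the study's conditions:

* **Median curves** log-linear in age, anchored to the published
  weekly sample means (boys' weight 3.26 kg at week 1 → 6.92 kg at
  week 26; girls 3.22 → 6.19 kg; boys' height 48.74 → 65.07 cm;
  girls 48.87 → 63.54 cm), i.e. exactly the M = 1 (log-link) regime.
* **σ** constant at 0.185 (weight) and 0.055 (height), on the
  coefficient-of-variation scale of the weekly summaries; **ν** = 1;
  **τ** per curve at the fitted values 1.660418, 1.448022, 1.188859,
  1.114607 (W/A male, W/A female, H/A male, H/A female).
* **Prevalences** p_ebf = 0.55, p_severe = 0.08, p_congested = 0.09,
  p_singleton = 0.985, p_fullterm = 0.90, p_birthorder≤4 = 0.80,
  p_nonsmoking = 0.97, whose product ≈ 0.317 matches the published
  overall yield (3,655 of 11,478). Criteria are independent by
  default, making expected yields analytic; a shared-latent-factor
  correlation knob exists but defaults to off.
* **Anthropometry missingness** 3.15% (weight) and 3.83% (height),
  from the published post-cleaning attrition.
* Province shares 23.0/40.1/22.4/14.5% and 23.6% urban, from the
  published sample composition. Ages are uniform on integer days
  0–182 — the real per-day age distribution is unpublished, so
  uniformity is an assumption.

Raw items are generated to be exactly consistent with the latent
indicators (e.g. a mixed-fed child always has at least one liquid or
food item set), so re-deriving EBF/illness/congestion from the raw
variables reproduces the latent truth record-for-record. What the
generator does **not** emulate: cluster sampling and design effects,
within-household correlation, age heaping, measurement error, or
informative missingness. Passing tests therefore demonstrate
correctness of the algorithms under the stated model, not robustness
to every artifact of real survey data.

## Problem sizes in the checks

The statistical acceptance tests run at the analysis scales the
procedure itself uses: n = 3,500 per curve for parameter recovery
(5 seeds), n = 3,500 × 20 replicates for the family-power check,
n = 1,500 × 20 replicates for the BIC df-grid check, n = 3,000 for
cross-validation coverage, and n = 10,000 for the selection-chain
yield. The acceptance script runs the full pipeline at the survey
scale of 11,478 children.

## Known limitations

* Curvature regularization (median-positive replacement) is a
  pragmatic quasi-Fisher device; badly misspecified models (e.g. a
  trending σ under a constant-μ specification) can oscillate and are
  reported as non-converged rather than rescued.
* The df grid tops out at 3 by design; the machinery supports larger
  grids but tie-break behavior beyond the published range is untested.
* `cs` uses 20 fixed knots rather than knots at every distinct age;
  for n in the thousands this is a standard low-rank approximation.
* Centile non-crossing is asserted on every generated table but is a
  property of monotone quantile functions at each age, not a joint
  constraint across ages; pathological fits would be caught by the
  table invariant, not prevented.
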