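# Methods

## Models

**Four-compartment fat mass.** FM = 2.748·BV − 0.699·TBW + 1.129·Mo −
2.051·BM, with BV in litres, TBW in litres, Mo and BM in kg. TBW is
stored in litres and enters as a mass equivalent at water density 1
(1 L = 1 kg). Mo is derived from DXA bone mineral content as
Mo = 1.0436·BMC. BF% = 100·FM/BM and FFM = BM − FM, so FM + FFM = BM is
an exact identity of every estimate, not a numerical coincidence. All
coefficients are the exact decimal literals of their published sources;
nothing is re-fitted.

**DXA body-volume predictions.** BV_SR = FM/0.84 + LM/1.03 + BMC/11.63 −
3.12 and BV_W = 0.95·LM + 1.14·FM + 0.21·BMC + 0.01. The Wilson
intercept is implemented as printed (+0.01 L); all coefficients are
exposed through the module constants should a sensitivity analysis need
to perturb them. Because the Wang equation is linear, switching the BV
source changes fat mass by exactly 2.748·ΔBV — a property the test suite
checks directly.

**Incoherent inputs.** Physiologically impossible measurement
combinations can produce negative FM or BF% outside [0, 100]. Estimates
are returned as computed and carry quality flags
(`negative_fat_mass`, `bf_percent_out_of_range`); nothing is clamped, so
group statistics remain auditable back to the raw arithmetic.

## Classification

Groups: NW (BMI < 25 kg/m² and waist below threshold), OW_BMI (BMI ≥ 25,
waist below threshold), OW_BMI_WC (BMI ≥ 25 and waist ≥ 88.0 cm women /
102.0 cm men). Both boundaries are inclusive on the at-risk side
(BMI = 25.0 is overweight; waist exactly at threshold is at-risk). The
BMI-below-25/at-risk-waist cell has no defined group and is labelled
UNCLASSIFIED, counted, and dropped from validity reports.

The two overweight groups are mutually exclusive by default: OW_BMI
requires a below-threshold waist. The published group sizes (40 vs 35)
and the OW_BMI group's below-threshold mean waists support this reading,
but it is a design choice, so `group_mode="inclusive"` implements the
alternative in which every BMI ≥ 25 subject is also an OW_BMI member.
Age eligibility (18–65 y) and free-text exclusion flags are applied at
the schema level before classification, each logged with counts.

## Agreement statistics

* CE = mean(predicted − criterion).
* Paired t on the differences, df = n − 1, two-sided p; significance is
  inclusive at the Bonferroni-adjusted alpha 0.05/2 = 0.025. Degenerate
  zero-variance differences report p = 0 (nonzero mean) or p = 1 (all
  zero), flagged.
* Cohen's d = |mean₁ − mean₂| / √((s₁² + s₂²)/2). This pooled-SD form
  reproduces the reference study's printed effect sizes in its
  normal-weight and at-risk-waist blocks; its BMI-only block's printed
  values fit no standard formula and are not used as fixtures. Hopkins
  bins: ≤0.2 trivial, ≤0.6 small, ≤1.2 moderate, ≤2.0 large, >2.0 very
  large; exact boundaries go to the lower bin.
* Pearson r, magnitude binned on |r|: <0.31 small, <0.50 moderate,
  <0.70 large, <0.90 very large, ≥0.90 near perfect.
* SEE from regressing the **criterion on the predicted** values:
  √(Σe²/(n−2)) = sd_crit·√(1−r²)·√((n−1)/(n−2)). This direction
  reproduces the reference normal-weight SEEs from the printed sd/r;
  the reverse direction does not.
* TE = √(Σd²/n) with denominator **n**; the SD of differences uses
  **n − 1**. These conventions are stated here because the validity
  literature cites rather than defines them. They give the identity
  TE² = CE² + ((n−1)/n)·SD², verified to 1e-9 relative tolerance.
* Bland-Altman limits: CE ± 1.96·SD of differences; per-subject points
  (mean of methods, difference) are exported for plotting. No confidence
  intervals on the limits are computed.
* Proportional bias: OLS of differences on the mean of the two methods
  (standard Bland-Altman regressor; configurable to the criterion),
  two-sided p for slope = 0.

Display rounding happens only at serialization: 1 decimal for BF% means,
CE and limits of agreement; 2 for d, SEE, TE; 3 for r, regression
coefficients and p-values. In-memory values are never rounded.

## Synthetic cohort generator

The generator emulates the reference study's six group × sex cells
(20/20/20/20/14/21 subjects). Per subject: height and BMI are truncated
normals at the cell's published mean ± SD (BMI truncated to the group's
admissible side of the 25 kg/m² cut-off; rejection sampling, since the
bounds are loose and acceptance is high); BM = BMI·(height/100)²; latent
BF% is a truncated normal on (2, 60)%; FM* = BF%·BM/100, FFM* = BM − FM*.
Water and bone follow textbook physiology — TBW = h·FFM* with hydration
h ≈ 0.732 L/kg (between-subject SD 0.01) and BMC = b·FFM* with
b ≈ 0.05 (SD 0.004) — because the study characterizes neither beyond
device names. Device noise is additive: ADP volume SD 0.3 L, DXA fat and
lean 0.5 kg, BMC 0.05 kg, TBW 0.8 L; values chosen as typical test-retest
precision for these instruments, and all exposed in the YAML config.

The ADP volume is constructed by inverting the Wang equation around the
stored (noisy) TBW and BMC plus ADP noise, so the criterion model
recovers the latent BF% exactly when ADP noise is zero — the anchor of
the parameter-recovery tests. Waist circumference is drawn uniformly on
the published mean ± 2 SD band intersected with the label-consistent
side of the sex threshold (the study gives no joint BMI–waist
distribution), so every generated subject classifies into its intended
group. Marginals are otherwise independent: the published tables give no
correlation structure, so none is imposed (e.g. height–BMI).

One integer seed drives the whole cohort; each cell draws from a
sub-stream derived via a fixed spawn key, so changing one cell's n never
perturbs another cell and a given seed yields byte-identical CSVs.

**What the generator is not.** It is a test harness, not a population
model: it does not reproduce real inter-device error covariances, the
reference study's actual biases between ADP and the DXA volume equations,
or DXA's internal fat/lean partitioning error. Consequently pipeline runs
on synthetic cohorts demonstrate that the statistics are computed
correctly, not that the reference study's agreement values recur; lean
synthetic subjects can even drive the Smith-Ryan model to (flagged)
negative fat mass. Passing tests certify arithmetic and statistical
machinery, and recovery of parameters the generator controls.

## Numerical and interface choices

* t and regression p-values use scipy's t distribution; no simulation.
* Regression statistics require n ≥ 3; groups below that are skipped
  with a warning rather than reported.
* A plausibility check warns (never fails) when DXA FM + LM + BMC
  misses body mass by more than 5%.
* The subject CSV schema is strict: missing columns fail immediately,
  malformed rows fail with their line number, sex is "M"/"F"
  case-insensitive. Floats round-trip losslessly through the writer.
* Outputs are ordered (group, then method) and serialized
  deterministically; run metadata carries config echo, seed and stage
  counts but no timestamps, so identical runs are byte-identical.

## Problem sizes

The packaged default run uses the study-sized 115-subject cohort. The
delta-method noise-propagation test uses a single degenerate cell of
10,000 identical subjects (only ADP noise active), where the SD of the
4C-DXA1 − 4C-ADP fat-mass differences must equal 2.748·σ_ADP within 5%;
the moment-recovery test uses one 2,000-subject cell against scipy's
closed-form truncated-normal moments. Property suites run 200–1000
random series. The whole suite completes in a few seconds.

## Known limitations

* The criterion's validity itself is assumed, not tested: everything is
  agreement relative to 4C-ADP.
* Only the two shipped BV regressions are implemented; no two-compartment
  (Siri/Brozek) or underwater-weighing alternatives.
* The UNCLASSIFIED cell is dropped rather than modelled; cohorts heavy in
  lean-but-large-waist adults will lose subjects.
* Printed-summary fixtures inherit the rounding of their source tables;
  worked-example checks therefore carry ±0.05-type tolerances where input
  rounding limits agreement.
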