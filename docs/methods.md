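# Methods

`akiplanner` implements a decision-support method for cardiac anesthesia:
given a patient's preoperative profile, it proposes intraoperative
anesthesia parameters with low risk of postoperative acute kidney injury
(AKI) and quantifies how risky any physician-chosen plan is. This note
documents the model, the synthetic cohort it is exercised on, and the
numerical choices a maintainer would want to know about.

## The dual-planner model

Patients are stratified by outcome: AKI+ (KDIGO stage ≥ 1 on postoperative
day 1 or 7) versus AKI−. Two regression networks with identical
architecture — the **AKI− Planner** and **AKI+ Planner** — are trained on
their respective strata to map the eight preoperative features

> Age, BMI, CCB use, serum creatinine (Cr), albumin (Alb), blood sugar
> (BS), HbA1C, hematocrit (Hct)

to the six intraoperative anesthesia parameters

> anesthesia time (min), CPB time (min), diuretic dose (mg), crystalloid
> dose (L), packed-cell transfusion (0/1), fresh-frozen-plasma transfusion
> (0/1).

Each planner's output is the plan a *typical patient of that stratum with
this profile* received: the AKI− output is a patient-specific low-risk
prototype, the AKI+ output a high-risk prototype.

**Architecture.** "Three-layer network" is implemented as
8 → 16 (ReLU) → 8 (ReLU) → 6 (linear), trained on standardized inputs and
targets with a single joint MSE loss (binary targets as 0/1). The exact
layer sizes are not critical on data of this size; they are isolated in
`ArchConfig` and overridable. Optimization is Adam (initial rate 1e-3,
batch 64, ≤ 2000 epochs) with early stopping on a seeded 10% validation
slice, patience 50. Training is bit-reproducible given the seed. A
degenerate stratum whose targets are all constant bypasses gradient
descent: the exact MSE minimizer (a zero network on standardized targets)
is returned directly, since a variance-based validation score is undefined
there.

**Prediction.** The fitted weights are extracted and the forward pass is
re-implemented in numpy, so models serialize losslessly to JSON.
Continuous outputs are inverse-standardized and clipped to plausible
clinical ranges; binary outputs are reported as probabilities in [0, 1]
(thresholded at 0.5 only for display); `cpb_time ≤ anesthesia_time` is
enforced by a final clip.

## The risk geometry

A proposed plan **t** for a patient with profile **x** is located by

d₋ = ‖z(t) − z(f₋(x))‖₂,  d₊ = ‖z(t) − z(f₊(x))‖₂,

where f₋, f₊ are the two planners and z(·) standardizes each of the six
parameters by the mean/SD of the pooled *training* plans (`PlanScaler`).
Without standardization the metric would be dominated by minutes over
liters; the binary parameters enter as continuous values (predicted
probabilities are never thresholded inside the metric).

- **Classification (y = x rule).** A plan is predicted AKI+ iff
  d₊ ≤ d₋ — it sits on or below the y = x line in the (d₋, d₊) plane,
  i.e. nearer the high-risk prototype. The on-line tie goes to AKI+, the
  clinically conservative choice. This is exactly a nearest-prototype rule,
  which the tests verify against a brute-force argmin on random fixtures.
- **Safety margin.** m = d₊ − d₋. Positive margins mean the plan is nearer
  the low-risk prototype; the recommender ranks candidate plans (the AKI−
  prediction plus a seeded uniform scan of the slider box) by descending
  margin. By the triangle inequality the AKI− prediction itself always
  attains the maximal margin ‖z(f₋) − z(f₊)‖.
- **Plan-shift comparison.** For an administered plan (point R1) and a
  proposed one (R2), the proposal *improves* iff its margin strictly
  increases — the point moves up relative to the y = x line.
- **Evaluation.** Each test patient's administered plan is classified and
  tallied against the true outcome (AKI+ positive). Precision, recall,
  accuracy and F1 are reported at 3 decimals, **truncated** by default:
  the published metric rows are jointly consistent only under truncation,
  with F1 computed as the harmonic mean of the already-truncated precision
  and recall. Rounding mode is configurable.
- **Candidate treatments.** k-means (k = 3, k-means++, seeded, on z-scored
  plans) clusters the training plans into candidate treatments; each
  cluster is labeled low-/high-risk by its members' majority stratum and
  reported as center ± within-cluster SD in clinical units. Expert-panel
  scaffolding is limited to `majority_vote` (modal choice of three raters;
  a 1-1-1 tie returns the first rater's vote with a tie flag).

## KDIGO staging

Serum-creatinine criteria only (the schema has no urine output or RRT
data). Against the preoperative baseline, each postoperative day stages:

| stage | trigger |
|---|---|
| 3 | ratio ≥ 3.0, or creatinine ≥ 4.0 mg/dL reached with a rise ≥ 0.3 |
| 2 | ratio ≥ 2.0 |
| 1 | ratio ≥ 1.5, or absolute rise ≥ 0.3 mg/dL |

The 0.3 mg/dL rise applies to each day against baseline. The stage is
monotone in the postoperative value; ratio triggers are scale-invariant,
the absolute triggers deliberately are not.

The 85/15 train/test split is stratified by group with *floor* allocation
of the training count, which reproduces the published bookkeeping exactly:
472 AKI− → 401/71, 526 AKI+ → 447/79, totals 848/150.

## The synthetic cohort

Patient-level data are unavailable, so a seeded generator
(`generate_cohort`) emulates the published cohort's statistical structure.
It is the study condition for every end-to-end test, not a tuning knob.

**Marginals.** Continuous features are truncated normals (truncated
log-normals for the right-skewed creatinine and diuretic dose) clipped to
the published ranges. The parent parameters are solved numerically so the
*truncated* mean/SD equal the published values: CPB time's lower clip sits
only 1.8 SD below its mean, and naive truncation would bias the cohort
mean by ≈ +2.4 min. With moment matching, sample means are unbiased for
every feature and the 3-SE calibration checks hold by construction.
Defaults: age 57.44 ± 11.40 [18, 85], BMI 26.76 ± 3.04, Cr 1.24 ± 0.80
[0.5, 12], Alb 3.85 ± 0.66, BS 162.03 ± 53.4, HbA1C 6.16 ± 1.19, Hct
39.34 ± 4.10, CCB rate 0.2915; CPB 112.44 ± 32.33 [53, 350], anesthesia
time 346.81 ± 71.29, PC rate 0.587, FFP rate 0.490. Where the published
anesthesia-parameter table is internally inconsistent (a 130–160 min
"range" against a 346.81 min mean; a 0.03 L crystalloid SD; a diuretic row
repeating the BMI statistics) the mean ± SD is trusted where
self-consistent and plausible substitutes are used otherwise: anesthesia
time clipped to [120, 700] min, crystalloid SD 0.5 on [1, 3] L, diuretic
mean 40 / SD 25 on the printed [20, 180] mg as a single
furosemide-equivalent scalar. Nineteen further preoperative columns
(demographics, history, drugs, EF) are generated at their published rates
as pass-through noise, giving feature selection the full 27-column table.

**Outcome link.** AKI+ membership is Bernoulli with logistic probability
σ(b + β·z), where z are the standardized eight features and β encodes a
clinically plausible direction (risk rises with Cr, BS, HbA1C, age, BMI,
CCB; falls with Alb, Hct). The intercept b is calibrated by root-finding
so the cohort's *expected* prevalence equals the target (52.71% by
default); an unreachable target raises `CalibrationError`.

**Plans.** Each parameter's mean is a linear function of the standardized
features (small coefficients, ‖β‖² ≈ 0.1–0.2 per parameter) plus a
group-conditional shift, with Gaussian noise at 0.6 of the marginal SD.
The shift (default 1 SD per continuous parameter, +0.30 event probability
per binary) is allocated **symmetrically about the marginal mean** — AKI−
down by `prevalence × δ`, AKI+ up by `(1 − prevalence) × δ` — so the
cohort-level marginals stay at their published values for any shift size
while the group separation is exactly δ. Binary parameters shift on the
probability scale (clipped to [0.02, 0.98]) with a small logit-scale
feature signal.

**Trajectories.** AKI− days draw a multiplier on [0.85, 1.45) capped so
the rise stays below 0.3 mg/dL — below every stage-1 trigger. AKI+
patients draw a qualifying day (day 1 with probability 0.6), a stage from
(0.60, 0.25, 0.15) over stages 1/2/3 (the stage mix is not published; this
mix reflects the usual predominance of stage-1 injury), and a creatinine
ratio uniform in that stage's band; the other day is quiet. Generated
labels therefore round-trip exactly through the staging module.

**What the generator does not emulate.** Inter-feature correlations beyond
the planted linear signal (real labs are correlated), time-varying
intraoperative dynamics, informative missingness (masking is independent
Bernoulli per cell), site effects, and any real relationship between
anesthesia choices and outcome beyond the planted shift. Passing
end-to-end tests therefore demonstrates that the pipeline recovers planted
structure of realistic magnitude — not clinical validity on real patients.

## Numerical conventions and edge cases

- All randomness flows from explicit seeds; the pipeline derives one
  sub-seed per stage from its root seed via `SeedSequence.spawn`, and
  re-running a config reproduces byte-identical artifacts.
- Degenerate SDs in any scaler are replaced by 1 so transforms stay
  invertible; scaler round-trips are exact to 1e-9.
- 3-decimal truncation is `floor(x·1000 + 1e-9)/1000`; the 1e-9 guard
  absorbs binary-representation error on exact thirds.
- Missingness injection never touches the creatinine trajectory or the
  group label; imputation (median/mode, learned on the training partition)
  runs before planner training and evaluation. Feature ranking handles
  missing cells natively via default-direction splits instead.
- Empty cohort CSVs are schema errors, not empty cohorts, to surface path
  mistakes; malformed cells are reported with row and column.
- The published eight-feature / six-parameter selections are hard-coded as
  the canonical default so the pipeline is well defined even when a
  re-ranking on other data disagrees.

## Problem sizes used in the shipped checks

The default cohort is the published size (n = 998, prevalence 0.5271,
85/15 split). The planted-signal selection check uses n = 3000 over 20
seeds; moment-calibration checks use n = 6000; the shift-recovery sweep
runs the full pipeline at shifts of 0.5/1/2/3 SD on n = 998. These sizes
make the stochastic checks stable at their stated tolerances while keeping
a full suite run around half a minute on one CPU.

## Known limitations

- The architecture, loss and optimizer of the original planners are not
  published; the defaults here are conventional choices whose adequacy is
  demonstrated only on fixtures (linear-map recovery to RMSE < 0.1,
  shift-signal propagation).
- The distance metric's scaling is likewise unpublished; z-scoring by
  pooled training plans is this package's choice, and all downstream
  invariances (unit rescaling, parameter permutation) are properties of
  that choice.
- Published headline accuracies (78.7% train / 80.6% test) belong to the
  original private cohort and cannot be recomputed here; the package
  reproduces their *arithmetic* exactly and demonstrates recovery of
  planted signal on synthetic cohorts instead.
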