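# Methods

## Problem setting

The package analyses a repeat cross-sectional cohort: every subject is
measured at two visits (ages 20 and 22) for 31 dietary fatty-acid intakes,
usage of 5 fat-spread types, a complete outcome panel (six seated blood
pressure readings per visit, serum lipids, fasting glucose and insulin),
and lifestyle/anthropometric covariates with realistic missingness.
Because fatty acids are strongly collinear across foods, exposure is
defined at the level of intake *patterns*: subjects are clustered on their
standardized intake profiles and pattern membership enters the outcome
models as a categorical exposure.

## Clustering model

**Exposure matrix.** Intakes are averaged over the two visits and each
column is z-scored.  Standardization is a deliberate choice (and can be
switched off): raw g/day scales differ by three orders of magnitude
between palmitic acid and the long-chain omega-3s, and an unscaled
Euclidean metric would be dominated by the bulk fats.  For the spread
matrix the default layout keeps the two visits as separate columns
(6 variables × 2 visits = 12), so a change of spread between ages 20 and
22 is itself part of the usage pattern; a visit-averaged 6-column layout
is available behind a switch.

**Network.** Exact K-NN search (K = 20, Euclidean; ties broken by subject
index for determinism), union symmetrization — at this K the union graph
is essentially connected, which is the standard choice in K-NN community
detection — and edge weights equal to the cosine similarity of the two
standardized intake vectors.  "Cosine similarity of the neighbours" is
genuinely ambiguous in this field; the implemented default is the most
literal reading (similarity of the two subjects' intake vectors,
restricted to K-NN pairs), and a shared-nearest-neighbour Jaccard
weighting is provided as a labelled alternative.  Weights ≤ 0 are dropped
(logged when it happens) because modularity optimization assumes
non-negative weights.

**Louvain.** Implemented from first principles with the weighted
Newman–Girvan modularity (resolution γ exposed, default 1).  Phase 1
sweeps nodes in a seeded shuffled order, moving each node to the
neighbouring community with the largest positive gain (incremental ΔQ
computation; ties to the smaller community id); phase 2 aggregates
communities into super-nodes with intra-community weight as self-loops —
an operation that preserves modularity exactly, which the tests check to
1e-12.  Because greedy sweeps can stall in local optima, the optimizer
runs `n_restarts = 5` independently seeded sweep orders and keeps the
best-Q partition; the whole procedure is deterministic given the seed.
Disconnected components simply remain separate communities and small
clusters are never merged post hoc.  An exhaustive enumeration over all
set partitions (`exhaustive_best_partition`) is included as an oracle for
graphs of ≤ 10 nodes; on random 8-node graphs the optimizer attains the
global maximum in ≥ 95/100 runs and never exceeds it.

Cluster ids are relabelled in decreasing size order for stable reporting;
interpretive names ("low-saturated/high n-3") are left to the user, who
gets per-cluster standardized and raw mean profiles with across-cluster
one-way tests instead.

## Outcome derivations

* Clinic BP: the first of the six seated readings is discarded (it runs
  systematically high) and readings 2–6 are averaged.  Hypertension is
  staged on that 5-reading mean: stage 2 if SBP ≥ 140 or DBP ≥ 90, stage 1
  if SBP ∈ [130, 140) or DBP ∈ [80, 90).
* Pulse pressure = mean SBP − mean DBP per visit (no standard definition
  beyond this).
* HOMA-IR = insulin (mU/L) × glucose (mmol/L) / 22.5.
* Non-HDL = total − HDL cholesterol.

## Association models

Gaussian GLMs on the stacked two-visit data (two rows per subject), with
the fatty-acid cluster and the spread cluster entered **together** as
categorical exposures, so each factor's coefficients are adjusted for the
other pattern dimension.  Reference levels are chosen from the profiles:
the no-spread cluster, and the fatty-acid cluster with the lowest
saturated-fat / highest omega-3 standardized intake.  Model 1 is
unadjusted; model 2 adjusts for age, waist–hip ratio, family history of
hypertension, healthy/Western diet scores, fruit and vegetable frequency,
alcohol, sodium, METs and physical-activity category.  Analyses are run
separately by sex (hard-wired stratification, not an interaction model).
Outcomes on the log scale (triglycerides, cholesterol fractions, HOMA-IR)
are natural-log transformed; coefficients are reported as geometric-mean
ratios and % change, `100·(exp(β) − 1)`.

**Variance estimation.** Reported coefficient covariances are the
subject-clustered sandwich
`V = c (X'X)⁻¹ (Σ_g X_g'û_g û_g'X_g) (X'X)⁻¹`, with the small-sample
factor `c = G/(G−1)·(N−1)/(N−p)` (statsmodels' cluster-robust OLS, checked
against a long-hand matrix oracle to 1e-8).  With one row per group this
collapses to the HC1 heteroskedasticity-robust form.

**Familywise gate.** Individual cluster contrasts are interpreted only if
the joint test that *all* of the factor's coefficients are zero passes at
α = 0.05.  A plain Wald chi-square reference is measurably
anti-conservative here — each non-reference level holds only a few dozen
subjects, so the covariance of the 7–9 tested coefficients is far noisier
than the total cluster count suggests (simulated type-I error ≈ 9% at
n = 400).  The gate therefore uses the bias-reduced CR2 cluster
adjustment and an approximate Hotelling T² reference whose effective
degrees of freedom come from matching the first two moments of the
covariance estimator to a Wishart distribution; for a single coefficient
this reduces to the Bell–McCaffrey/Satterthwaite df.  In the all-null
simulation of the acceptance suite the gate rejects at ≈ 5%.  On gate
failure the pairwise contrasts are still emitted, flagged non-inferential.

**Missing covariates.** Multiple imputation by chained equations,
m = 20 datasets, 10 cycles.  Covariates are recorded once per subject, so
imputation runs on a one-row-per-subject table; the always-complete
predictors entering every conditional model are the per-visit mean
systolic and diastolic pressures (which jointly encode subject and visit)
plus sex — a group-level representation of the subject indicator, since
one dummy per subject would be degenerate.  Categorical covariates
(family history, smoking, activity category) use predictive mean matching
with 5 donors, so imputed values stay inside the observed codes;
continuous covariates use Bayesian linear regression draws from the
posterior predictive.  Scalar estimates pool by Rubin's rules with
Barnard–Rubin degrees of freedom (complete-data df = the Satterthwaite
value above); the gate pools across imputations with the D1 statistic,
its denominator df capped at the complete-data Hotelling value.

## Synthetic cohort generator

The generator exists so that every stage has a ground truth.  What it
emulates, and the defaults:

* **Fatty-acid intakes** are log-normal: `intake = exp(b + 0.5·z)` with
  per-acid baselines `b` spanning trace (22:6n-3 ≈ 0.25 g/day) to bulk
  (18:1 ≈ 30 g/day) intakes.  The latent `z` has unit marginal variance
  with a 3-factor structure (30% shared variance) inducing the
  multicollinearity that motivates pattern analysis.  Each of the 8
  planted clusters shifts a signature subset of ~1/3 of the fatty acids by
  ±`separation`/2 SD (default separation 3), so any two clusters differ by
  at most `separation` SD per variable — dietary patterns move whole
  fatty-acid families, not isolated nutrients, and this is also the
  geometry under which K-NN + Louvain recovery is achievable at realistic
  n; a single 3-SD gap between 31-dimensional mean vectors would drown in
  within-cluster noise.  At separation 0 planted labels are unrecoverable
  (ARI ≈ 0), as required of a null case.
* **Spread usage** is zero-inflated: each of the 10 planted clusters uses
  a fixed subset of spread types (none / butter only / high margarine /
  margarine + blends / ...), with log-normal amounts around moderate
  (7 g/day) or high (22 g/day) medians and exact structural zeros
  elsewhere, mirroring real "no spread" response patterns.
* **Two visits** are generated jointly with within-subject correlation
  0.6 (typical FFQ repeatability), never as independent draws — the
  models cluster errors by subject, so the generator must produce that
  dependence.
* **Outcomes** are complete (the analysis population is defined that
  way): SBP = sex-specific baseline (male 122.2, female 111.7 mmHg,
  SD 11, an ≈ 10 mmHg male excess) + planted cluster effects + subject
  intercept + visit noise; six readings per visit with the first elevated
  by 4 mmHg so the drop-first rule is consequential.  Lipids, glucose and
  insulin are log-normal; HDL and non-HDL are generated separately and
  summed so total > HDL always holds.  The default planted effect table
  places male spread-cluster effects on SBP/DBP/triglycerides and female
  fatty-acid effects on HDL, with magnitudes of a few mmHg and 10–30%.
* **Missingness** is MAR given sex and mean SBP only — both always
  observed and both in the imputation model, so chained equations are
  correctly specified.  Default rates (8–19%) follow the questionnaire
  variables' typical gaps.  Intake and outcome data are never missing.

What the generator does **not** emulate: the FFQ instrument itself
(portion sizes, nutrient-composition tables), confounding between diet
patterns and covariates (covariates are independent of cluster membership,
so adjusted and unadjusted estimates coincide in expectation),
fatty-acid/spread cluster dependence (the two planted labelings are
independent, so the cross-tabulation test is null on synthetic data), and
MNAR mechanisms.  Passing tests therefore demonstrate algorithmic
correctness and statistical calibration under the stated model — not
robustness to instrument error or unmeasured confounding in real cohorts.

## Numerical choices and degenerate inputs

* K-NN ties and Louvain gain ties break to the smaller index/community id;
  all stochastic stages take explicit seeds, and the pipeline derives
  per-stage seeds from one global seed, so a full run is byte-reproducible.
* Louvain accepts a move only if the gain exceeds 1e-7 (configurable);
  modularity is recomputed from scratch at every level and the trace is
  exposed (`q_trace`), which the tests require to be non-decreasing.
* Zero-variance columns fail standardization loudly (no silent dropping);
  BP panels must have exactly six readings (no padding); a subject with
  one visit aborts matrix construction with the offending ids listed.
* Singular model designs raise with the collinear columns named; fewer
  clusters than parameters warns.
* PMM donor pools shrink to the observed-case count when fewer than 5
  donors exist; Bayesian regression draws fall back to the OLS point
  estimate if the posterior covariance is numerically non-PSD.

## Problem sizes used in the checks

The acceptance suite runs the benchmark cohort at n = 785–800 (the
recovery and determinism checks), the gate calibration at 500 null
cohorts of n = 400, and the imputation coverage study at 200 cohorts of
n = 300 with m = 20 imputations and 5 chained-equation cycles — sizes at
which each check's Monte-Carlo error is small relative to its acceptance
band while the whole suite stays inexpensive.

## Known limitations

* The Hotelling-type gate reference is an approximation; with very few
  clusters per factor level it turns conservative (simulated df estimates
  stabilize only with ≥ ~20 subjects per level).
* The chained-equation engine models every conditional with a linear
  predictor; ordinal covariates imputed by linear regression can take
  non-integer values (deliberately, matching the declared method mix).
* Louvain with restarts is still a greedy heuristic; global optimality is
  only guaranteed where the exhaustive oracle can run (≤ 10 nodes).
* The generator's independence of covariates and cluster membership means
  model-2 adjustment is exercised mechanically (does the machinery work)
  rather than substantively (does adjustment move estimates).
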