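# Methods

This note documents the models, rules and numerical choices implemented in
`lltproject`, the assumptions behind the synthetic-cohort generator, and
what the test suite does and does not establish about real data.

## Timeline construction

**Day convention.** Integer days relative to the index angiography; day 0
is the procedure date.  All windows are closed on both ends.

**Exposure windows.** A fill released on day `r` with `s` days supplied is
active on `[r + 14, r + s + 14]`.  The 14-day onset lag models dispensing
delay and the time to reach steady-state LDL-C; the same 14 days extend the
tail, so consecutive refills chain into a single interval without
artificial gaps.  Among overlapping statin fills the most recently released
defines the active statin (a new fill is treated as a switch; statins do
not stack), with input order breaking release-day ties.  Ezetimibe runs on
its own track and combines with whatever statin is concurrently active.

**Baseline LDL-C.** The qualifying lab is the one closest to day 0 within
365 days before (preferred) or 90 days after; "3 months after" is
implemented as the closed interval (0, 90], and a lab equidistant before
and after the index resolves to the pre-index lab.  If the active regimen
at the lab date differs from the regimen at day 0, the value is
back-calculated to the day-0 regimen and flagged `imputed`.  Patients with
no qualifying lab are excluded (a signal, not an exception).

**LDL-C transformation.** With fractional reductions from an untreated
baseline `r_from` and `r_to` (ezetimibe multiplying on as
`1 − (1 − r_statin)(1 − 0.15)`):

    untreated = value / (1 − r_from);   result = untreated · (1 − r_to).

This is algebraically exact under the proportional-reduction model, hence
the round-trip invariant `transform(transform(v, a→b), b→a) = v`.

**Effect table.** Only two entries are anchored by evidence this package
takes as given: atorvastatin 80 mg → 0.54, and ezetimibe → a further 0.15
multiplicative reduction.  Every other agent/dose entry (atorvastatin
40/20/10 → 0.49/0.43/0.37; rosuvastatin 40/20/10/5 → 0.55/0.52/0.46/0.41;
simvastatin 40/20/10 → 0.41/0.35/0.30; pravastatin 40/20 → 0.34/0.24) is an
implementer default consistent with published dose-response orderings, and
is plain configuration — override it when better estimates are available
for a target population.  Validation enforces reductions in [0, 0.9] and
monotonicity across intensity classes none < low < moderate < high.

**Trajectory.** A right-continuous step function starting at baseline.  New
points arise only at measurements (`measured`) and regimen-change days
(`imputed`, transformed from the most recent point); a measurement on a
change day wins.  Imputed values are superseded by the next measurement.

**Exclusions.** No qualifying baseline lab; any statin fill outside the
configured intensity map ("nonstandard"); any PCSK9-inhibitor fill;
dialysis; eGFR < 15 mL/min; age < 18; death within 30 days of the index.
Reasons are counted non-exclusively; the filter is idempotent.

## Counterfactual scenarios

Contraindication class maps deterministically to a tier: none → full dose
(atorvastatin 80), relative → reduced dose (atorvastatin 20), absolute → no
statin.  The clinical rule that produces the contraindication label is out
of scope: the class arrives as data (the simulator emits it with the
configured mix), keeping the unavailable clinical logic out of the
computational core.

Each observed point is transformed to the tier regimen (± ezetimibe) and
clipped at the observed value, independently per scenario:

    opt        = min(transform(v, obs → tier),      v)
    opt_ez     = min(transform(v, obs → tier + ez), v)

so optimization never raises LDL-C — relevant for patients observed on
regimens stronger than the tier (e.g. rosuvastatin 40) or already on
ezetimibe.  Whenever the clip is inactive the identity
`opt_ez = 0.85 · opt` holds exactly.  Projection commutes with
carry-forward, so projecting the step function pointwise is exact.

## Trajectory model

Per-patient LDL-C is averaged in 30-day bins, weighting each value by the
days it is active within the bin (exact integration of the step function);
the terminal bin may be partial.  Bins enter the mixed model unweighted —
the fitter has no residual-variance weights, and at 30-day resolution
partial-bin heteroscedasticity is negligible next to between-patient
variance; the day weights are still emitted alongside the averages.

The model is `LDL ~ 1 + ns(day, df) + (1 | patient)` with a natural cubic
spline (default 6 df).  The basis follows the R `splines::ns` convention
(cubic B-splines with second derivatives constrained to zero at the
boundary), built directly from scipy B-splines; interior knots sit at the
`1/(df−1) … (df−2)/(df−1)` quantiles of the interval midpoints and boundary
knots at day 0 and the horizon (1460).  An OLS fit on this basis reproduces
R's `ns` fit to ~1e-11 (kept as a live cross-check against `Rscript`).

**Fitting.** The random-intercept model is estimated by profiled maximum
likelihood: for a fixed variance ratio `λ = σ²_b / σ²_e`, GLS is OLS on
cluster-shrunken data `z − θ_g z̄_g` with `θ_g = 1 − (1 + n_g λ)^{−1/2}`,
leaving the one-dimensional profile deviance
`N log RSS(λ) + Σ_g log(1 + n_g λ)` to minimize.  All quantities reduce to
per-cluster sums and cross-products, additive over clusters, so a
cluster-bootstrap refit only reweights clusters by multiplicity and costs
milliseconds at any cohort size.  The fitter agrees with
`statsmodels.MixedLM(reml=False)` to ~1e-11 in the fixed effects (a test
asserts this); `λ = 0` (plain OLS) is always evaluated as a candidate, so a
singular random-intercept fit degrades gracefully, with pseudo-inverse
fallback for singular normal equations.

**Bootstrap.** The unit is the patient (all of a patient's intervals move
together) — the only resampling unit consistent with the random intercept.
A patient drawn twice contributes two independent clusters.  Resample `k`
derives from seed stream `(seed, 3, k)`, so the first resamples are
identical regardless of the total count, and the same resamples drive every
scenario, making scenario contrasts within-sample pairings.  Point
estimates are bootstrap means; intervals are 2.5/97.5 percentiles.
Default 1000 bootstraps; the test suite and examples use 10–200, which
widens Monte-Carlo noise on the CI endpoints but changes nothing
structurally.

## Outcome projection

**Observed incidence.** Death: complement of the Kaplan–Meier survivor
function.  Nonfatal outcomes: Aalen–Johansen cause-specific cumulative
incidence with death competing; censored subjects at a tied time remain in
the risk set for events at that time (the standard convention).
Revascularizations in the first 30 days do not count (the patient remains
at risk); all patients have ≥ 30 days of potential follow-up by the
early-death exclusion, and follow-up ends at min(death, 4 years,
administrative censoring).  The estimator is a compact numpy routine
because the bootstrap and coverage loops evaluate it tens of thousands of
times; tests pin it against lifelines and an independent brute-force
implementation on hundreds of random datasets, including heavy ties.

**Rate-ratio sampling.**  For an association RR (95% CI `l`–`u`) per
38.67 mg/dL of LDL-C reduction, draws are lognormal with
`meanlog = ln RR`, `sdlog = (ln u − ln l) / (2 · 1.959964)`.  By default
one draw per outcome per bootstrap, held across time points (the
`per_timepoint` mode redraws at every grid point; both are available
because either reading of the indexing is defensible, and with a CI this
narrow they are numerically close).  The per-outcome association table is
required configuration; shipped defaults (death 0.90 [0.87–0.93], MI 0.74
[0.70–0.79], stroke 0.85 [0.80–0.89], revascularization 0.76 [0.73–0.79])
are implementer-supplied values in the style of the Cholesterol Treatment
Trialists' meta-analyses and should be replaced deliberately, not trusted
silently.

**Projection.**  `I_proj = I_obs · RR^(Δ/38.67)`, clamped to [0, 1].  The
formula acts multiplicatively on the cumulative incidence — the standard
rate-ratio extrapolation; for the event probabilities involved here
(≤ ~20%) the distinction from a hazard-scale transformation is well inside
the bootstrap noise.  Δ at time point `j` is the resample's mean
observed-minus-scenario LDL-C among patients still under observation at
`j`, taken from the step-function trajectories directly (cohort-level Δ;
a per-patient mode is deliberately not the default, matching the
cohort-curve framing of the trajectory model).  ARR = `I_obs − I_proj`
per bootstrap, summarized by mean and percentiles.

**NNT.** Ceiling of 1/ARR; CI bounds are ceilings of the reciprocal CI
bounds of the ARR (upper ARR → lower NNT).  Non-positive ARR yields an NA
marker, mirroring how sparse early strokes behave.  The ceiling convention
satisfies `nnt(x)·x ≥ 1 > (nnt(x)−1)·x`.

## Synthetic cohort generator

The generator is the package's test bed and demonstration data source; its
defaults are the study conditions the analysis targets:

| knob | default | note |
| --- | --- | --- |
| ACS prevalence | 26.8% | share presenting acutely |
| eligibility mix | 83.89 / 15.34 / 0.77% | full / reduced / no statin tier |
| baseline statin coverage | 59.7% (34.9% high-intensity) | at index |
| baseline ezetimibe | 0.6% | |
| untreated LDL-C | N(113, 40), truncated ≥ 30 | gives observed baseline mean ≈ 80 mg/dL under the regimen mix |
| lab noise | N(0, 8) mg/dL, floor 1 | assay + biological variation |
| first post-index lab | Exponential(mean 194.8 d) | median 135 days; then ~180-day cadence with jitter |
| pre-index lab coverage | 93% | the rest risk baseline exclusion |
| intensification | 28% of non-high patients at U(14, 180) d | lifts high-intensity use toward ~53% by 6 months |
| baseline hazards | death .055, MI .014, stroke .006, revasc .045 /p-y | at reference LDL-C 79.7 mg/dL |
| rate ratios per mmol/L | .90 / .74 / .85 / .76 | same values the projection defaults assume |
| administrative censoring | 1460 days for everyone | no staggered entry |

Event model: per outcome, a piecewise-constant hazard
`h_i(t) = h0_i · RR_i^((ref − LDL(t)) / 38.67)` over the patient's regimen
phases, sampled by inversion of the piecewise-linear cumulative hazard.
Death is terminal; nonfatal events do not censor death.  Because the
generator and the projection share the rate-ratio law, projection parameter
recovery is an exact test of the pipeline, not a plausibility argument.

Each patient has at most two regimen phases (baseline, then an optional
switch), realized as pharmacy-fill chains that the timeline module's window
rule resolves back into exactly those phases — so with zero lab noise the
pipeline's imputed trajectory reproduces the generating truth to the 0.1
mg/dL recording resolution of the lab table.  Patient-level latent draws
(untreated LDL-C, flags, event exponentials) come from a substream whose
consumption depends only on `n_patients`; cohorts simulated under the
`observed` and `opt_statin`/`opt_statin_ez` policies from one seed are
therefore coupled twins of the same patients, enabling direct simulation of
the counterfactual with strong variance reduction.

**What the generator does not emulate:** comorbidity correlation
structure, facility effects, adherence gaps (fills are taken as
prescribed), staggered study entry (every patient gets the full 4-year
window, so follow-up is longer than in a staggered-enrollment registry),
inter-individual variability in response to therapy (reductions are the
table's means), and any confounding between treatment choice and hazard
beyond what LDL-C itself carries.  Passing tests therefore establish the
*internal* correctness of the pipeline — windows, imputation, estimators,
bootstrap, projection algebra, and recovery of known generating parameters
— not that the rate-ratio extrapolation holds in any particular real
population, nor the magnitude of real-world confounding by indication.

## Problem sizes in tests and scripts

The default test run simulates cohorts of 200–50 000 patients: hand-oracle
and property tests run on tiny inputs; marginal and hazard-law checks use
20 000–50 000; the counterfactual-twin comparison uses 50 000 with
common-random-number pairing (Monte-Carlo SE ≈ 0.2 pp on the 4-year death
CIF); CI coverage uses 100 replicates of 5 000 patients with 100
bootstraps.  `scripts/acceptance.py` uses 20 000 patients and 200
bootstraps for the pipeline quantities and 30 000 for parameter recovery.
These sizes were chosen so Monte-Carlo error is small relative to the
tolerances being asserted while a full run stays in the minutes range on a
single CPU.

## Known limitations

* The proportional-reduction LDL-C model ignores inter-individual response
  variability; imputation error is therefore systematic per patient, not
  random.
* Cohort-level Δ in the projection formula ignores within-cohort
  covariance between LDL-C reduction and baseline risk; the twin-recovery
  test bounds the resulting bias under the generator's assumptions only.
* The percentile bootstrap CI for NNT inherits the ARR's skew; for ARRs
  near zero the NNT interval is reported as NA-bounded rather than
  negative.
* `apply_exclusions` checks baseline-lab availability by window presence
  only; a lab could exist in-window yet be unusable for other reasons in
  messier real data.
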