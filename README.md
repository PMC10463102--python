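# lltproject

Counterfactual projection of cardiovascular outcomes under optimized
lipid-lowering therapy (LLT), for observational cohorts built from routine
pharmacy-fill and laboratory data.

Secondary-prevention patients — for example a cohort with coronary artery
disease documented at an index angiography — are often undertreated: many
receive no statin or a submaximal dose, and ezetimibe use is rare.  This
package quantifies the unrealized benefit: given each patient's observed
LDL-C trajectory, it projects what LDL-C *would have been* under an
optimized statin regimen (with or without ezetimibe) and converts the
cohort-level LDL-C difference into projected reductions in the cumulative
incidence of death, myocardial infarction, stroke and coronary
revascularization, with numbers needed to treat.  It is a library for
epidemiologists and outcomes researchers, with a thin `lltproject` CLI over
the same pipeline.

## Method

1. **Exposure windows.** A prescription is active from the 14th day after
   its release through the days supplied plus 14; overlapping fills of
   different statins resolve to the most recently released (a switch, not a
   stack).

2. **Observed LDL-C trajectory.** Baseline LDL-C is the lab closest to the
   index date within 12 months before (preferred) or 3 months after.
   Values carry forward until a new measurement or a regimen change; at a
   regimen change the value is re-expressed via the expected-reduction
   table: with fractional reductions `r` from an untreated baseline,

       LDL_new = LDL_old · (1 − r_new) / (1 − r_old),

   where ezetimibe multiplies on as `(1 − r_statin)(1 − 0.15)`.
   Atorvastatin 80 mg is anchored at `r = 0.54`.

3. **Counterfactual scenarios.** Each patient's contraindication class maps
   to a tier (none → atorvastatin 80, relative → atorvastatin 20,
   absolute → no statin); ezetimibe is an appropriate addition in every
   tier.  Observed values are transformed to the tier regimen and clipped
   so optimization never raises LDL-C.

4. **Cohort curves.** Per-patient 30-day weighted interval averages enter a
   linear mixed model, `LDL ~ ns(day, 6 df) + (1 | patient)`, refit across
   cluster-bootstrap resamples (default 1000); curves and scenario
   contrasts are summarized by the bootstrap mean and 2.5/97.5 percentiles.

5. **Outcome projection.** Observed cumulative incidence uses Kaplan–Meier
   (death) or Aalen–Johansen with death competing (nonfatal outcomes) on a
   6-month grid.  Within each bootstrap, a rate ratio per 38.67 mg/dL
   (1 mmol/L) LDL-C reduction is drawn per outcome from a lognormal
   parameterized by its meta-analytic point estimate and 95% CI, and

       I_proj(i, j, k) = I_obs(i, j, k) · RR_{i,k}^{ΔLDL_{j,k} / 38.67}.

   Absolute risk reduction is `I_obs − I_proj`; NNT is the ceiling of its
   reciprocal.

A synthetic-cohort generator (`lltproject.simulate`) produces
patients/fills/labs/events tables with this exact structure and a ground
truth table — event hazards follow the same rate-ratio law — so the whole
pipeline is testable end to end, including direct simulation of the
counterfactual twin cohort.

## Worked example

```bash
python examples/project_outcomes.py
```

simulates 4000 patients, runs the pipeline with 100 bootstraps and prints
(abridged):

```
projected mean LDL-C reductions vs observed therapy (mg/dL):
  1y: optimized statin  21.0;  + ezetimibe adds  7.2  (total  28.1, ratio 34.2%)
  3y: optimized statin  21.7;  + ezetimibe adds  7.2  (total  28.9, ratio 33.3%)

4-year death incidence:
  observed: 18.48%
  optimized statin : projected 17.46%, ARR 1.03% (95% CI 0.74-1.31)
  + ezetimibe      : projected 17.12%, ARR 1.37% (95% CI 0.99-1.71)

NNT to prevent one event (95% CI):
     scenario  years         death            mi           stroke revascularization
   opt_statin      4   97 (77-136) 140 (107-176)    465 (332-672)        51 (43-61)
opt_statin_ez      4   73 (59-102)  108 (83-135)    353 (252-503)        39 (33-46)
```

Optimizing statin therapy alone lowers cohort mean LDL-C by ~21 mg/dL at
1 year; adding ezetimibe contributes a further ~7 mg/dL (about a third as
much again).  Under the rate-ratio extrapolation that corresponds to ~1 in
97 deaths within 4 years averted by statin optimization alone, ~1 in 73
with ezetimibe added.  `examples/simulate_cohort.py` and
`examples/ldl_trajectory.py` walk through the generator and the timeline
rules on their own.

The same pipeline runs from the shell on CSV inputs:

```bash
lltproject simulate --n 5000 --seed 7 --out data/
lltproject run-all --data data/ --out results/ --seed 7 --bootstraps 1000
```

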