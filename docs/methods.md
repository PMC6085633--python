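# Methods

`batcea` implements a decision-analytic cost-utility model comparing
baroreflex activation therapy (BAT, an implantable carotid-baroreceptor
stimulator) with optimized medical management (OMT) in adults with chronic
heart failure, NYHA class III, LVEF ≤ 35%, not eligible for cardiac
resynchronization therapy. Perspective is a statutory health insurer
(2013 EUR), horizon is lifetime, outcomes are discounted costs, life-years
(LY) and quality-adjusted life-years (QALYs), and the headline statistic is
the incremental cost-effectiveness ratio ICER = ΔCost/ΔQALY.

## Model structure

**Decision tree (month 0).** The first 30 days after treatment assignment.
The BAT arm pays the device system (€21,000), implant procedure (€3,628)
and physician visits (€68), faces a 30-day adverse-event probability of
0.070 costing €3,056 in expectation, and loses a procedural-death fraction
(default 0; the branch exists but no probability is published). Both arms
face one month of background plus NYHA-III excess mortality — the
treatment-effect relative risks start with the Markov phase. Both arms
also accrue one month of routine-management and expected hospitalization
cost during the tree month: patients are under NYHA-III-level care in both
arms from day 0, and the symmetric accrual preserves exact arm equivalence
under a null effect.

**Markov model (months 1, 2, …).** Five states: NYHA I–IV and death;
cycle length one month; state changes once per cycle. Per cycle and state:

1. *Mortality.* Background mortality (sex-specific annual `qx` converted
   to a monthly rate) and NYHA excess mortality (six-month probabilities
   0.04 / 0.07 / 0.28 for classes II–IV, none for class I, converted to
   monthly rates) combine additively on the rate scale. Under BAT the
   mortality relative risk (0.61) multiplies the **total** rate, matching
   its derivation for all-cause death; `rr_on_total_rate=False` restricts
   it to the excess rate for sensitivity exploration (see "Known
   limitations" for why this distinction matters).
2. *NYHA transitions.* Survivors redistribute by the first-cycle matrix at
   month 1 and the subsequent-cycle matrix thereafter (both recovered by
   calibration, below).
3. *Hospitalization.* Expected HF admissions = occupancy × monthly
   probability (0.015 / 0.024 / 0.024 / 0.154 by class; × RR 0.40 under
   BAT), costed at the case-mix mean €5,645.9. The printed case-mix shares
   sum to 98.2%; they are used as printed, not renormalized, because the
   published expected cost arises from the raw shares.
4. *Accruals.* Routine management cost (€516/910/900/967 per year by
   class, divided by 12), LY = occupancy/12, QALY = LY × class utility.
   Accruals use end-of-cycle occupancy; a half-cycle-correction flag
   exists and defaults off (the source analysis is silent on it).
5. *Battery replacement.* At months 72, 144, … (battery life 6 years) the
   surviving BAT fraction pays battery (€15,000) plus replacement
   procedure (€1,808). No replacement is scheduled beyond the horizon.
6. *Discounting.* Costs and outcomes beyond the first year are discounted
   at 3.0%/year: factor 1 for months ≤ 12, `1.03^(−(m−12)/12)` after.

Periods are converted with the constant-rate rule
`p' = 1 − (1 − p)^(to/from)`, the standard actuarial assumption.

The production engine propagates cohort expectations, vectorized over
draws (`engine.run_batch`); male and female sub-cohorts are propagated
separately with their own life tables and mixed by the male share, so
differential survival by sex is respected. An individual-level
micro-simulation exists only as a test oracle and the suite requires the
cohort engine to match it within 3 Monte Carlo standard errors on a
24-month horizon.

## Background mortality

National sex-specific life tables are emulated by a Gompertz–Makeham
model, `qx(age) = 1 − exp(−(a + (b/c)·e^{c·age}·(e^c − 1)))`, closed at
age 110. Defaults (per sex) are fitted to early-2010s German longevity:
life expectancy at birth ≈ 78.1 y (male) / 83.1 y (female) and plausible
`qx` at ages 65 and 80. `LifeTable.from_csv` accepts a real table
(columns `age,qx`) when cell-level fidelity matters; no claim is made to
reproduce any specific national table cell-for-cell.

## Calibration

Two inputs of the original analysis are cited but never printed: the
monthly NYHA transition matrices (first cycle and onward) and the
per-class EQ-5D utilities. They are recovered from two printed anchors:

* OMT all-cause mortality at month 30 = 0.31 at the external-validation
  profile (age 66 ± 6.6, 73% male), and
* OMT cohort-average utility = 0.671 at the base-case profile (the ratio
  of the published discounted QALYs to life-years, 3.67/5.47).

A 4×4 matrix is far under-determined by two scalars, so the matrix family
is sparse: one class up with probability `p_up`, one class down with
`p_down` times a class multiplier (defaults 1), no two-class jumps,
remainder on the diagonal. The improvement probability is front-loaded:
the first cycle carries `p_up_first` in full; subsequent cycles carry a
fixed fraction of it (default 0). This shape reflects how response to
optimized therapy appears early while chronic heart failure then
progresses, and it makes the calibration well identified: across
anchor-consistent `(p_up_first, p_down)` pairs the implied OMT lifetime
discounted LY varies only between ≈5.1 and 5.6 — close to the published
5.47 even though that value is deliberately **not** an anchor (it serves
as an out-of-sample check). Structures with sustained month-on-month net
improvement also satisfy the anchors but imply 6.7–7.9 discounted LY,
which is clinically implausible for progressive NYHA-III disease and was
rejected on that ground.

Utilities are parameterized as `u3` plus fixed spreads
(`u1 = u3 + 0.225`, `u2 = u3 + 0.13`, `u4 = u3 − 0.08`, the shape of
published EQ-5D-by-NYHA sets); given a matrix, the average-utility anchor
is linear in `u3` and solved exactly. `(p_up_first, p_down)` are fitted to
the mortality anchor by Nelder–Mead from multiple seeded starts with a
weak quadratic pull toward the start point `(0.40, 0.004)` to pin the
residual free direction; tolerance 1e-4 on the weighted squared relative
anchor error, failure raises with a per-anchor report rather than
accepting a bad fit. Calibrated defaults land at `p_up_first ≈ 0.40`,
`p_down ≈ 0.004`, `u3 ≈ 0.62`.

## Probabilistic analyses

**Base case** (the headline results): 5000 Monte Carlo draws sampling only
demographics — age ~ Normal(63, 6.6) (the only SD printed anywhere,
documented as an assumption for this profile; clipped to 30–95) and male
share ~ Beta with mean 0.832 and effective sample size 146 (the trial
size; no parameters are printed) — with all model parameters at point
estimates. Both arms share each draw. Means and 2.5/97.5 percentiles are
reported; the headline ICER is mean ΔCost over mean ΔQALY.

**Full PSA**: 5000 draws sampling every distributed parameter:

* probabilities ~ Beta with the printed coefficients;
* utilities ~ Beta with mean at the calibrated value and effective sample
  size 100 (assumption; none printed), re-drawn per draw until the class
  ordering holds (retry-capped, count logged);
* costs ~ Gamma(shape 1, mean = point value). The cost table prints Gamma
  coefficients only for the routine-management rows, but the sensitivity-
  analysis methods state flatly that Gamma was used for cost data, and in
  every printed row the rate parameter equals the point estimate; all
  nonzero costs are therefore sampled this way (zero costs stay zero);
* relative risks ~ log-normal (SE_log 0.0467 and 0.18);
* transition rows ~ Dirichlet with concentration 100 × row (pseudo-count
  assumption; structural zeros stay zero);
* demographics sampled as in the base case (a flag freezes them).

Parameter correlation is not modeled, matching the source analysis's own
stated limitation. Per draw both arms see the identical sampled set
(common random numbers; asserted via an input digest). The CEAC reports,
per willingness-to-pay value, the fraction of draws with positive
incremental net monetary benefit `wtp·ΔQALY − ΔCost`.

**One-way sensitivity analysis** varies each parameter with a declared
range to its bounds with everything else at base case, using deterministic
point demographics so the tornado is noise-free. Ranges are the printed
ones; battery life 3–6 years; utilities ±20% jointly; age 50–75 (the
published tornado's age range is not printed; this default is a documented
assumption).

## Treatment-effect derivation

The mortality RR is reproduced methodologically: an integer risk score
(thirteen covariates: age, LVEF, NYHA class, creatinine, diabetes,
beta-blocker, systolic pressure, BMI, time since diagnosis, smoking, COPD,
sex, ACEi/ARB) maps each patient to a predicted 1-year death probability
through a monotone link, and RR = mean predicted risk (device) / mean
predicted risk (control). The real published point table is not embedded —
`RiskScoreModel` is a schema-documented YAML interface, and the packaged
`synthetic_risk_score.yaml` is a clearly labelled synthetic stand-in with
the same shape. Synthetic cohorts mirror the trial profile (age 63 ± 11,
83% male, predominantly NYHA III, LVEF ≤ 35; 52/30 arm split at n = 82);
three covariates unavailable in the trial are randomly assigned at
configurable prevalences, mirroring the original procedure. A known
effect is encoded by shifting device-arm covariates along an
improvement direction until the score-implied risk ratio on an
*independent* reference cohort equals the target, so parameter-recovery
tests (encoded 0.61 recovered ± 0.05 at 2000/arm) are genuine.
Ratio-of-means is the default (mean-of-ratios available by flag); the
derived `RelativeRisk` plugs directly into `ModelParameters.rr_mortality`.

## What the synthetic data do and do not show

The life tables, cohorts and the packaged risk score are parametric
stand-ins: they reproduce marginal plausibility (longevity targets,
trial-like covariate profiles, monotone risk), not joint distributions,
covariate correlations, or any real population's values. Passing tests
demonstrate the *methods* are implemented correctly (conservation,
pairing, recovery, oracle agreement) and that the calibrated model is
observationally equivalent to the published one on its anchors — not that
absolute survival or costs match any real registry.

## Numerical choices

Probabilities are converted through rates with `log1p`/`expm1` for
stability; ages beyond the table force death; transition rows must be
stochastic within 1e-9; occupancy is conserved within 1e-9 per cycle;
dominance and zero-ΔQALY cases are flagged instead of returning a ratio;
all Monte Carlo runs are reproducible from a single seed (the CLI and the
acceptance script derive fixed per-stage substreams from it). Problem
sizes: 5000 draws in the acceptance script and CLI defaults; 2000 draws in
the quantitative test layer and 100,000–200,000 walkers in the oracle
comparison, sizes at which Monte Carlo error is far below the assertion
bands.

## Known limitations

* The recovered transition matrix and utilities are observationally
  equivalent on two anchors, not the unpublished originals; published
  outcome reproduction is therefore expected only to ~10–15%.
* Whether the original model multiplied the mortality RR into the total
  death rate or only the HF excess rate is not identifiable from its
  printed numbers: the total-rate default reproduces the ICER and Table-3
  quantities closely but yields a CEAC at €35,000/QALY of ~74% (published:
  59%), while the excess-only flag reproduces the CEAC (~60%) but misses
  the ICER by ~+18%. The default follows the all-cause derivation of the
  RR; the flag exposes the alternative.
* Age ranks lower in our tornado than in the published one: with
  background mortality dominated by HF excess risk at this profile, age
  moves costs and QALYs together and the ICER only mildly. Battery life
  and the mortality RR rank on top, as published.
* The year of the emulated life table, the Dirichlet concentration, the
  utility effective sample size, the PSA demographic sampling and the age
  sensitivity range are documented assumptions where the source prints
  nothing.
* No treatment switching, no CRT comparator, no EVPI, no inflation
  adjustment (all defaults are the printed 2013-EUR values).
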