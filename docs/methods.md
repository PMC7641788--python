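# Methods

This note records the statistical model behind each stage, the defaults
and why they were chosen, and what the synthetic cohorts do and do not
establish about real diary data.

## Data model

A diary table has one row per consumed food item with participant,
phase (T1 = training, T2 = held-out), day index, and per-portion values
for eight nutrients under two databases.  Reference values are complete;
app values may be missing, reflecting app database rows that carry only
partial nutrient information.  **Missing app values contribute 0 to daily
sums** — that is how incomplete rows enter real app totals — but are kept
distinct from 0 in storage so the generator's audit and the cleaner can
reason about them.  Mean daily intake divides each participant's phase
total by the number of *distinct* observed days, so diaries with fewer or
non-consecutive days aggregate correctly.

## Synthetic cohort generator

The generator is the package's test bed: it produces cohorts with the
statistical structure the analysis assumes, with every planted anomaly
auditable.

**Truth process.** Each participant has a latent habitual daily-intake
vector drawn from a multivariate log-normal, moment-matched per nutrient
to the configured daily targets — defaults: energy 1958 (SD 543)
kcal/day, carbohydrate 225 (61), fat 81 (27), protein 78 (26), fiber
19 (8), sugar 85 (35) g/day, cholesterol 242 (131), sodium 2638 (848)
mg/day, values typical of a European adult validation cohort.  The SD is
interpreted as *between-participant* spread of habitual intake.  On the
log scale, energy correlates 0.5 with each other nutrient and non-energy
pairs at 0.25, giving the correlated nutrient structure real diaries
show.  Realized daily totals multiply in mean-one log-normal day-to-day
variation (log-SD 0.15, a modest within-person component), and are split
across the day's 12–16 items by a symmetric Dirichlet(α = 2) weight
vector shared across nutrients — daily totals are preserved exactly and
item sizes vary without modelling actual foods.

**App error channel**, applied per item in order:

1. multiplicative bias per nutrient (defaults 1.01 energy … 0.45
   cholesterol), modelling systematic under-reporting;
2. mean-one multiplicative log-normal noise with a **participant-level**
   component (log-SD 0.08–0.9; systematic per-person error that does not
   average out over items) and an **item-level** component (log-SD
   0.2–0.8).  Both are centered at −σ²/2 on the log scale so the bias
   factors control the app means exactly;
3. missingness per nutrient (default 0.5 for cholesterol and sodium,
   0.02 otherwise), reproducing the severe micronutrient incompleteness
   of app databases (app sodium means land near half the reference);
4. gross entry errors: with probability 0.03 per item, one uniformly
   chosen non-missing nutrient is multiplied by ×10 or ×100 (unit or
   decimal mistakes).

The split between participant- and item-level noise was derived once from
the variance algebra of 4-day means (item noise shrinks by √(items);
participant noise does not) so that the participant-level app–reference
correlations land near the pattern reported for consumer-app databases:
energy ≈ 0.95, macronutrients ≈ 0.9, fiber/sugar ≈ 0.8,
cholesterol/sodium ≈ 0.5.  Contamination at 3% of items yields cleaning
fractions near the few-percent rejection rates such studies report.

Randomness is split across independent child streams (structure, noise,
missingness, contamination), so identical seeds give bit-identical
cohorts and raising the contamination rate contaminates a superset of
items.  The audit log lists every planted missing value and gross error
with the pre-anomaly channel value.

**What the generator does not emulate:** real food items and portion
semantics, recipe composition, reactivity of self-reporting, day-of-week
or seasonal structure, and correlated missingness within food groups.
Tests passing on these cohorts show the *algorithms* are correct under
the stated error model, not that any particular app database behaves this
way.

## Limit learning

For one nutrient, candidates L sweep an ascending grid; app values
strictly above L are excluded (contribute 0), participant daily means are
recomputed, and the app–reference correlation across participants is
recorded.  The learned limit is the correlation-maximizing candidate;
**ties break to the largest tied candidate**, which removes the fewest
values (no false positives when the data are already clean).  The default
grid runs from the 50th percentile of observed app per-portion values to
the observed maximum in 200 even steps, so "remove nothing" is always a
candidate and the trained-phase correlation can never fall below the
uncleaned correlation.  Correlation is evaluated on participant-level
mean daily intakes (the level at which validation tables are reported),
with Pearson for energy/macronutrients/sugar/fiber and Spearman for the
heavy-tailed cholesterol/sodium.

Applying a limit set converts app values strictly above their limit to
missing, leaving the item and its other nutrients intact; the operation
is idempotent, and removal counts are monotone in the limit.

Known limitation: because ties break upward, the trained limit sits just
below the smallest *training-phase* error.  Held-out errors smaller than
that (possible, since gross errors scale item values of varying size) can
survive cleaning; on cohorts whose gross errors are well separated from
clean values the cleaner is exact (sensitivity 1, zero false positives),
which the test suite verifies against the audit log.

## Agreement statistics

The normality gate applies Shapiro–Wilk at α = .05 to both margins *and*
their differences: the parametric pair (paired *t*, Pearson) is used only
if all three pass, otherwise the rank pair (Wilcoxon signed-rank,
Spearman).  Testing margins and differences together is stricter than
either alone; it is this package's documented composite rule.  A
zero-variance sample is routed to the rank branch, and all-zero
differences report p = 1 by convention.

Bland–Altman analysis uses differences d = app − ref (so under-reporting
is negative): limits of agreement at mean ± 1.96 SD, fixed bias when the
95% one-sample *t* interval of the mean difference excludes 0, and
proportional bias when the OLS slope of d on the pair mean (x + y)/2 is
significant at α = .05 — the standard regression-on-mean check.  The
proportional-bias test is skipped (with a warning) when pair means have
zero variance.

## Attenuation power analysis

Under joint normality, corr(M, O) = ρ·r where ρ = corr(N, O) and
r = corr(N, M): measurement error attenuates the detectable association.
Analytic power of the two-sided zero-correlation test uses the Fisher-z
approximation (above); the empirical mode simulates outcomes
O = ρ·standardize(N) + √(1−ρ²)·ε over a ρ grid and counts rejections of
the correlation t-test t = r√((n−2)/(1−r²)), sharing the simulated
outcomes between the N–O and M–O tests (common random numbers).  A second
Monte Carlo route (`empirical_power_joint`) draws fresh bivariate-normal
(N, M, O) per replicate and is exactly unbiased for the true power — the
test suite uses it to bound the Fisher-z approximation.

The ρ grid is 0.005–0.5 in steps of 0.005 (100 points); ρ = 0 is excluded
because power there equals the test size.  The default 100 replicates
keep the classical small-simulation design; tests and cross-checks use
2000.  Power loss at the intended power (default 0.80) interpolates the
grid linearly for ρ* (root-finding tolerance 1e-6 where used) and reports
100·(0.80 − power_M(ρ*)) in percentage points; headline losses are quoted
at n = 50 unless overridden.  Sample-size inflation solves
power(ρ*, n) = 0.80 by Brent's method, attenuates ρ* by r, and scans for
the smallest integer n′ restoring the target, reporting 100·(n′ − n)/n.
As n → ∞ this converges to 100·(1/r² − 1)%, the classical variance
penalty of an unreliable regressor.

## Pipeline

`run_validation` trains limits on T1 only and cleans T2 only (training on
the phase being cleaned requires an explicit override), writes limits,
traces, cleaning report, original + cleaned agreement tables,
Bland–Altman plot data, power curves and the inflation table, and logs
every learned limit and removal count.  No output contains timestamps, so
identical configurations reproduce byte-identical bundles.  Nutrients
whose cleaned correlation is not in (0, 1] are skipped in the power stage
with a logged warning.

## Problem sizes

Default cohorts are 50 participants × 2 phases × 4 days × ~14 items
(~5600 items); the test suite mostly uses 10–15-participant, 2-day
cohorts, which exercise every code path at a fraction of the cost.
Monte Carlo checks use 1500–4000 replicates, where the binomial SE is
small enough to separate implementation error from simulation noise.
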