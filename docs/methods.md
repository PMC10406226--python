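# Methods

## The dynamical model

Nightly alcohol consumption `A_n` and desire to drink `D_n` are coupled
linear delayed difference equations:

    D_n = d1·A_{n-1} + d2·D_{n-1} + d3·(A_{n-1} − A_{n-2})
    A_n = a1·(D_n − D_{n-1}) + a2·A_{n-1} + a3·(A_{n-1} − A_{n-2})

All six coefficients are per-unit responses: `a1` drinks per unit same-day
desire change; `a2` drinks per drink last night; `a3` drinks per unit
two-night drinking trend; `d1`, `d2`, `d3` the desire analogues. `a1`,
`a2`, `d1`, `d2` are nonnegative; the trend coefficients `a3`, `d3` may take
either sign — a rising streak can carry drinking along or trigger
compensatory restraint. Linearity is an empirical choice: pooled binned lag
plots of diary data are close to straight lines over the observed range.

**Update order.** The drinking equation references the same-day desire value,
so each evening desire is computed first and drinking second. This is the
only order that makes the system explicit; `model.step` and every consumer
of it honor the contract, and a property test checks it against a two-line
oracle on randomized inputs.

**Initial conditions.** The two-night delay in `A` and one-night delay in
`D` require `A_0`, `A_1`, `D_1`. `A_0` is the pre-study baseline (a 30-day
Timeline Followback average); `A_1` and `D_1` are the first diary values.
Day 1 of a trajectory is therefore data, not dynamics, and behavior
classification ignores it.

**Equilibria.** The origin (abstinence, no desire) always exists. When
`d2 = 1` a line of abstinent states with constant positive desire appears;
when `a2 = 1` and `d2 ≠ 1` a line of sustained-moderation states
`(A*, d1·A*/(1−d2))` appears, the achieved `A*` depending on initial
conditions. Equality is tested to a configurable tolerance (default 1e-9);
the printed conditions are exact. Long-run behavior is classified from the
simulated path (sign changes of successive differences of `A`, envelope
trend) with the spectral radius of the 3×3 companion matrix of
`(A_n, A_{n-1}, D_n)` reported as a linear-theory cross-check. The
oscillation threshold (≥ 2 sign changes) is this package's convention.

**Non-negativity clipping** is off by default — calibration targets the raw
linear model, matching the Gaussian likelihood — and on inside sensitivity
sweeps, whose wide parameter ranges would otherwise produce biologically
meaningless negative drinking.

## Preprocessing

Desire is a 0–12 composite of three 0–4 Likert items with the first
("I really don't feel like drinking") reverse-coded; a missing item makes
the composite missing. Drink counts are winsorized at an integer cap,
`round(mean + 2·sd)` of the pooled sample with the sample (n−1) standard
deviation; the packaged default cap is 17. Only the upper tail is capped.
Patients enter the analysis when at least 30% of the 84 diary days are
complete (both outcomes reported; the denominator is the full window, not
days enrolled) and data extend past day 42. Lag tables pool consecutive-day
tuples across patients with no imputation — a tuple is used only when every
field it needs is observed on consecutive calendar days — and bin predictors
at integers, flagging bins with fewer than 10 pairs. Winsorized drinks feed
the lag tables, consistent with the cap's purpose of limiting outlier
influence on model building.

## Synthetic cohorts

`synthetic.generate_cohort` emulates a 37-patient, 84-day diary study:

- Effective parameters `β_i = β + b_i`, `b_i ~ N(0, Ψ)` over
  `{a2, a3, d2, d3}`, with draws rejected until `a2, d2 ≥ 0`. The default
  `Ψ` is diagonal with the reference cohort's individual-level standard
  deviations (a2 0.0088, a3 0.4475, d2 0.2168, d3 0.3426); the true
  off-diagonal structure is unknown, so the diagonal default is a fixture,
  not an empirical claim. Because `d2`'s mean sits ~1.9 sd above zero, the
  rejection measurably shifts its expectation (+0.015); tests oracle against
  the truncated-normal mean.
- Initial conditions from independent truncated normals matching the
  reference summary statistics (mean/sd truncated to observed min/max).
- Observations are the exact trajectory plus i.i.d. `N(0, σ²)` noise on both
  outcomes (default σ² = 1.0 ≈ one drink / one desire unit of nightly
  reporting noise; a separate desire variance is available). Days are masked
  missing completely at random (default 20%, a typical diary compliance
  rate). Optional rounding/clipping to the observation scales (integers in
  [0, 17] and [0, 12]) is off for calibration-validation cohorts — it would
  leave the Gaussian likelihood family — and on for realism fixtures.
- **Day-1 convention.** The analysis *defines* the initial conditions as the
  first diary values, so the generator emits day 1 noise-free and never
  masks it. This is not a simplification but the definitional seed of the
  assumed observation model: noise on day 1 would place the data outside the
  likelihood family being validated, and near-unit-root patients amplify a
  day-1 seed error by many orders of magnitude over 84 days.

What the generator deliberately does not emulate: weekday/weekend
periodicity, assessment reactivity beyond what the dynamics produce,
informative (non-random) missingness, and the joint dependence structure of
real effective parameters. Passing recovery tests therefore demonstrate
correctness of the estimation machinery under the assumed model, not
robustness to these departures.

## Identifiability

The collinearity index of a parameter subset is `1/√λ_min(Ŝᵀ Ŝ)` where `Ŝ`
holds the subset's unit-normalized columns of the scaled local sensitivity
matrix (central finite differences of the trajectory, 1% relative step,
1e-4 absolute fallback at zero, one-sided at the boundary of nonnegative
parameters; each entry multiplied by `θ_k` and divided by the mean observed
magnitude of its output). The index is 1 for orthogonal columns, infinite
for an exactly compensable direction, and non-decreasing under column
addition; subsets with index ≥ 20 are flagged non-identifiable, with indices
in [20, 30) annotated near-threshold since the cutoff is conventional. The
per-output scaling is exposed as configuration; the index is invariant to
per-column rescaling, so only the A-row/D-row balance matters, and
alternatives rarely change the ranking.

Because the method is local, the screen runs per patient at that patient's
own six-parameter least-squares estimate. The final subset is the largest
one identifiable in at least 80% of patients (ties: more patients, then
smaller worst index). Size takes precedence over unanimity deliberately: a
four-parameter subset identifiable in nearly all patients preserves more
model flexibility than a three-parameter subset identifiable in all, and the
failures are typically near-threshold outliers of the local method.

## Mixed-effects calibration

Hierarchy: `y_ij = f_ij(β_i) + ε_ij` with `ε ~ N(0, σ²)` shared by both
outcomes, `β_i = β + b_i`, `b_i ~ N(0, Ψ)` over the varying subset (default
`{a2, a3, d2, d3}`; `a1 = 0.2829`, `d1 = 0.8144` fixed). Model predictions
during fitting are full trajectories simulated from the patient's own
data-derived initial conditions, not one-step-ahead predictions. Priors:
flat (improper) on `β`; `σ² ~ Inv-Gamma(shape n0/2, scale n0·s0²/2)` with
`n0 = 1`; `Ψ ~ Inv-Wishart(Ψ0, ρ0)` with density
`∝ |Ψ|^{−(ρ0+p+1)/2} exp(−½ tr(Ψ0 Ψ⁻¹))` and `ρ0 = 100`, expressing
confidence in the frequentist covariance estimate `C` the prior is centred
on — hence `Ψ0 = (ρ0 − m − 1)·C`, since an Inverse-Wishart's mean is
`Ψ0/(ρ0 − m − 1)`. Off-diagonal elements of `Ψ` are estimated.

**Initialization** is a two-stage frequentist pass: a six-parameter
least-squares fit per patient (multistart from documented generic points
plus a one-step-ahead linear-regression estimate — the model is linear in
its parameters given lagged observations, which keeps the start
well-conditioned even for escalating, near-unit-root patients), then a
conditional re-fit with `a1, d1` clamped, whose estimates seed the chain's
effective parameters and the `β0`/`Ψ0`/`s0²` hyperparameters.

**Sampler.** One sweep = (a) a blocked DRAM update of each patient's
4-dimensional `β_i` targeting `−SSR_i/(2σ²) − ½(β_i−β)ᵀΨ⁻¹(β_i−β)`:
Gaussian proposal with covariance `(2.38²/d)·cov(history)` re-estimated
every 100 sweeps from running moments, and on first rejection one delayed-
rejection stage with the proposal shrunk by 1/5, accepted with the standard
two-stage ratio; (b) `β | {β_i}, Ψ ~ N(mean β_i, Ψ/N)` (flat prior);
(c) `Ψ | · ~ IW(Ψ0 + Σ devᵢdevᵢᵀ, ρ0 + N)`; (d) `σ² | · ~
IG((n0 + n_obs)/2, (n0 s0² + SS)/2)`. Adaptation and delayed rejection can
each be disabled, reducing the sampler to adaptive Metropolis or plain
Metropolis-Hastings for testing. Burn-in discards the first half; identical
seeds give bit-identical chains. Proposals violating `a2, d2 ≥ 0` are
rejected via a −∞ target.

**Numerically stiff patients.** A random-effects draw occasionally yields
dynamics with spectral radius ≈ 1.2–1.6, whose 84-day trajectories amplify
parameter perturbations by up to ~1e16 — the exact conditional posterior of
such a patient is a point mass narrower than double-precision spacing, which
neither an optimizer nor a sampler can occupy. When a patient's best
trajectory-matching residual variance exceeds the cohort median by more than
1e6 (an unambiguous six-order gap), the sampler freezes that patient's
effective parameters at the one-step regression estimate (which approximates
the point mass to ~1e-10) and excludes their numerically meaningless
residuals from the `σ²` update; they still inform `β` and `Ψ`. The `Chain`
records the mask. Real bounded diary data (0–17 drinks) never trigger this
path.

**Summaries and diagnostics.** The population estimate is the posterior mean
of `β`; individual-level min/max/mean/median/sd are computed over the
per-patient posterior means, with fixed parameters echoed at zero spread.
Convergence uses the Geweke statistic (first 10% vs last 50% means with
Newey–West long-run variances, lag `n^{1/3}`; |z| > 2 flags) and effective
sample size; supplement-specific criteria of the original analysis are
unavailable, so these standard diagnostics stand in. Parameter-count
bookkeeping: `m` fixed effects + `m·N` random effects + 1 error variance +
`m(m+1)/2` covariance elements — 388 for nine varying quantities over 37
patients, 163 after the reduction to four.

## Global sensitivity analysis

Nine inputs (six parameters, three initial conditions) are sampled by Latin
hypercube — one uniform draw per equal-width stratum per input, strata
permuted independently — over mean ± 2 sd ranges centred on the population
estimates, floored at 0.001 for `d2` and the initial conditions, and with
`a1 ∈ [0.001, 1.0015]`, `d1 ∈ [0.001, 2.2742]`: the caps keep
single-parameter excursions from pushing any day's alcohol above the
17-drink cap (verified by the acceptance script). Outputs per sample are
total and maximum alcohol and desire over 84 days and one year, simulated
with clipping on; default design size 1000.

PRCC for input `k` is the Pearson correlation of the residuals of its ranks
and the output's ranks after regressing both (with intercept) on all other
inputs' ranks; ties get average ranks. Significance uses
`z = r·√((n − 2 − k)/(1 − r²))` against the standard normal (a Student-t
reference is available; at the default design size they agree to ~3%);
p-values are unadjusted two-sided. PRCC is meaningful for monotone
input-output relations, so single-input sweeps over each range report a
monotonicity verdict; at the population baseline the `d2` sweep is monotone
but flat through the estimate and steep only near the top of its range — a
large global PRCC does not imply local sensitivity at a given patient's
value.

## Pipeline

`run_pipeline` chains generate (or load CSVs) → winsorize/filter →
per-patient fits → collinearity screen → mixed-effects calibration →
posterior summary → LHS/PRCC + sweeps, writing tidy CSV/JSON artifacts and a
manifest with the configuration hash and seed; reruns are byte-identical.
With calibration disabled the sensitivity stage falls back to the packaged
reference estimates. The CLI (`drinkdyn simulate|generate|preprocess|
identify|fit|sensitivity|run|report`) is a thin wrapper over these library
functions.

## Problem sizes used in the shipped checks

Unit and property tests run on cohorts of 3–10 patients with short chains;
the recovery acceptance check uses five replicate cohorts at study scale
(37 patients × 84 days, σ² = 0.25, 20% missingness, rounding off) with
5000-iteration chains, asserting ≥ 90% coverage of the generating fixed
effects by the 95% credible intervals. Example scripts use 500-point LHS
designs; the packaged default is 1000.

## Known limitations

- The single shared `σ²` treats a drink and a desire unit as equally noisy;
  a per-outcome error variance exists in the generator but not in the
  likelihood, which follows the single-variance form.
- The diagonal default `Ψ` ignores the (unknown) correlation of real
  effective parameters and, combined with a population `a2` at the edge of
  stability, places ~35% of synthetic patients in locally unstable regimes —
  realistic in direction (escalating drinkers exist) but heavy-tailed in
  magnitude.
- The collinearity screen is local; a different least-squares basin can
  change a patient's verdict, which is why near-threshold indices are
  annotated rather than trusted.
- No train/test predictive validation is included; recovery tests validate
  estimation under the assumed model only.
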