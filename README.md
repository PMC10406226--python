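# drinkdyn

Coupled daily drinking–desire dynamics for ecological momentary assessment
(EMA) diary data.

People with mild-to-moderate alcohol use disorder who aim to *moderate*
rather than quit drinking generate a distinctive kind of data: a nightly
diary of standard drinks consumed and of desire (craving) to drink, collected
for twelve weeks. `drinkdyn` models those two series jointly with a pair of
delayed difference equations,

```
D_n = d1·A_{n-1} + d2·D_{n-1} + d3·(A_{n-1} − A_{n-2})
A_n = a1·(D_n − D_{n-1}) + a2·A_{n-1} + a3·(A_{n-1} − A_{n-2})
```

where `A_n` is drinks and `D_n` desire (a 0–12 composite of three Likert
items) on evening `n`. Desire is updated first; drinking then responds to the
same-day *change* in desire, to last night's drinking, and to the recent
drinking trend. Three initial conditions seed the recursion: a pre-study
baseline `A_0` (30-day Timeline Followback average) and the first diary
values `A_1`, `D_1`.

Around that core the package implements the full analysis pipeline such a
study needs:

- **`drinkdyn.model`** — simulation, equilibrium structure (abstinence
  `E0 = (0,0)`; abstinence with persistent desire when `d2 = 1`; sustained
  moderated drinking with `D* = d1·A*/(1−d2)` when `a2 = 1`), and qualitative
  behavior classification backed by the companion-matrix spectrum.
- **`drinkdyn.preprocess`** — diary CSV ingestion, the reverse-coded desire
  composite, winsorization of drink counts (cap 17 = mean + 2 sd), the
  cohort inclusion rule (≥ 30% complete days, data past day 42), weekly
  averages, and the pooled binned lag tables that motivate each linear term.
- **`drinkdyn.synthetic`** — a cohort generator with the exact statistical
  structure the analysis assumes (population parameters + Gaussian random
  effects on {a2, a3, d2, d3}, truncated-normal initial conditions, shared
  observation-noise variance, missingness, optional rounding/clipping), with
  ground truth attached for recovery studies.
- **`drinkdyn.identifiability`** — scaled local sensitivity matrices,
  collinearity indices `1/√λ_min` of every parameter subset (threshold 20),
  and selection of the largest subset identifiable across patients.
- **`drinkdyn.calibration`** — Bayesian mixed-effects estimation by
  Metropolis-within-Gibbs: per-patient DRAM (delayed-rejection adaptive
  Metropolis) blocks for the effective parameters, conjugate draws for the
  fixed effects (flat prior), the random-effects covariance
  (Inverse-Wishart) and the error variance (Inverse-Gamma), seeded by a
  two-stage frequentist fit; posterior summaries and Geweke/ESS diagnostics.
- **`drinkdyn.sensitivity`** — Latin hypercube sampling over parameters and
  initial conditions (mean ± 2 sd with documented floors/caps), four output
  measures (total and maximum alcohol and desire over 84 days or one year),
  PRCC with z-test significance, and single-input monotonicity sweeps.
- **`drinkdyn.pipeline` / CLI `drinkdyn`** — one-command orchestration of
  generate → preprocess → fit → identify → calibrate → sensitivity with a
  reproducibility manifest.

## Worked example

Simulate the cohort-average patient and read off its long-run behavior:

```python
from drinkdyn import classify_behavior, simulate
from drinkdyn.references import MEDIAN_ICS, POPULATION_PARAMS

traj = simulate(POPULATION_PARAMS, MEDIAN_ICS, horizon=84)
print(traj.to_frame().head(3))
#    day      A       D
# 0    1  4.000  7.0000
# 1    2  5.800  6.3814
# 2    3  5.195  7.2451
print(classify_behavior(POPULATION_PARAMS, MEDIAN_ICS))
# {'label': 'damped-oscillatory', 'dominant_eigenvalue_modulus': 0.9947}
```

The day-2 values (5.800 drinks, 6.38 desire units) are one application of the
two equations above; the spectral radius 0.9947 < 1 says the average patient
drifts — very slowly — toward abstinence, oscillating as desire and drinking
chase each other.

Calibrate a synthetic cohort and check recovery (`examples/calibrate_cohort.py`):

```
mean DRAM acceptance rate: 0.74
posterior mean sigma2: 0.245 (generating value 0.25)

fixed effects: posterior mean [95% credible interval] vs generating value
  a2: +0.9949 [+0.9877, +1.0020]   truth +0.9944
  a3: -0.6736 [-1.0106, -0.3331]   truth -0.4539
  d2: +0.3550 [+0.2258, +0.4925]   truth +0.4110
  d3: +0.0982 [-0.0643, +0.2749]   truth -0.0561
```

With only eight patients the trend coefficients are loose (their
individual-level spread is large), but every interval behaves as a 95%
interval should; at the study scale of 37 patients the acceptance suite
verifies ≥ 90% coverage across replicates.

The other scripts in `examples/` walk through cohort generation and
preprocessing, the identifiability screen (the six-parameter set fails the
collinearity threshold while `{a2, a3, d2, d3}` passes comfortably), and the
LHS/PRCC sensitivity analysis with its single-parameter sweeps.

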