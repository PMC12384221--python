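# Methods

## Survival model

All event and drop-out times are drawn from piecewise-exponential
distributions: the hazard h(x) is constant on segments `[b_i, b_{i+1})`
with the last segment extending to infinity, so the cumulative hazard
H(x) is piecewise linear and S(x) = exp(−H(x)) is exact.  Sampling is
by inverse transform on H (solve H(x) = E, E ~ Exp(1), segment by
segment), so the empirical distribution matches the closed form up to
Monte-Carlo error only.  The restricted mean μ(τ) = ∫₀^τ S(x) dx is
evaluated segment-wise in closed form.

Treatment effects are multiplicative, piecewise-constant hazard ratios
applied to the control hazard in *patient time* (time since
enrollment).  Hazards are right-continuous: a changepoint k belongs to
the later segment.  This convention is immaterial for continuous
distributions but is fixed for reproducibility.  Four patterns are
provided: proportional (single HR), early benefit (HR 0.4 before k,
0.8 after), late benefit (0.8 then 0.4), and crossing (1.2 then 0.6).

Drop-out is an independent exponential process specified by its
cumulative probability p by 5 years; the unique consistent rate is
λ_d = −ln(1−p)/5.  Informative censoring is out of scope.

## Trial generation

Entry times are continuous-uniform over the accrual window (no monthly
discretization of entries), with calendar time 0 at the opening of
enrollment.  Each patient has latent entry, event and drop-out times;
the follow-up regime turns them into the analysis snapshot:

* **Event-driven**: the analysis calendar time A is the calendar time
  of the D-th event, where an event occurs at entry + X only if
  X < C_d.  Observed time is min(X, C_d, A − entry); patients enrolled
  after A are excluded (cannot occur under the reference parameters,
  but the engine is total).  Event membership is decided on the
  calendar scale (entry + X ≤ A), which is exact because A is itself
  one of the event calendar times; deciding on the patient-time scale
  can lose the defining event to floating-point rounding.  If fewer
  than D events are ever attainable, the analysis happens when the
  last patient resolves and proceeds with the attained events — the
  attained-events count is invariant to this choice.
* **Fixed-horizon**: observed time is min(X, C_d, horizon);
  A = accrual duration + horizon.

The observed drop-out proportion at a horizon counts patients whose
latent drop-out precedes both their event and the horizon, so it is
regime-independent.

## Tests

Risk sets use the standard conventions: at a tied time, events precede
censorings (censored observations remain at risk at that time), and
Fleming–Harrington weights use the left limit of the *pooled*
Kaplan–Meier curve.  Variance terms with Y_j = 1 are defined as 0.

The design operationalizes the hypotheses one-sidedly at α = 0.025
with rejection only for treatment benefit; `weighted_logrank` exposes a
`two_sided` flag for the symmetric alternative.  The
survival-probability test is on the plain difference scale (no
complementary-log-log transform) with Greenwood variances.  The RMST
variance is Σ_{t_j ≤ τ} d_j/(Y_j(Y_j − d_j)) · (∫_{t_j}^τ Ŝ)², with
the d_j = Y_j term defined as 0 (the remaining area is then 0).  A
test that cannot be computed — no events, KM curve inestimable at t or
undefined on [0, τ] — reports p = 1 with a note and is counted as a
non-rejection by the simulation drivers.

MaxCombo components share per-row hypergeometric variance terms, so
their covariance matrix is exact.  The one-sided p-value is
1 − P(Z₁ ≤ z_max, …, Z_K ≤ z_max) under the components' joint Gaussian
law.  For K ≤ 3 this equicoordinate CDF is computed by nested
conditioning with a fixed 128-node Gauss–Legendre rule on the
probability scale — deterministic, absolute error below ~1e−6 for the
high inter-component correlations that arise in practice (validated
against scipy's quasi-Monte-Carlo CDF at tight tolerance); K > 3 falls
back to scipy with a pinned seed.  Exactly duplicated weight
components are dropped (they carry no information and make the joint
law singular); a degenerate correlation matrix falls back to a
Bonferroni bound, noted in the result.

## Design calculators

The event target is Schoenfeld's
D = ⌈(z_{1−α} + z_{1−β})² / (p₀p₁ (ln HR)²)⌉ with double-precision
normal quantiles.  Expected events by calendar time T under uniform
accrual over a years with exponential event rate λ_e and drop-out rate
λ_d is, per arm with θ = λ_e + λ_d:

n_arm · (λ_e/θ) · [1 − e^{−θT}(e^{θa} − 1)/(θa)].

The enrollment size is the smallest multiple of the monthly accrual
cohort (whole accrual months) whose expected events reach D by T — the
convention under which the reference inputs give exactly 350 (the
unconstrained minimum is ≈347).  Since accrual cannot extend past the
analysis time, the search is bounded and infeasible targets raise an
explicit error.  Horizons for the fixed-duration designs are
calibrated empirically: power is simulated on a candidate grid and the
horizon nearest the target power wins, ties going to the shorter
trial.

## Reference design and scenario grid

The reference design: exponential control arm with median 3 years,
proportional HR 0.6, 1:1 allocation, one-sided α = 0.025, 90% power,
D = 162 events, n = 350.  The planning arithmetic uses 10
patients/month (35 months of accrual); the simulated trials enroll
uniformly over 3.0 years, which is the accrual duration the deviation
family perturbs and the value that reproduces the event-driven
duration distributions.  Calibrated fixed-duration horizons are
t = 3.5 years (survival probability) and τ = 4.5 years (RMST).
MaxCombo variants: 2-component {(0,0), (0,0.5)} and 3-component
{(0,0), (0,0.5), (0.5,0.5)}.

The grid holds 35 alternative scenarios — control medians
{2, 2.5, 3, 4, 5}; HR {0.4, 0.5, 0.6, 0.7, 0.8}; early- and
late-benefit changepoints k ∈ {1,…,5}; crossing changepoints
k ∈ {0.25, 0.5, 1, 1.5, 2}; accrual durations {2, 2.5, 3, 3.5, 4};
5-year drop-out {0, 0.15, 0.30, 0.45, 0.60} — plus 13 null twins
(HR = 1) for the baseline, accrual and drop-out families, where Type I
error is meaningful.  Null twins of the effect families would change
the alternative itself and are not part of the grid.  Under
drop-out/accrual null scenarios the control model is the reference
(median 3 years).

## Monte Carlo and seeding

The study scale is 10,000 iterations per scenario (MC standard error
of a 0.9 power ≈ 0.3%; of a 0.025 size ≈ 0.16%); `reps` is a parameter
everywhere and the examples use 1,000–2,000 where the point is
illustration.  Within an iteration the same latent patient times are
analyzed under every regime (toggleable), which removes between-test
sampling noise from comparisons.

All randomness derives from one master seed through
`numpy.random.SeedSequence` spawn keys: one substream per (scenario
family, scenario index, process), with processes = entry, control
events, treatment events, drop-out.  Iterations are rows of the
substream's draw matrices.  Consequences: running a subset of
scenarios reproduces the full grid's numbers exactly; adding scenarios
never perturbs existing ones; and designs differing only in one
process (say the drop-out rate) are coupled — drop-out times are
monotone in the rate for fixed uniforms, so raising drop-out can never
add events to a coupled trial.

## What the generator does and does not emulate

The generator reproduces the study conditions: uniform accrual,
exponential-family event times, independent exponential drop-out, and
instantaneous complete ascertainment at the analysis time.  Real
trials add features deliberately not modeled here: staggered site
activation and non-uniform accrual, informative censoring, interval-
censored assessment schedules, cure fractions and non-exponential
baselines (Weibull, log-logistic), and data-cleaning lag between the
D-th event and the analysis.  Passing tests therefore validate the
operating characteristics of the *methods under these idealized
conditions*, not the behavior of any particular real trial.

## Numerical notes and limitations

* Event times, being continuous, tie with probability zero; the tie
  conventions above exist for degenerate/rounded inputs.
* The event-driven engine uses `np.partition` for the D-th event time;
  with the calendar-scale event rule the dataset contains exactly D
  events whenever attainable, bit-exactly.
* CSV round-trips serialize floats at 17 significant digits and read
  back with `float_precision="round_trip"`.
* Multi-arm designs, unequal allocation beyond a single ratio,
  stratified or covariate-adjusted tests, interim analyses and
  group-sequential monitoring are out of scope.
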