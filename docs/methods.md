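# Methods

## The design and its two clocks

The standard stepped-wedge layout has K clusters observed over
n = K + 1 equally spaced calendar steps t = 1..n. All clusters are under
control at t = 1; at each later step exactly one cluster crosses to the
intervention, permanently, so the treatment matrix x_tk is the familiar
upper-triangular wedge and at step t exactly t − 1 clusters are treated.
Each cluster k therefore carries two clocks: calendar time t and exposure
time d_tk = t − s_k + 1 (0 under control), where s_k is the cluster's
crossover step. Exposure is 1 at the first treated step and at most
n − 1. The cohort is closed: every participant is measured at all n
steps, so with m participants per cluster a dataset has K·m·n rows.

The default rollout order is the identity (cluster k crosses at step
k + 1); a seeded random permutation is available, but no design-level
summary depends on which cluster takes which step, so the deterministic
default keeps replications simple.

## Generating scenarios

Thirty-six scenarios (D1..D36) define the simulator's mean models on a
13-step design. Each combines an intercept of 14 (a typical total HoNOS
level, the 0–48 mental-health outcome the simulator emulates) with a
subset of: a step intervention effect ∂ ∈ {0, +2, −2}; a linear calendar
slope τ = 0.25 per month; a linear exposure slope ψ ∈ {0.15, 0.25, −0.50}
per month; a sinusoidal calendar profile (half cycle 2·sin((t−1)π/12) or
full cycle 2·sin((t−1)π/6)); and a sinusoidal exposure profile
(sin((d−1)π/12) or sin((d−1)π/6), zero at d = 0). Scenarios use either
the linear terms or the profiles, never both. Odd-numbered scenarios set
the within-participant correlation ρ = −0.5 (the estimate from the
motivating trial's repeated HoNOS measures), even-numbered +0.5.

One entry of the half-cycle calendar vector is worth noting: at t = 6 the
formula gives 2·sin(5π/12) = 1.93, which also follows from the vector's
symmetry about its t = 7 peak; the package uses the formula value
throughout.

Random structure, common to all scenarios and estimated from the
motivating trial: cluster intercepts γ_k ~ N(0, 0.96²), participant
intercepts h_i ~ N(0, 4.42²), residual SD σ = 5.44. Residuals follow a
stationary AR(1): ε_1 ~ N(0, σ²) and ε_t = ρ ε_{t−1} + s_t with
innovation variance (1 − ρ²)σ², which keeps Var(ε_t) = σ² at every step
and corr(ε_t, ε_{t+r}) = ρ^r. All components are overridable; the listed
values are the defaults because they are the study conditions the
simulator exists to emulate.

What the generator does **not** emulate: open cohorts (entry/exit),
missing visits, bounded/discrete outcomes (HoNOS totals are integers in
[0, 48]; the simulator is Gaussian), cluster-size imbalance, and
calendar-by-cluster interactions. Passing tests therefore demonstrate
correctness of the machinery under the stated Gaussian closed-cohort
conditions, not robustness of any formulation to those real-data
features.

## Seed discipline

A master seed spawns one independent substream per (scenario, replicate)
via `numpy.random.SeedSequence(master, spawn_key=(scenario_index,
replicate))`. Any replicate can be regenerated in isolation, grids are
resumable and parallelizable without changing results, and — because the
substream does not depend on the fitted model — every formulation sees
identical data in matched comparisons.

## The likelihood engine

The marginal model is Gaussian with block-diagonal covariance, one block
per cluster: V_k = σγ²·J + blockdiag_i(σh²·J_n + R), with R = σ²·I under
compound symmetry or R_ab = σ²ρ^|t_a−t_b| under AR(1). Fixed effects are
profiled out by GLS at each candidate variance parameter vector, and the
exact Gaussian log-density at (β̂(θ), θ) is maximized over θ on
transformed coordinates — log SDs and atanh ρ — with L-BFGS-B inside
generous box bounds (log SD ∈ [−8, 8], atanh ρ ∈ [−5, 5]), a Nelder–Mead
polish on non-convergence, and a method-of-moments restart. Boundary
solutions (σγ → 0, common in small-cluster trials) are reported, not
errored. The moment start decomposes OLS residuals into cluster-mean,
participant-mean and within-participant variances and pools a lag-1
autocorrelation.

Numerically, clusters sharing a covariance pattern are factorized once.
For the common balanced case (every participant in a cluster observed at
the same time grid) the cluster covariance is a rank-one update of
I_m ⊗ A, A = σh²J_n + R, so a Sherman–Morrison identity reduces all dense
work to the n × n scale; irregular clusters fall back to a per-cluster
Cholesky of the full block. Both paths are tested against a dense
multivariate-normal log-density to 1e−8.

BIC is −2·logLik + p·ln(N) with p counting fixed effects plus variance
parameters (3 under CS, 4 under AR1) — the convention of standard
mixed-model software, verified to match `nlme::lme` (ML) to ~1e−4 on both
structures, along with the log-likelihood, fixed effects, variance
components and ρ.

## Formulations, identifiability, estimands

Categorical calendar time uses t = 1 as reference (κ_1 = 0) and
categorical exposure d = 0 (ξ_0 = 0) — forced by the tabulated vectors
leading with zero. Two constraints are structural in a stepped wedge:

- the categorical time × treatment model carries interaction columns only
  for t = 3..n−1 (ten columns at n = 13). At t = 2 the single treated
  cluster's effect is already the step term, and at t = n there is no
  concurrent control, so κ_n absorbs the treated-only calendar effect and
  φ_n is incomputable;
- the categorical time + categorical exposure model has no separate step
  term: treatment is exactly "exposure > 0", so a step column is a linear
  combination of the exposure dummies.

Requesting the unrestricted versions raises a rank error naming the
aliased columns rather than silently dropping parameters.

Both estimands are linear contrasts with Wald intervals from
(X′V̂⁻¹X)⁻¹, using the normal reference by default (the convention of
contrast machinery on ML fits; a t reference with N − p_fixed degrees of
freedom is available as an option since software differs here). Six
months is the median exposure of a 13-step wedge, which is why the
six-month and time-averaged estimands coincide for the
continuous-exposure models (∂ + 6ψ), while the interaction models average
over calendar time (∂ + 7ω continuous; mean of φ_3..φ_12 categorical)
and the exposure-dummy model averages ξ_1..ξ_12.

True estimand values depend only on the generating scenario:
∂ + 6ψ + X(6) for six months, and ∂ + 6ψ + mean_{d=1..12} X(d)
time-averaged, with X the scenario's exposure profile (zero if absent).

## Evaluation metrics

Per grid cell (scenario × formulation × structure), replicates are scored
on: coverage (fraction of 95% intervals containing the true estimand),
bias of the mean estimate, mean interval width, mean squared error of the
fit, and mean BIC. Non-converged replicates are excluded from all metric
means and counted; a second coverage denominator treating them as misses
is reported alongside, since silent inclusion would corrupt coverage and
the exclusion convention is otherwise a judgement call.

MSE uses conditional fitted values by default — fixed effects plus
empirical BLUPs of both random intercepts, σγ²·1′V⁻¹r per cluster and
σh²·Σ V⁻¹r over a participant's rows — matching the default fitted values
of standard mixed-model software; a marginal (fixed-effects-only) switch
is retained for sensitivity.

## Numerical and scale choices

- Convergence: L-BFGS-B ftol 1e−11 (relative), with polish; refits are
  bit-identical given identical inputs.
- Desk-scale defaults: the shipped `desk.cfg` runs a 4-scenario ×
  4-formulation CS grid at 200 replicates; `paper_full.cfg` documents the
  full 648-cell, 1000-replicate setting. The test suite uses the
  desk-scale sizes, which keep the whole run in minutes while leaving
  binomial noise on a 200-replicate coverage estimate at about ±1.5
  percentage points (1 SE at 0.95).
- The canonical master seed is 20181206.

## Known behaviour and limitations

Fitting with the CS working covariance when the generating residuals have
ρ = −0.5 produces mildly **conservative** Wald intervals for the
exposure-dummy contrasts: the model-based SE exceeds the sampling SD of
the estimator, so coverage sits near 0.97–0.98 rather than 0.95 (the
effect reverses sign in expectation for ρ = +0.5). The estimator itself
remains unbiased. This is a genuine consequence of covariance
misspecification, visible in the coverage tests; fitting the correctly
specified AR(1) structure moves coverage back toward nominal.

Other limitations: REML is not implemented (ML is required for BIC
comparison across mean models); random slopes, crossed random effects and
non-Gaussian outcomes are out of scope; the deposited-workbook reader
infers its column mapping by name matching and derives exposure from each
cluster's first treated month, so workbooks with exotic headers need
renaming before ingest.
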