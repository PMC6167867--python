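# Methods

## Model and framework

Each subject carries a waiting time `W` to an intermediate clinical event
(IE) and an event time `T`, assumed independent. With `Z = I(W ≤ T)`, the
event time decomposes as `T = (1 − Z)·T₀ + Z·T₁`, where `T₀` follows the
pre-IE survival distribution `Q₀` and `T₁` the post-IE distribution `Q₁`,
left-truncated at `W`: a subject observed to experience the IE has, by
selection, survived to `W`. This is the length-bias mechanism that breaks
the plain and the IE-stratified log-rank tests when the two arms differ in
IE incidence.

`T` is interval-censored by a visit process: observed data per subject are
the arm label, the censoring interval `(L, R]` (`R = ∞` if right-censored,
`L = R` if exact), the event indicator `δ`, the IE indicator `Z`, and —
exactly observed — the IE time `W` when `Z = 1`. The truncation set
`(W, ∞)` always contains the censoring interval (`W ≤ L`).

Two-arm comparison is formulated under stratum-specific proportional
hazards `Q_kA(t) = Q_kB(t)^{β_k}` (`k = 0` pre-IE, `k = 1` post-IE) and the
composite null `β₀ = β₁ = 0`, tested by the 2-df chi-square combining the
two score statistics (`score_tests.nam_zelen_score`). The hypothesis is
separable; 1-df component tests are reported alongside. The test is
independent of the waiting-time distribution.

## Score statistics and ties

The scores are computed in counting-process form; each event contributes
to exactly one component according to its subject's IE status at its own
event time (`z(t) = I(W ≤ t)`, closed at `W`). Entry into the post-IE risk
set is likewise at `W` inclusive, uniformly with the printed definition of
`z`; this uniform convention also makes the all-exact-intervals reduction
(below) exact.

Tied event times are aggregated with shared risk-set shares, and the null
variance carries the hypergeometric multiplicity factor `(N − dN)/(N − 1)`
per distinct event time. The factor is 1 wherever events are untied — the
situation the variance formula `Σ p(1 − p) dN` assumes — but it matters
after imputation: draws from a discrete distribution with few atoms tie
heavily (an NPMLE-weighted imputation of ~50 events can land on fewer than
a dozen distinct values), and the uncorrected variance then overstates the
null variance enough to visibly depress size and power. Zero-variance
components are dropped with the degrees of freedom reduced and a warning.

## Multiple imputation

Candidate mass points per stratum (`npmle.build_candidate_sets`): for the
pre-IE stratum, the interval endpoints of non-IE subjects plus the IE times
of IE subjects (their pre-IE course is right-censored at `W`); for the
post-IE stratum, the endpoints and IE times of IE subjects only. Both sets
include 0 and ∞ as sentinels.

Each of `M` imputations completes the data twice:

* pre-IE view (all subjects): non-IE censored subjects keep `L` as
  censoring time; IE subjects are censored at `W`; non-IE events get a
  drawn time in `(L, R]`;
* post-IE view (IE subjects only, truncated at `W`): censored subjects
  keep `L`; events get a drawn time in `(L, R]`.

Draw weights are either uniform over the stratum candidate points inside
`(L, R]`, or proportional to the stratum NPMLE restricted to `(L, R]` and
renormalized. Exact observations (`L = R`) impute deterministically at
`R`. Two degenerate cases are guarded and logged: an empty candidate
subset imputes `R` itself (a valid upper bound), and zero conditional
NPMLE mass falls back to the uniform draw. `M` defaults to 10; `M = 1` is
permitted (between-variance 0, warning).

Pooling (`imputation.pool_rubin`): with `S̄ₖ` the mean score, `withinₖ` the
mean per-imputation null variance and `betweenₖ` the across-imputation
sample variance, both variance combinations are reported —

    V₁ = within + (1 + 1/M)·between      (additive)
    V₂ = within − between                (subtractive)

and satisfy `V₁ − V₂ = (2 + 1/M)·between` identically. The additive form
tends to slight over-coverage, the subtractive to slight under-coverage.
A nonpositive `V₂` (possible, e.g. when all per-imputation variances are
equal and scores vary) falls back to `V₁` for that component and is
flagged in the result. P-values use the chi-square reference (2 df
composite, 1 df separable); no finite-`M` F-type reference is applied.

When every interval is exact the imputations are all identical and the
pooled test coincides with the direct score test on the observed data —
asserted in the test suite up to summation order.

## Turnbull NPMLE

The stratum NPMLEs used as sampling weights are fitted by the
self-consistency/EM iteration on the innermost (Turnbull) intervals
computed from all observation endpoints, with truncation endpoints
participating as left endpoints (they may carry mass). Truncation is
handled by Turnbull's ghost-count E-step: each subject contributes its
expected number of unobserved companions outside its truncation region.
Right endpoints sort before left endpoints at ties so abutting intervals
`(1,2], (2,3]` both survive; exact observations are encoded by opening the
left endpoint by a relative 1e-9. Each support interval is represented in
sampling by its right endpoint, consistent with the endpoint candidate
sets used elsewhere.

Convergence: maximum absolute mass change < 1e-6 (also applied to the
log-likelihood change), capped at 5000 iterations with a flagged,
non-fatal warning on failure. The log-likelihood is nondecreasing along
the iteration and masses stay normalized to 1e-8. With only exact and
right-censored observations and no truncation the estimate equals the
Kaplan–Meier estimator (asserted against lifelines). Under left truncation
the unconditional NPMLE is known to be inconsistent at early times; no
correction is applied, since the estimate serves only as an imputation
weight, not as a reported estimator — the uniform- and NPMLE-weighted
tests behave near-identically in simulation.

## Synthetic cohorts

The generator (`simulate`) draws, per arm `g ∈ {A, B}`:

* `W ~ Exponential(μ_g)` with `μ_g = θ_g λ₀g / (1 − θ_g)`, so the IE
  probability is exactly `θ_g = μ_g / (μ_g + λ₀g)`;
* `T₀ ~ Exponential(λ₀g)`; if `W ≤ T₀` then `Z = 1` and `T₁` is drawn from
  the `Exponential(λ₁g = 1/m₁g)` left-truncated at `W` by inversion
  (equivalently `W` plus a fresh exponential, by memorylessness);
* an independent Bernoulli censoring flag with probability `c_p`;
* a visit process: first visit `E ~ U(0, ψ)` (`U(W, W + ψ)` for IE
  subjects — post-IE follow-up starts at the observed IE), subsequent
  visits every `ψ = 0.5`, each missed independently with probability 0.1
  before time 1.0 and 0.2 afterward; the first visit is always attended
  and the visit count is uncapped. `L` is the largest attended visit below
  `T` (falling back to the follow-up origin, 0 or `W`) and `R` the
  smallest attended visit at or above `T`; right-censored subjects keep
  `L` and get `R = ∞`.

Defaults mirror the simulation scenarios the package reproduces:
`θ_A = 0.5`, `λ₀ = 1` in both arms, post-IE means `m₁ ∈ [1, 2]`,
`c_p ∈ {0, 0.3}`, 50–200 subjects per group, 1000 replications. "Before
time 1.0" for the visit-miss probability is one mean pre-IE survival time,
the natural unit of the scenario scale.

Randomness is organized as one root `SeedSequence` with spawned child
streams: per replication, then (cohort, uniform MI, weighted MI), then one
stream per imputation — so any method's draws are invariant to which other
methods run, and results are exactly reproducible from the scenario seed.

What the generator does *not* emulate: dependent censoring, non-exponential
latency families, interval-censored IE times, covariates, staggered entry.
Passing simulations therefore certify the procedure under exactly the
stated mechanism, not robustness to these departures.

## Simulation harness and problem sizes

`experiments.run_scenario` replicates the pipeline and reports, per
scenario, the fraction of replications with `p < 0.05` for each of: plain
log-rank and IE-stratified log-rank (computed on the latent true times, as
comparators), and both MI tests under both variance forms. Failed
replications are logged and excluded; a row with more than 1% failures is
marked invalid. Monte-Carlo standard errors `sqrt(p(1−p)/n_reps)`
accompany every cell.

The bundled acceptance script re-computes six headline cells at 1000
replications and n = 50–200 per group, matching the published values to
within binomial Monte-Carlo error; the test suite additionally checks the
size of both MI tests at n = 100 per group (the middle of the sample-size
grid) against the binomial 99% band [0.03, 0.07] around the nominal level.

## Known limitations

* The IE time must be exactly observed; interval-censored `W` is out of
  scope.
* Two arms only; no covariate adjustment, no weighted (G-rho) log-rank
  family.
* The NPMLE weight inherits the early-time inconsistency under truncation
  noted above.
* The chi-square reference ignores finite-`M` variability in the pooled
  variance; with `M = 10` this is visible only as the documented mild
  over/under-coverage of the additive/subtractive forms.
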