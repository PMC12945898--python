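# Methods

`accumulate` implements a complete individual-differences workflow for
binary choice/RT data: two evidence-accumulation models with matched
omission handling, individual Bayesian estimation, posterior predictive
assessment, the EEA/SEA decomposition of accumulation rates, and the
mixed-model association stage that relates those measures to external
criteria. Every stage is exercised end to end on synthetic cohorts, so the
whole pipeline is testable without any restricted-access data.

## Models

### Linear ballistic accumulator (LBA)

Each response option has an independent accumulator that starts at a point
drawn uniformly from `[0, A]` and rises linearly at a rate drawn from
`Normal(v_j, sv_j)` toward a threshold `b_j = A + B_j`. The first
accumulator to reach threshold produces its response at decision time
`(b_j - start)/rate`; observed RT adds a nondecision time `t0`. Rates are
condition- and match-specific: in condition `c` the accumulator for the
correct response has mean rate `v_match[c]`, the other `v_mismatch[c]`.
The matching accumulator's rate SD is fixed at 1 as the scaling constant
(multiplying `v, sv, A, B` jointly by `k` leaves choice probabilities
unchanged); `sv_mismatch` is estimated, shared across conditions.

Rates are untruncated normal, so an accumulator can draw a negative rate
and never finish; the event that no accumulator finishes is folded into
the omission probability, which makes the omission model coherent:

    P(omission) = p_gf + (1 - p_gf) * [1 - sum_r P(response r recorded
                                                   inside the window)]

where `p_gf` is a go-failure mixture (trials with no response for reasons
outside the race) and the bracket covers both never-finishing races and
censoring by the response window (2 s for n-back, 3 s for numerosity).
Responded trials contribute `(1 - p_gf) * f_r(rt - t0) * prod_{j != r} (1 -
F_j(rt - t0))` with the standard two-Phi/two-phi closed forms for the node
density `f` and CDF `F`. The `A -> 0` limit (finish time `b/rate`) is
evaluated by an analytically simplified branch below `A = 1e-3` in the
batched likelihood (`1e-6` in the reference functions) to avoid
catastrophic cancellation.

The n-back design estimates one threshold gap `B`; the numerosity design
estimates response-specific gaps (`B_many`, `B_few`), which mirrors how
these tasks are usually parameterized.

### Diffusion decision model (DDM)

A single accumulator starts at `z = z_rel * a` between boundaries 0
(error) and `a` (correct) and drifts at condition-wise mean rate `v[c]`
with within-trial noise SD fixed at `s = 1`. Note the scaling convention:
packages in this area split between `s = 1` and the legacy `s = 0.1`;
drifts and boundaries here are on the `s = 1` scale (10x the legacy
scale). The parameter set is deliberately minimal — `v[c], a, z_rel, Ter,
st0, p_gf` — with no between-trial drift or start-point variability; this
is the matched counterpart of the LBA above, not the "full DDM". The start
point is estimated as relative (`z_rel`) for sampler geometry and reported
both ways.

First-passage densities use the classical infinite-series solution with
automatic switching between the small-time and large-time representations,
chosen per evaluation by comparing the number of terms each needs for an
absolute truncation tolerance of 1e-10; the two representations agree to
better than 1e-8 across the switching region. The survival function (for
censoring/omissions) uses the analytically integrated large-time series,
accurate once `t/a^2` exceeds about 1e-3 — always the case at response
windows. Nondecision time is uniform on `[Ter - st0/2, Ter + st0/2]` and
integrated by 11-point Gauss-Legendre quadrature (error < 1e-5 over the
tested parameter grid; order configurable).

The Euler-Maruyama simulator (default `dt = 1e-3` s, cap 10 s, cap
reached counts as an omission) is kept deliberately plain because it
serves as an *independent* oracle for the series likelihood; its known
small-`dt` discretization bias (first-passage times late by
O(sqrt(dt))) is why likelihood-vs-simulation comparisons in the tests use
`dt = 1e-4` or finer.

## Estimation

Each subject is fit independently (no hierarchical pooling) by
differential-evolution MCMC: each chain's proposal is `gamma * (chain_a -
chain_b) + Uniform(-eps, eps)` with distinct random partners, Metropolis
acceptance, and `gamma` drawn per iteration from `[0.5, 1] x
2.38/sqrt(2d)` so the ensemble keeps mixing when local scales differ from
the global one. During burn-in a ring-migration step (probability 0.05 per
iteration) offers random chains their predecessor's state, rescuing chains
stranded in the tails of the broad initialization. Defaults: `3d` chains
(`d` = number of parameters), burn-in 500, sampling blocks of 500 up to a
cap of 10,000 iterations, jitter `eps = 1e-3`; all configurable via
`FitConfig`.

Positive parameters are sampled on the log scale and interval-bounded ones
on the probit scale, with Jacobians included, so the sampler works on an
unconstrained space. Priors are broad: rates `Normal(1, 3)`; `a, A, B,
sv_mismatch` positive-truncated `Normal(1, 2)`; `t0/Ter ~ Uniform(0.05,
1)` s; `st0 ~ Uniform(0, 0.5)` s; `p_gf ~ Uniform(0, 0.2)`; `z_rel ~
Uniform(0.05, 0.95)`. These are declared substitutes chosen to cover
published DDM/LBA ranges, not reconstructions of any particular study's
priors, and are user-overridable.

Convergence is gated on the Gelman-Rubin potential scale reduction factor:
after each sampling block, R-hat is computed per parameter on the second
halves of the chains, and sampling stops when the maximum falls below 1.10
or the cap is reached; the result carries a `converged` flag either way.
`gelman_rubin()` itself applies no halving (so hand-checkable examples
hold exactly); the halving is the fitting loop's policy.

## Derived measures

From the LBA: `EEA = mean_c(v_match[c] - v_mismatch[c])` (efficiency —
how selectively task-relevant evidence is accumulated) and `SEA =
mean_c((v_match[c] + v_mismatch[c])/2)` (speed — how fast evidence
accumulates regardless of quality). From the DDM: `v_mean`, the unweighted
mean of condition drifts. Point estimates use posterior means (medians by
option). EEA is invariant to adding a constant to both rates; SEA shifts
one-to-one — together they are an invertible linear map of the
condition-averaged rates.

## Posterior predictive checks

For each of `n_draws` posterior draws a dataset with the observed
per-condition trial counts is simulated and summarized identically to the
data: response proportions (summing to 1 with omissions included) and RT
quantiles at .1/.3/.5/.7/.9 per response. The numeric table (observed,
predictive median, 2.5/97.5 percentiles) is the testable artifact; the
cumulative-probability-by-quintile plot is a thin optional layer. Checking
a model against data it generated yields ~95% coverage of the 95%
intervals, which is the calibration property the tests assert.

## Association stage

Criterion scores are related to EEA and SEA with linear mixed models with
random intercepts for nesting factors (family, site), fit by REML via
statsmodels `MixedLM` (crossed factors as variance components on a single
super-group; degenerate designs fall back to OLS with components pinned at
0 and flagged). Marginal R-squared is `var(X beta) / (var(X beta) + sum of
variance components + residual variance)`. The unique contribution of a
predictor set is the semipartial (part) R-squared: marginal R-squared of
the full model minus the model without the set, floored at 0; its 95% CI
is a percentile bootstrap (default 1000 resamples) over top-level groups
(families) to respect nesting, switchable to subject resampling.

## Synthetic studies

The generator draws latent `(EEA, SEA, B, t0, logit p_gf)` per subject
from a multivariate normal — defaults `EEA ~ N(1.5, 0.5)`, `SEA ~ N(1.75,
0.4)`, `corr(EEA, SEA) = 0.3`, `B ~ N(0.9, 0.15)`, `t0 ~ N(0.3, 0.05)` s,
`p_gf ~ logit-N(-3.5, 0.4)` (median ~3%) — chosen once as representative
of individual-difference spreads in large cohort n-back samples. Rates
come from the exact inverse of the EEA/SEA definitions plus zero-mean
condition offsets (lures harder in n-back; hard numerosity ratios lower
both margins), so the generating EEA/SEA equal the latent traits and
parameter recovery closes the loop. Subjects are nested two per family
across two sites. Criterion scores are `loading * z(EEA) + family
intercept + site intercept + noise` with default loading 0.45 and noise
calibrated so the leading criterion has population R-squared ~0.20.

What the generator does *not* emulate: stimulus-level variation (faces,
asterisk counts), sequential effects, response-window anticipations, fast
guesses, practice/fatigue drift, or heritability structure beyond a
generic family intercept. Passing tests therefore demonstrate internal
consistency of the method — likelihoods match their processes, estimation
recovers known truths, the inferential stage detects a known generative
ordering — not robustness to the many ways real behavioral data violate
these models.

### The speed/efficiency dissociation

Sweeping SEA with EEA fixed lowers mean choice RT monotonically while
accuracy barely moves; sweeping EEA with SEA fixed moves accuracy
monotonically. Accuracy is not *exactly* invariant to SEA — start-point
variability and window censoring induce a weak dependence — so the
package defines the sweep grids once: SEA over its central population
range (mean +/- 1.25 SD, analytic accuracy range ~1.3 percentage points)
and EEA over its full range (mean +/- 2 SD). Over a much wider SEA sweep
(+/- 3 SD) the accuracy drift would exceed 2 percentage points; the
dissociation is a property of realistic individual-difference ranges, not
a mathematical identity.

## Problem sizes and numerical choices

Reference checks in the tests use 1e6-trial simulations for choice
probabilities and omission rates (Monte-Carlo SE ~5e-4) and 1e6 Euler
paths at `dt = 1e-4` for the DDM. Cohort-level checks use 40 subjects at
300 trials/condition with shortened schedules (LBA: burn-in 500, blocks
of 250, cap 1250 sampling iterations with 3d chains; DDM: burn-in 300,
blocks of 150, cap 600 with 16 = 2d chains, which matches the 3d-chain
estimates to ~0.02 in `v_mean`) — enough for stable posterior means of
the rate parameters and EEA/SEA recovery correlations above .9/.89,
though LBA nuisance parameters (A, sv_mismatch) often retain R-hat above
1.10 at that length; the full-length defaults are the package's
recommendation for substantive use. The batched likelihoods are backed by
compiled kernels that agree with the reference implementations to
machine precision (tested), with one documented divergence: the batched
LBA path switches to the analytic `A -> 0` branch at `A < 1e-3` rather
than `1e-6`. Defective-density integrals
use panelled Gauss-Legendre quadrature (96 nodes per panel, a 1/t
substitution for the unbounded tail; absolute error ~1e-9). Likelihood
floors densities at 1e-300 before logging and returns -inf for
responded trials with zero density (e.g. `rt <= t0`); the Ter-st0/2 >= 0
constraint is enforced as a hard rejection in the DDM posterior.

A note on the headline ordering: the DDM's `v_mean`, fit to LBA-generated
cohorts, loads primarily on latent EEA but also partly on latent SEA
(faster accumulation at equal discriminability is resolved as somewhat
higher drift with a lower boundary). The *gap* between `r(v_mean, EEA)`
and `r(v_mean, SEA)` therefore shrinks as the cohort's sample correlation
between the two traits grows; at 40 subjects that sample correlation
fluctuates substantially around its population value of 0.3, so the gap
varies noticeably from seed to seed even though the ordering itself is
stable. The gap computed on fitted EEA/SEA (the quantities an empirical
study would correlate) is consistently wider than the gap against the
latent truths.

## Known limitations

- Individual estimation only; no hierarchical shrinkage.
- Binary choice only (the defective-density product supports n-ary races,
  but task designs ship for two-response paradigms).
- The DDM omits between-trial drift/start variability by design; fits to
  data generated by richer processes will show the corresponding misfits.
- QC accuracy uses responded trials as the denominator and pools across
  conditions; a per-condition criterion would exclude different subjects.
- Part-R2 bootstrap refits two mixed models per resample; with many
  criteria and 1000 resamples this dominates pipeline runtime.
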