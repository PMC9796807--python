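# Methods

## Model

An m-state Poisson hidden Markov model: an unobserved irreducible Markov
chain {C_t} on {1..m} with transition probability matrix Γ (rows sum to
one), and counts X_t | C_t = i ~ Poisson(λ_i), conditionally independent
given the state path. By default the chain is assumed stationary, so the
initial state distribution is the stationary vector δ solving δΓ = δ,
Σδ_i = 1; a free (estimated) or user-supplied initial distribution is also
supported. The likelihood is the matrix product

    L = δ P(x_1) Γ P(x_2) Γ ... Γ P(x_T) 1',

with P(x) = diag(p_1(x), ..., p_m(x)) the Poisson probabilities. A missing
observation contributes P = I (it is marginalized exactly); all other
observations must be non-negative integers.

## Likelihood evaluation

The forward recursion is computed with per-step scaling: at each t the
forward vector is renormalized to sum to one and the log of the
normalizer is accumulated. In addition, the log-pmf row at each t is
shifted by its maximum before exponentiation, and the shift is added back
to the accumulated log-likelihood; the shift is a constant factor at each
step and therefore does not affect derivatives. This keeps the evaluation
finite for series of length 10^5–10^6 and for extreme parameter values
visited during optimization. The backward recursion is scaled the same
way; the forward and backward log-likelihoods are cross-checked at 1e-8.

## Parameterization

Optimization runs on an unconstrained working vector:

- η_i = log λ_i (m components);
- multinomial-logit transition rows with the diagonal element as the
  reference category: γ_ij = exp(τ_ij) / (1 + Σ_{k≠i} exp(τ_ik)) with
  τ_ij = log(γ_ij / γ_ii), stored row-major with the diagonal skipped
  (m(m−1) components);
- optionally m−1 initial-distribution logits ξ with state 1 as reference,
  present only when the initial distribution is estimated freely.

The flattening order is (η, τ, ξ). The inverse map uses a row-wise
softmax over (0, τ_i·) shifted by the row maximum, so extreme logits do
not overflow. Natural parameters exactly on the boundary (a zero
transition probability) have no finite working image and raise a
boundary error.

## Exact derivatives

The gradient and Hessian of the negative log-likelihood with respect to
the working parameters are computed analytically, not by finite
differences, via forward-mode sensitivity recursions: alongside the
scaled forward vector φ_t, the recursion propagates ∂φ_t/∂θ_q and
∂²φ_t/∂θ_q∂θ_r through the same scaling operations. The chain rule
inputs are closed-form:

- Poisson log-pmf: ∂ log p / ∂η = x − λ, ∂² log p / ∂η² = −λ (zeroed at
  missing positions);
- softmax Jacobian and Hessian of each transition row with respect to its
  row logits;
- stationary-distribution derivatives from the augmented linear system
  δ(I − Γ + U) = 1' (U the all-ones matrix): dδ = δ (dΓ) A⁻¹ and the
  analogous second-order identity, with A factored once.

The recursions are compiled with numba. Validation: agreement with
central finite differences at ~2e-8 (gradient) and ~3e-9 (Hessian)
relative error, and closed-form checks for m = 1.

## Fitting

`fit_ml` minimizes the nll over free working coordinates:

- default optimizer L-BFGS-B with the exact gradient (ftol 1e-12,
  gtol 1e-8, maxiter 1000), followed by a damped-Newton polish using the
  exact Hessian (Levenberg damping with backtracking, gtol 1e-9, up to 25
  steps);
- `optimizer="newton"`: scipy trust-exact with exact gradient and Hessian;
- `optimizer="lbfgs-fd"`: no supplied derivatives, for comparison only.

Evaluations where the likelihood is non-finite (overflowed means, or a
transition matrix pushed to a reducible limit during line search) return
a large penalty value instead of raising, so the optimizer can retreat.
A fit is reported converged only if the optimizer succeeded and the final
gradient norm is below 1e-5; non-convergence is recorded on the result,
never silently ignored.

Default starting values: λ quantiles of the positive counts at levels
(i − 0.5)/m, forced strictly increasing; transition matrix with 0.8 on
the diagonal and the remainder uniform. Fits are deterministic given the
data, starting values, and options.

Constraints are declared positionally on the working vector: the label
`FIXED` pins a coordinate at its starting value; coordinates sharing any
other label are constrained equal. Internally the full vector is an
affine function θ = S z + offset of the free coordinates, and derivatives
reduce exactly via g_z = S'g, H_z = S'HS. AIC = 2 nll + 2k and
BIC = 2 nll + k log T use k = number of free coordinates.

## Confidence intervals

**Wald (delta method).** Σ = J H⁻¹ J′, where H is the exact working-scale
Hessian at the optimum restricted to free coordinates and J the exact
Jacobian of the map from free working coordinates to the natural vector
(Γ row-major, λ, δ). If H is not positive definite the pseudo-inverse is
used and the report is flagged unreliable. Fixed parameters get exactly
zero standard error. Intervals are estimate ± z σ, not clipped to the
natural range (clipping is applied only for display rounding in CSV
output). Confidence level 1.0 degenerates to a large-but-finite z.

**Profile likelihood.** For a working coordinate v, the profile nll re-
optimizes all other coordinates with v pinned (warm-started from the
nearest cached solution). The interval ends solve
2(nll_p(v) − nll̂) = χ²₁(level), found by stepping outward in units of the
Wald standard error (0.5–8 SE) to bracket the root and then Brent's
method (xtol 1e-7 scaled). An unbracketed side (parameter near a
boundary) is reported as NaN, not invented. Natural-scale ends use the
monotone transform: exp for η; for a transition logit τ_ij, the row
transform evaluated with the other row logits at their re-optimized
values at the bound (for m > 2 this construction is flagged
`use_with_care` because the row elements are dependent). No profile
interval exists for δ — it is not a likelihood coordinate — and the
machinery reports it as unavailable rather than substituting a Wald
interval.

**Parametric bootstrap.** B series of length T are simulated from the
fitted model (stationary start) and refitted; the percentile interval
takes the α/2 and 1 − α/2 empirical quantiles per natural parameter.
Replicate labels are aligned before aggregation by sorting states on
ascending fitted mean (ties broken on descending initial probability).
Replicates whose simulated state path misses a state, or whose refit
fails to converge, are replaced, with causes counted in the report; the
attempt budget is 10·B, and exhausting it raises an error carrying the
attrition statistics. Child streams derive from `seed` via numpy
SeedSequence spawning keyed on `[seed, attempt]`, so results are
reproducible and independent of how many replicates were replaced before
a given attempt.

*Design decision — bootstrap refit starting values.* Bootstrap refits
start at the generating (fitted) parameters rather than at the
data-driven quantile starts (`refit_init="default"` restores the
latter). Short replicates with weakly separated states frequently send
data-driven starts into label-degenerate local optima whose both means
are high, which inflates the lower-state percentile interval; starting
at the generating model measures the sampling variability around the
model that generated the replicate, which is what the percentile
interval is meant to capture.

## Decoding and forecasting

Smoothing probabilities P(C_t = i | x_1..x_T) come from the scaled
forward and backward vectors; rows are renormalized and sum to one.
Local decoding takes the per-time argmax; the Viterbi path maximizes the
joint probability by a log-space dynamic program. All argmax tie-breaks
are deterministic toward the lower state index. The h-step forecast pmf
is P(X_{T+h} = x) = (φ_T Γ^h) p(x) with φ_T the filtered state
distribution; as h grows it converges to the stationary mixture
Σ δ_i p_i(x).

## Simulation and coverage studies

Built-in study models (the defaults of the coverage harness — these are
the study conditions, not tuning knobs):

- m = 2: Γ = ((0.95, 0.05), (0.15, 0.85)), λ = (1, 7)
- m = 3: Γ = ((0.95, 0.025, 0.025), (0.05, 0.90, 0.05),
  (0.075, 0.075, 0.85)), λ = (1, 4, 7)
- m = 4: Γ = ((0.85, 0.05, 0.05, 0.05), (0.05, 0.85, 0.05, 0.05),
  (0.05, 0.10, 0.80, 0.05), (0.034, 0.033, 0.033, 0.90)), λ = (1, 5, 9, 13)

A coverage study simulates M replicates of length T from the truth
(canonicalized to ascending λ), refits each from the default starting
values, builds the requested intervals (Wald / profile / bootstrap), and
reports the fraction containing the truth per parameter. Fitted labels
are aligned to the truth's ordering before checking containment.
Replicates are replaced — with counted causes — when the state path
misses a state (the validity filter, optional), the refit fails, or a
requested profile bound cannot be bracketed. Replicate seeds derive from
`[seed, attempt]` as in the bootstrap. For m = 2, profile intervals for
the diagonal transition probabilities use the row complement
γ_ii = 1 − γ_ij.

## Problem sizes exercised

- TYT series: T = 87, m = 2 (reference estimates reproduced to 1e-6).
- Coverage: M = 500, T = 2000, m = 2 for the Wald study (≈15 s after JIT
  warm-up); scaled-down M = 50 smoke runs for all three methods.
- Likelihood evaluation validated up to T = 2×10^5 in the test suite and
  designed for 10^6.

## Limitations

- Profile natural-scale bounds for transition probabilities with m > 2
  are flagged `use_with_care` (row dependence; see above).
- The percentile bootstrap interval is seed-sensitive at the second
  decimal for B = 1000 on an 87-observation series; reported widths can
  differ by ~0.1 across seeds.
- Full-scale three-method coverage at M = 1000, T = 2000 with B = 1000
  bootstrap replicates is computationally heavy (≈10^7 refits); the test
  suite verifies the coverage band at reduced scale instead.
- Observed (non-stationary) initial-distribution estimation is supported
  (`free_init`), but all reference analyses use the stationary start.
- The likelihood surface is multimodal; the default single-start fit is
  validated by a multistart stability test on the reference series, but
  arbitrary data may require user-supplied starts.
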