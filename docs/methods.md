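# Methods

## Model and identification

`pairdif` fits the multi-group two-parameter logistic (2PL) model: for
respondent *i* of group *s* ∈ {1..S} and item *j* ∈ {1..J},
P(y=1|θ) = expit(a_js θ − b_js) with slope a_js and negative intercept
b_js, and latent trait θ ~ N(μ_s, σ_s²) per group (impact).  The marginal
likelihood integrates θ out; products run over observed responses only,
so missing-at-random sparsity (as in adaptive tests) is handled
naturally.  Group 1 is pinned at μ=0, σ²=1; all other impact parameters
are free.  Slopes are unconstrained reals — no positivity bound is
imposed; the neutral initialization at a=1 keeps iterates in the positive
regime in practice.

With every item parameter free per group and no penalty, the impact
parameters of groups 2..S are *not identified*: the likelihood depends on
group s only through (a_js σ_s, a_js μ_s − b_js).  The pairwise penalty
(or any cross-group tie) restores identification.  Consequences adopted
here:

* At λ=0 the solver drops the ADMM quadratic coupling entirely and runs
  plain EM; a proximal term would otherwise select an arbitrary point on
  the flat ridge.
* Unpenalized parameter estimates for s ≥ 2 should be interpreted via the
  identified combinations only.

## Penalty

The group-pairwise truncated L1 penalty (TLP) is
λ Σ_j Σ_{m<n} [min(|a_jm − a_jn|, τ) + min(|b_jm − b_jn|, τ)].
One common (λ, τ) covers both parameter kinds: separate tuning would add
a third grid dimension, and the TLP's approximation of the
scale-invariant L0 penalty makes a common value defensible.  λ is applied
on the total log-likelihood scale; user-facing interfaces take a
per-respondent value λ_user with λ = λ_user · N, so that comparable
shrinkage strengths can be quoted across sample sizes.  Differences are
always oriented param(m) − param(n) for m < n; one fixed sign convention
for differences, duals and reports prevents sign errors in the dual
update.

## Algorithm

Outer DC loop: the TLP is majorized by a weighted L1 term with binary
weight w = 1{|δ| ≤ τ} recomputed from the current difference parameters
at each outer iteration (the boundary |δ| = τ keeps w = 1, so the τ = ∞
LP limit is exact).  Inner ADMM loop (scaled duals u, penalty parameter
ρ):

1. Θ-update: one EM cycle — E-step posteriors over Gauss–Hermite nodes,
   closed-form impact update (posterior mean / central second moment per
   group, group 1 fixed), then one L-BFGS-B pass per item block (2S
   parameters) on the posterior-weighted Bernoulli loss plus
   (ρ/2)‖difference − δ + u‖².  A block that fails its line search keeps
   its previous values with a warning.
2. δ-update: soft-threshold of (difference + u) at wλ/ρ — closed form;
   pairs with w = 0 pass through unshrunk.
3. u-update: u ← u + difference − δ.

Convergence requires every entry of {a, b, μ, σ², δ} to move less than
`tol` (strict), with the outer weights stable; duals are auxiliary and
excluded, and primal feasibility max|difference − δ| is reported
separately.  The Θ-update is deliberately inexact (a single EM cycle,
L-BFGS capped at 20 iterations per block): exact inner minimization per
ADMM step would waste work, and the fixed point is unchanged.

Initialization: neutral start (a = 1, b_j = −logit of the pooled
proportion correct, no impact, δ = u = 0, w = 1), then one full run with
τ = ∞ — the convex LP problem — whose solution warm-starts the TLP fit.
When τ = ∞ is itself requested, the neutral start is used directly so the
LP is solved exactly once.

Defaults: tol = 1e-4, max 20 outer / 500 inner iterations, K = 21
quadrature nodes (Gauss–Hermite with a per-group affine map; weights
renormalized to sum to one), ρ = N/10.  ρ must be commensurate with
likelihood curvature, which grows with N; it mainly affects the
convergence rate, not the solution.  Group variances are floored at 1e-4
to prevent collapse in very small groups.  All posterior computation is
in log space with per-row max subtraction.

## Post-processing and model selection

Soft-thresholding yields exact zeros, but transitivity is not enforced
during iteration: δ(1,2) = δ(2,3) = 0 can coexist with a tiny nonzero
δ(1,3).  After convergence, groups connected by zero differences
(|δ| < 1e-6, the numerical-zero tolerance that survives cluster averaging
and text round-trips) are merged per (item, kind) with a union-find
structure with path compression, and every within-cluster δ is reset to
exactly 0.  A pair is flagged DIF on an item iff, after this repair, the
corresponding δ is nonzero; the any-kind flag is the OR over kinds.

BIC = −2ℓ + log(N)(p_a + p_b + 2(S−1)), where p_a and p_b are the
numbers of distinct slope and intercept parameters (cluster counts summed
over items).  The 2(S−1) impact terms are constant across candidates but
keep reported values self-consistent.  Because the ADMM Θ-update drives
within-cluster differences to zero without enforcing exact equality, each
cluster's parameter is replaced by the group-size-weighted mean of its
members before the BIC's likelihood is evaluated — the counted model and
the scored likelihood then describe the same object.  Grid search spans
λ_user ∈ {0.0025, …, 0.08} × τ ∈ {0.05, …, 0.5} by default, shares a
single LP warm start (run at the median λ of the grid — the LP pass only
supplies starting values, so its exact λ is not critical), and breaks
BIC ties toward larger λ,
then larger τ (the more parsimonious candidate).

## Synthetic data

The generator emulates a multi-group DIF simulation design: base item
parameters drawn once and shared across groups (slopes LogNormal(0,
0.25), intercepts N(0, 1)), a leading block of DIF items receiving
per-group offsets (default alternating 0, +d, −d, +d, … across groups,
with d = 0.5 for slopes and 1.0 for intercepts; full offset matrices may
be supplied), impact as group means (default: group 1 at 0, the rest
evenly spaced in [−0.5, 0.5]) with a common variance, optional uniform
MCAR missingness or a fixed number of items per respondent (emulating
design-based sparsity), and deterministic output given a seed.  Ground
truth is stored on the identified metric (a common generating variance is
absorbed into slopes and impact means).  Unbalanced designs use
geometrically decaying group shares as the documented fallback scheme.

What the generator does *not* emulate: guessing/slipping, multidimensional
traits, local dependence between items (e.g. subtasks nested in a
passage), nonignorable missingness, and polytomous responses.  Passing
the seeded detection suites therefore shows that the estimator recovers
the generating 2PL structure under its own assumptions, not that real
assessment data meet those assumptions.

Detection quality is scored pairwise: TPR = flagged ∧ true / true and
FPR = flagged ∧ ¬true / ¬true over all (item, pair) cells per parameter
kind, with empty denominators reported as missing rather than zero.

## Study conditions used by the seeded suites

The balanced detection suite runs S=4 groups × 500 respondents, J=20
items with 4 leading DIF items (intercept offsets ±1.0, slope offsets
±0.5), 10 replications, a reduced 3λ × 2τ grid
({0.005, 0.01, 0.02} × {0.1, 0.3}) and tol = 1e-3 — a deliberately
scaled-down analog of a full simulation study, sized so the entire suite
runs in minutes on one CPU; the acceptance script uses the same designs
with 5 replications.  The null suite uses S=3 × 500, J=15, impact means
(0, −0.3, 0.3) and no DIF.  Under these conditions intercept DIF is
detected essentially perfectly while slope DIF of magnitude 0.5 is mostly
absorbed into group trait variances — slope differences are
systematically harder to detect at these sample sizes, a pattern the
per-kind TPRs make explicit.

## Numerical choices and edge cases

* Quadrature: probabilists' Gauss–Hermite; nodes strictly increasing,
  weights positive and normalized per group.  K=21 suffices for the
  smooth 2PL integrands; K=49 matches dense-grid integration to ~1e-8.
* The δ-update at λ = 0 is the identity and the subsequent dual update
  returns exact floating-point zeros, so δ tracks the raw differences
  bit-exactly in the unpenalized fit.
* A finite-τ fit takes an LP warm-start pass first, while a τ = ∞ fit
  *is* that LP pass; the two default paths therefore end one EM cycle
  apart (within tol).  From a shared warm start the paths are identical
  bit-for-bit whenever τ exceeds every |δ| encountered.
* Items or respondents with no observed responses are rejected at
  construction; observed entries must be exactly 0 or 1, with offending
  cells named in the error.
* Degenerate tiny groups: variances clamp at the floor rather than
  collapsing; an empty group is rejected by the data container.

## Known limitations

* Unidimensional latent trait only; quadrature-based EM does not scale to
  multidimensional traits.
* Slope-DIF sensitivity is intrinsically low at moderate sample sizes,
  and slope effects can be absorbed by group variances.
* BIC evaluates cluster-averaged parameters rather than refitting under
  the implied equality constraints; the difference is O(feasibility gap)
  but nonzero.
* The DC majorization guarantees a stationary point of the surrogate
  sequence, not a global optimum; the LP warm start is the device that
  selects a good basin.
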