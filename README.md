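# pairdif

Reference-group-free detection of differential item functioning (DIF)
across many groups, for binary (2PL) item response data.

## The problem

An item of a test shows DIF when respondents with the *same* latent
ability but from different groups have different probabilities of
answering it correctly.  Classical regularized DIF detection designates
one group as the reference and shrinks every other group toward it, which
is inequitable, blind to DIF among the focal groups, and biased by lasso
over-shrinkage.  `pairdif` instead penalizes the item-parameter
differences between **every pair of groups** with a truncated L1 penalty
(TLP), so all groups are treated symmetrically and large real differences
are not shrunk.  This matters most when groups are numerous and small —
for example intersectional subgroups (native language × gender) in
large-scale assessments.

## Model

For respondent *i* of group *s* and item *j*,

    P(y_ij = 1 | θ_i) = expit(a_js θ_i − b_js),     θ_i ~ N(μ_s, σ_s²),

with group 1 fixed at N(0, 1) for identification ("impact" = genuine
group differences in the trait distribution, distinct from DIF).  The fit
minimizes the penalized negative log marginal likelihood

    −ℓ(Θ) + λ Σ_j Σ_{m<n} [ min(|a_jm − a_jn|, τ) + min(|b_jm − b_jn|, τ) ],

a group-pairwise TLP with common (λ, τ) for both parameter kinds.  The
TLP behaves like the lasso below the truncation point τ (shrinking small
differences to exactly zero) and is constant above it (leaving genuine
DIF unbiased); as τ → ∞ it becomes the plain lasso (LP).

The nonconvex penalty is solved by difference-of-convex (DC) majorization
around binary weights `w = 1{|δ| ≤ τ}`, with an inner ADMM whose
difference-parameter update is a closed-form soft-threshold and whose
model-parameter update is one EM cycle (Gauss–Hermite quadrature E-step,
closed-form impact update, per-item L-BFGS).  The solver is warm-started
from a pure-LP run.  After convergence, groups linked by zero differences
are collapsed with a union-find structure (path compression) to restore
exact transitivity; a pair (m, n) is DIF-free on item *j* iff both of its
difference parameters are zero.  The tuning pair (λ, τ) is selected by
BIC = −2ℓ + log(N) · (p_a + p_b + 2(S−1)), where p_a, p_b count the
distinct slope and intercept parameters after collapsing.

## Worked example

Simulate a balanced 4-group study (500 respondents per group, 20 items,
the first 4 carrying DIF with intercept offsets ±1.0 and slope offsets
±0.5) and recover the DIF structure:

```python
from pairdif import GroupPairwise2PL, SimulationConfig, simulate_dataset, tpr_fpr

cfg = SimulationConfig(S=4, group_sizes=[500] * 4, J=20, n_dif_items=4,
                       dif_a=0.5, dif_b=1.0, seed=1001)
sim = simulate_dataset(cfg)
model = GroupPairwise2PL(sim.data)
res = model.fit_select(lam_grid=[0.005, 0.01, 0.02], tau_grid=[0.1, 0.3],
                       tol=1e-3)
print(res.summary())
```

```
Group-pairwise TLP DIF detection (2PL)
======================================================
Respondents: 2000   Items: 20   Groups: 4
lam = 0.005 (per respondent)   tau = 0.1   rho = 200
log-likelihood = -22477.971   BIC = 45366.391
distinct parameters: 20 slopes, 28 intercepts
converged: True (outer 2, inner 128, feasibility gap 1.46e-04)
items with DIF on any pair: 4 / 20

Impact (latent trait by group):
  group      1: mu = +0.000, sigma2 = 1.000
  group      2: mu = -0.563, sigma2 = 1.064
  group      3: mu = +0.106, sigma2 = 0.708
  group      4: mu = +0.619, sigma2 = 1.170

Flagged (item, group pair) cells: 20
  item1: 5 pair(s)
  item2: 5 pair(s)
  item3: 5 pair(s)
  item4: 5 pair(s)
```

The BIC-selected model flags exactly the four generating DIF items, and
for each of them exactly the five group pairs whose intercepts truly
differ (pair (2, 4) shares the same offset and is correctly left
unflagged).  Scoring against the generating truth:

```python
print(tpr_fpr(res.dif.flags_a, res.dif.flags_b,
              sim.true_flags_a, sim.true_flags_b))
# {'tpr_a': 0.0, 'fpr_a': 0.0, 'tpr_b': 1.0, 'fpr_b': 0.0}
```

Intercept DIF is recovered perfectly; slope DIF of this magnitude is
largely absorbed into the group trait variances and is much harder to
detect — the known asymmetry between the two parameter kinds.

`res.item_table()`, `res.flag_table()` and `res.impact_table()` expose
the estimates as DataFrames; `res.save(out_dir)` writes them together
with a metadata JSON.

## Command line

```sh
pairdif simulate --config examples/balanced_s4.yaml --out sim/
pairdif fit --responses sim/responses.csv --group-col group \
            --lam-grid 0.005,0.01,0.02 --tau-grid 0.1,0.3 --out fit/
pairdif evaluate --flags fit/dif_flags.csv --truth sim/truth.csv
```

Input is a wide CSV (one row per respondent, one column per item, a group
column, missing entries as `NA`); a long-format reader
(`pairdif.read_responses_long`) covers sparse adaptive-test data.

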