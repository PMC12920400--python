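# Methods

## Problem and identification

We observe n iid triples (Xᵢ, tᵢ, yᵢ): covariates, one received treatment
from a finite set 𝒯, and the outcome under that treatment.  The goal is a
policy s: 𝒳 → 𝒯 optimizing the population mean outcome.  Identification
relies on the two standard assumptions of causal inference from
observational data: conditional exchangeability (potential outcomes are
independent of the assigned treatment given X) and positivity (every
treatment has positive probability for every covariate value).  Under
them the value of any policy can be estimated from observational rows via
inverse propensity weighting (IPW), arm-wise outcome regression (the
direct method, DM), or their doubly robust (DR/AIPW) combination, which
is consistent when either nuisance model is.

The per-treatment AIPW score implemented here is

    ψ̂_t(zᵢ) = μ̂_t(xᵢ) + 1{tᵢ = t} (yᵢ − μ̂_t(xᵢ)) / max(p̂(t|xᵢ), c)

with clip floor c (default 0.01) guarding the IPW division.  Some DR
formulations write a candidate or baseline policy inside the indicator,
which does not yield a policy-independent score table; the standard AIPW
score above makes the policy value (1/n)Σᵢ Σ_t 1{s(xᵢ)=t} ψ̂_t(zᵢ) well
defined for every candidate policy, and reduces exactly to IPW when
μ̂ ≡ 0 and to DM when the correction term is dropped.

For smaller-is-better outcomes every score is negated before
optimization (ψ̃ = −ψ̂), so the trainer always maximizes.

## Network and training MIP

The policy is a depth-L feed-forward network with binary indicator
activations σ(z) = 1[z ≥ 0] on hidden units and an affine score per
treatment at the output; inference prescribes the argmax score, ties to
the lowest treatment index.  Training chooses weights α, biases β (both in
[α_L, α_U], default [−1, 1]) and per-row activations jointly:

* hidden unit on  ⇒ pre-activation ≥ ε (default 10⁻⁴),
* hidden unit off ⇒ pre-activation ≤ −ε/2,
* output unit one-hot per row (Σ_t h_{i,t} = 1), with the selected
  treatment's score ≥ ε and all others ≤ 0,
* products α·h from the second layer on replaced by auxiliary variables
  with exact big-M linearizations,
* objective: mean selected score, minus λ₀ times the number of nonzero
  weights (binary use-indicators) and λ₁ times the ℓ₁ norm of the
  weights (nonnegative split variables); an optional baseline policy
  subtracts a constant so the objective reads as an advantage.

Numerical choices:

* **Off-margin −ε/2.**  A pre-activation of exactly 0 is "on" for the
  inference indicator but would be admissible as "off" in the plain
  big-M disjunction, and LP-vertex solutions actively exploit that
  boundary.  Forcing the off side strictly below zero keeps every
  training pre-activation out of (−ε/2, ε), so the returned network's
  forward pass reproduces the solver's activations row-for-row.  Unseen
  inputs landing in the excluded band simply activate, consistent with
  σ.  The output layer keeps the plain (≥ ε / ≤ 0) disjunction because
  argmax inference is insensitive to the zero boundary there.
* **Big-M constants.**  Data-driven and per-row on the input layer,
  M_i = max(|α_L|,|α_U|)(Σ_d |X_{i,d}| + 1) + 1, and
  K·max|α| + max|α| + 1 on deeper layers.  Per-row constants tighten the
  LP relaxation substantially (on a 100-row width-3 instance they cut
  HiGHS solve time from beyond 60 s to ~25 s).
* **Symmetry breaking** (optional, off by default): ordering the hidden
  biases within a layer removes the K! relabeling symmetry without
  changing the optimum.
* **Integral weights** (optional): declares weights and biases integer
  within their bounds, which restricts the search to a finite grid; used
  by the exhaustive-enumeration oracle tests.
* **Solver.**  HiGHS via `scipy.optimize.milp`, single-threaded and
  deterministic for a fixed model.  Termination at a relative gap
  tolerance or a wall-clock limit; the incumbent and its gap are always
  reported.  Identical incumbents across solver versions are not
  promised, only objective values within the gap tolerance.
* **Infeasibility** cannot arise from the one-treatment constraint: a
  constant policy (all output weight mass on one arm via its bias) is
  always feasible; an infeasible model therefore indicates a
  configuration error (e.g. ε ≥ M) and is reported as such.

The exhaustive oracle `brute_force_train` enumerates every weight/bias
assignment on a finite grid, scores it through the inference forward
pass, and is entirely independent of the MIP path; on tiny instances
(n ≤ 6, K = 1, grid {−1,0,1}) the MIP optimum matches it exactly.

## Nuisance estimation

`fit_nuisance` selects the propensity model by K-fold cross-validated
classification accuracy and the outcome model by K-fold cross-validated
RMSE, fit per arm on that arm's subpopulation (regress-and-compare
partition), then refits the winners on the full training part.  Default
candidates: logistic regression and a depth-4 decision tree for the
propensity, linear regression and lasso for the outcome, 10 folds.  Nuisance models are fit on the training fold only;
cross-fitting is not performed.  Propensity rows sum to one before
clipping; arms with zero observations raise a positivity error.

## Synthetic-study generator

Covariates are iid standard normal; potential outcomes follow

    Y(t) = η(X) + ½(2t−1)κ(X) + ε,    ε ~ N(0, 0.01)

with three designs: (1) F=2, η = x₁/2 + x₂, κ = x₁/2; (2) F=10,
η = (x₁+x₂)/2 + x₃+…+x₆, κ = Σ_{f≤2} 1{x_f>0}x_f; (3) F=20,
η = (x₁+…+x₄)/2 + x₅+…+x₈, κ = Σ_{f≤4} 1{x_f>0}x_f.  N(0, 0.01) is read
as variance 0.01 (sd 0.1); a flag reinterprets it as an sd.  Treatments
are conditionally randomized: each individual receives their realized
optimal arm with probability p ∈ (0,1) and the other arm otherwise.

By default noise is drawn **independently per arm**.  Under a single
shared draw, designs 2 and 3 have exact ties (κ = 0) on regions of
probability ¼ and 1/16 respectively, leaving "the optimal arm" — and
hence the correct-assignment probability — ill-defined there.
Independent draws make the realized optimum almost surely unique and
put the treat-everyone policy's out-of-sample performance at ~85%
(design 2) and ~96% (design 3) on large test sets.  Both noise modes are
implemented.

Decile binarization uses theoretical N(0,1) decile boundaries with
left-open/right-closed bins (a value exactly on a boundary falls in the
lower bin; 0 lands in decile 5); the adapted (thermometer) transform
propagates the hot decile rightward.  These transforms serve tree-style
baselines and are not used by the network itself.

What the generator does **not** emulate: non-Gaussian or correlated
covariates, more than two arms, missing data, or outcome models beyond
the additive form above — so green tests here say nothing about, e.g.,
confounding structures outside conditional exchangeability.

## Evaluation harness

OOSP is the percentage of test rows prescribed their realized-optimal
arm; policy RMSE is the root-mean-square gap between the attained and the
best attainable outcome.  `cross_validate` trains one network per fold
(nuisance models refit per training part) and values it on held-out rows
with held-out scores.  `paired_policy_test` is a two-sided paired t test
on per-fold values (per-fold pairing is the default experimental unit;
zero-variance differences are handled explicitly).  Feature importance
for a single-hidden-layer network is the mean absolute input weight per
feature; rank tables average descending ranks across folds (zero-weight
features share the worst rank, tied ranks share their mean position),
optionally collapse binarized column groups to their best member rank,
normalize to [0,1] and report 1 − rank so larger is more important.

## Problem sizes used in the shipped tests

The test suite runs the full pipeline at desk scale: tiny
oracle-equivalence instances (n ≤ 6); a design-1 study with n_train=100,
width 3, a 180 s solver limit and a 5% gap tolerance (reaching ~90% OOSP
on 10,000 test points); estimator-sanity checks over 200 replicates of
n=500; and a sample-size trend comparison at n=50 versus n=500 with
2-minute solver limits.

## Known limitations

* **Scale.**  Training is exact but combinatorial: n·(K + |T|) binary
  variables.  HiGHS handles n ≈ 100 at width 3 in seconds-to-minutes,
  but at n = 500 it can fail to leave the root node within minutes-scale
  limits, returning only a trivial feasibility-pump incumbent; the
  sample-size trend test documents this regime honestly rather than
  masking it.  Commercial solvers with stronger heuristics and longer
  budgets are advisable for n in the hundreds.
* The formulation excludes training pre-activations in (−ε/2, ε); new
  data in that band activates by convention.
* IPW/DR scores inherit clip-floor bias when propensity estimates are
  degenerate (e.g. overfit tree leaves); raising the floor trades
  variance for bias.
* Tie-breaking (argmax to the lowest treatment index) and the
  off-margin are this package's conventions; other implementations of
  the same model class may differ on boundary cases.
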