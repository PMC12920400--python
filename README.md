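# pnn — prescriptive neural networks

`pnn` learns **treatment policies from observational data** by training
shallow 0-1 activation neural networks with mixed-integer programming
(MIP).  It is aimed at medium-data prescriptive problems — think a few
hundred patients with covariates, a recorded treatment, and an outcome —
where randomized experiments are unavailable, stochastic-gradient training
is unreliable, and the policy must be auditable.

## The model

A policy network maps covariates X ∈ ℝ^F to one of |T| treatments through
K hidden units with the indicator activation σ(z) = 1[z ≥ 0]:

    h_k   = 1[ α_k · X + β_k ≥ 0 ],            k = 1..K
    s(X)  = argmax_t ( α_t · h + β_t )

Because the counterfactual outcome of an unassigned treatment is never
observed, the training objective is a counterfactually estimated policy
value.  With per-individual, per-treatment scores ψ̂_t(z_i) — inverse
propensity weighting (IPW), the direct method (DM), or the doubly robust
AIPW combination (DR)

    ψ̂_t(z_i) = μ̂_t(x_i) + 1{t_i = t} · (y_i − μ̂_t(x_i)) / p̂(t | x_i),

training solves

    max_θ  (1/n) Σ_i Σ_t  h_{i,t} · ψ̂_t(z_i)  −  λ₀‖α‖₀  −  λ₁‖α‖₁

over both the network parameters θ = (α, β) and the per-row unit
activations h, which are tied together exactly by big-M indicator
constraints and linearized bilinear products, and solved with the HiGHS
branch-and-bound solver.  Exactly one treatment is assigned per row.  The
learned weights are directly inspectable: features with large absolute
input weights drive the policy.

The package also ships the standard synthetic benchmark for such methods:
Gaussian covariates with potential outcomes
Y(t) = η(X) + ½(2t−1)κ(X) + ε across three designs of increasing
dimension, conditionally randomized assignment with a tunable probability
of correct treatment, decile/thermometer binarization transforms, and an
evaluation harness (out-of-sample performance, policy regret, paired
tests, feature rankings).

## Worked example

```sh
pnn simulate --design 1 --n-train 100 --n-test 10000 --p 0.5 --seed 7 --out-dir study
pnn estimate --data study/train.csv --out study/table.csv --seed 7
pnn train    --data study/train.csv --table study/table.csv \
             --width 3 --objective dr --time-limit 300 --gap 0.05 \
             --seed 7 --symmetry-breaking --out study/model.json
pnn predict  --model study/model.json --data study/test.csv --out study/assignments.csv
pnn evaluate --model study/model.json --test study/test.csv \
             --sidecar study/test_sidecar.csv --out study/report.csv
```

Training runs up to its 300 s limit and keeps the best incumbent; the
evaluate step then prints, for this seed:

```
           model  oosp     rmse  n_test
study/model.json 91.14 0.038037   10000
```

meaning the learned width-3 policy assigns 91.1% of 10,000 unseen
individuals their true optimal treatment (`oosp`), with a root-mean-square
outcome regret of 0.038 against the best attainable outcome per person
(`rmse`).  The training solve log (`study/model.solvelog.json`) records
the incumbent objective (0.1218), the solver's proven bound (0.1294), the
optimality gap (6.2%) and wall time.  The same pipeline is available as library calls
(`pnn.generate_dataset`, `pnn.fit_nuisance`, `pnn.dr_score_table`,
`pnn.train_pnn`, `pnn.forward_policy`, `pnn.oosp`).

`pnn experiment` reproduces the full simulated-study grid (designs ×
assignment probabilities × replicates) at any scale and writes a tidy
results table.

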