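# powerhazard

Estimation and hypothesis testing for the **lifetime performance index**
`C_L = (mean − L_X) / sd` of products whose lifetimes follow the
two-parameter power-hazard distribution (hazard `h(x) = α·x^β`), observed
under **progressive type-II censoring**: `n` units on test, `m` failures
observed, `R_i` surviving units withdrawn at the i-th failure.

Features:

- closed-form distribution functions, moments, quantiles and i.i.d. sampling
  for the power-hazard model (exponential at `β = 0`, Rayleigh at `β = 1`);
- censoring schemes I/II/III (all withdrawals at the first / middle / last
  failure), an exact progressive-censoring sampler plus a literal
  withdrawal-process simulator used to cross-validate it, and a plain-text
  sample file format;
- the index `C_L`, its scale-free link to the conforming rate
  `P(X ≥ L_X)`, and table generation;
- ML and conjugate-gamma Bayes estimation of the scale `α` and of `C_L`
  (shape `β` known), exact chi-square pivotal one-sided lower
  confidence/credible bounds, and the one-sided capability test
  `H0: C_L ≤ c` vs `H1: C_L > c`;
- a Monte-Carlo study engine scoring MSE and empirical coverage per design
  cell, bit-reproducible from a single master seed;
- the classical censored ball-bearing dataset (`n = 23`, `m = 18`) bundled
  in `powerhazard.datasets`.

Two conventions are exposed for the ML lower bound (and mirrored in
`assess`/the CLI): `pivotal` (default) uses the exact pivot
`2αW/(β+1) ~ χ²(2m)` and attains nominal coverage; `reported` is the
point-estimate rewrite found in published worked examples, which carries an
extra `(β+1)` inside the chi-square factor and under-covers for `β > 0`.
Similarly, `lower_bound_bayes` is the published point-estimate rewrite while
`lower_bound_bayes_exact` is the exact posterior quantile.

## CLI

The console script is `powerhazard` (equivalently
`python -m powerhazard.cli`). Sample files are plain text with a
`# n=<int> m=<int> [beta=<float>]` header comment, a `time,removed` header
row, and one `time,removed` row per observed failure.

```sh
# simulate a censored sample (scheme I: all withdrawals at the first failure)
powerhazard simulate --n 25 --m 15 --scheme I --alpha 1.092 --beta 0.332 \
    --seed 1 --output sample.csv

# point estimates (add --prior-a/--prior-b for Bayes)
powerhazard fit --input sample.csv --l-x 0.022

# capability test at level 95%
powerhazard test --input sample.csv --l-x 0.022 --c 0.9 --delta 0.05 \
    --method ml

# conforming-rate table over an index grid
powerhazard rate-table --beta 0.332

# Monte-Carlo study from a YAML config
powerhazard mc-study --config study.yaml --format csv --output report.csv
```

A study config is a flat YAML file:

```yaml
true_alpha: 1.092
true_beta: 0.332
l_x: 0.022
delta: 0.05
reps: 1000
seed: 0
cells:
  - 25,15,I
  - 90,70,I
priors:
  - 1,2
  - 2,3
```

Exit codes: 0 success, 1 computation/domain error, 2 usage or I/O error.

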