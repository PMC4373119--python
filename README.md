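# geostar

Bayesian **geoadditive logistic regression** for individual-level survey
data, built for under-five mortality risk-factor analysis and small-area
risk mapping of the kind done with Demographic and Health Survey (DHS)
data.

## The model

For child *i* with death indicator *y<sub>i</sub>* ∈ {0, 1},

  *y<sub>i</sub>* ~ Bernoulli(*π<sub>i</sub>*),
  logit(*π<sub>i</sub>*) = *η<sub>i</sub>* = *α*₀ + **w**′<sub>i</sub>**α** + Σ<sub>j</sub> *f<sub>j</sub>*(*x<sub>ij</sub>*) + *f*<sub>str</sub>(*s<sub>i</sub>*) + *f*<sub>unstr</sub>(*s<sub>i</sub>*)

a structured additive (STAR / geoadditive) predictor with

- **fixed effects** **α** of reference-coded categorical covariates, with a
  diffuse mean-zero Gaussian prior;
- **P-spline smooths** *f<sub>j</sub>* of continuous covariates: cubic
  B-splines on 20 equidistant segments (*d* = *s* + *l* basis functions),
  with a second-order random-walk prior on the coefficients,
  p(ξ<sub>j</sub> | τ²<sub>j</sub>) ∝ exp(−ξ′<sub>j</sub>K<sub>j</sub>ξ<sub>j</sub> / 2τ²<sub>j</sub>),
  K<sub>j</sub> = D′D the difference-penalty matrix;
- a **structured spatial effect** *f*<sub>str</sub> over regions *s* ∈
  {1, …, S}: an intrinsic Gaussian Markov random field whose conditional
  prior is N(mean of neighbouring regions, τ²<sub>str</sub>/N<sub>s</sub>),
  on an adjacency or k-nearest-neighbour region graph;
- an **unstructured spatial effect** *f*<sub>unstr</sub>(s) ~ N(0,
  τ²<sub>unstr</sub>) for non-spatial region heterogeneity;
- **inverse-Gamma hyperpriors** IG(a, b), a = b = 0.001, on every variance.

Estimation is fully Bayesian: a Polya-Gamma-augmented Gibbs sampler in
which every coefficient block has an exact Gaussian full conditional and
every variance an exact inverse-Gamma full conditional (default chain:
10,000 iterations, 1,000 burn-in, thinning 50 → 180 retained draws).

A **screening stage** (cross-tabulations of mortality against each factor
with Pearson chi-square tests) and a **synthetic survey generator** with
known ground truth round out the pipeline; restricted DHS microdata never
needs to be bundled.

## Worked example

```python
import numpy as np
from geostar import GeoadditiveLogit, SmoothSpec, default_spec, simulate_survey

spec = default_spec()                       # 11 regions, ~2,000 children
table, graph, truth = simulate_survey(spec, np.random.default_rng(42))
model = GeoadditiveLogit.from_table(
    table, spec.factor_specs(),
    [SmoothSpec("mother_age"), SmoothSpec("family_size")], graph)
res = model.fit(iterations=3000, burnin=1000, thin=10, seed=7)
print(res.summary())
```

prints

```
Geoadditive logistic regression — posterior summary
retained draws: 200

parameter                     estimate      OR    2.5%   97.5%
intercept                       -2.032   0.131   0.095   0.177
residence[rural]                 0.374   1.453   1.058   2.001
wealth[middle]                  -0.142   0.868   0.642   1.147
wealth[richest]                 -0.226   0.797   0.597   1.143

tau2:mother_age                 0.0069  [0.0004, 0.0342]
tau2:family_size                0.0048  [0.0005, 0.0221]
tau2_str                        0.0565  [0.0010, 0.2717]
tau2_unstr                      0.0175  [0.0008, 0.0805]
```

Each `estimate` is a posterior mean on the log-odds scale; `OR` is its
exponential with an equal-tailed 95% credible interval. Rural residence
raises the odds of dying before age five by ~45% here (true simulated
effect: +0.30 log-odds, OR 1.35, inside the interval); wealth lowers them
(true effects −0.20, −0.50). `res.smooth_curve("mother_age")` returns the
posterior mean curve with 95% bands, and `res.region_risk()` the per-region
predicted death probability at reference covariates with its posterior SD:

```
 region  mean_prob       sd
      1   0.102842 0.023224
      2   0.092344 0.023122
      3   0.119002 0.025825
```

The same pipeline is scriptable from a shell: `geostar simulate`,
`geostar screen`, `geostar make-graph`, `geostar fit`, `geostar summarize`
(see `geostar --help`).

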