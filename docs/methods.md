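# Methods

## Model

`geostar` fits a structured additive (geoadditive) logistic regression to
individual-level survey records. The death indicator of child *i* in
region *s<sub>i</sub>* is Bernoulli(π<sub>i</sub>) with

    logit(π_i) = α0 + w_i' α + Σ_j f_j(x_ij) + f_str(s_i) + f_unstr(s_i).

The model assumes (i) conditional independence of outcomes given the
predictor, (ii) additivity of covariate effects on the log-odds scale,
(iii) smoothness of the continuous-covariate effects, and (iv) Markovian
spatial dependence of region effects on their graph neighbours. Survey
design features (stratification, sampling weights, cluster-level
correlation below the region) are not modelled; a weight column is read
and carried but unused.

### Priors

- Fixed effects (intercept included): independent N(0, 10⁶). A proper but
  very diffuse prior, so every full conditional is proper.
- Smooths: f_j = Σ_m ξ_jm B_m with B-splines of degree *l* on *s*
  equidistant segments (d = s + l basis functions; knots extended *l*
  spacings beyond each boundary by spacing repetition, not multiplicity).
  Random-walk prior of order 1 or 2 on ξ_j — the stochastic analogue of a
  difference penalty: p(ξ_j | τ_j²) ∝ exp(−ξ_j'K_jξ_j / 2τ_j²) with
  K_j = D'D of rank d − order. RW1 leaves constants unpenalised, RW2
  constants and linear trends.
- Structured spatial effect: intrinsic GMRF with conditional prior
  N((1/N_s) Σ_{s'∈∂s} f_str(s'), τ_str²/N_s); joint quadratic form given
  by the graph structure matrix (diagonal N_s, off-diagonal −1 for
  neighbours, rank S − #components).
- Unstructured effect: f_unstr(s) iid N(0, τ_unstr²).
- All variances: inverse-Gamma IG(a, b) with a = b = 0.001 ("highly
  dispersed"), overridable per config.

### Sampler

Each Bernoulli observation is augmented with a Polya-Gamma auxiliary
ω_i ~ PG(1, η_i), after which every coefficient block has the exact
Gaussian full conditional with precision B'ΩB + K/τ² and every variance
the exact inverse-Gamma full conditional IG(a + rank(K)/2, b + ξ'Kξ/2).
One systematic-scan sweep updates: auxiliaries → fixed block → each
smooth block → structured spatial block → unstructured block → each
variance. Defaults follow the standard configuration for this model
class: 10,000 iterations, 1,000 burn-in, thinning 50 (180 retained
draws).

The PG(1, z) sampler is implemented in-package from the
infinite-sum-of-gammas representation, truncated at 200 terms with an
analytic tail-mean correction; the first moment is then essentially exact
(checked against E[PG(1,z)] = tanh(z/2)/(2z) by Monte Carlo), and the
residual truncation error is far below the Monte Carlo noise of any
chain of realistic length. An independent 2-D grid-quadrature posterior
for a one-covariate logistic model serves as an external correctness
oracle for the whole update cycle (agreement of posterior mean and SD
within 0.05 at n = 500 is asserted in the acceptance suite).

### Identifiability and centring

The intrinsic GMRF and the random-walk priors are partially improper
(their null spaces contain constants, and linear trends for RW2), so
smooth blocks and f_str are re-centred every sweep: the removed constant
is transferred into the intercept, leaving η unchanged. Because B-spline
rows sum to one, subtracting a constant from ξ shifts the fitted curve by
exactly that constant. f_unstr is left uncentred — its proper mean-zero
prior identifies it. Retained draws satisfy the sum-to-zero constraints
to machine precision (asserted to 1e−8 in tests).

The structured/unstructured decomposition itself is only weakly
identified (a generic property of convolution-type spatial models); the
sum f_str + f_unstr — the quantity the risk map depends on — is well
identified, and recovery checks of the map are therefore phrased against
the true total region effect.

## Tunable parameters

| parameter | default | units / scale | rationale |
|---|---|---|---|
| `segments` per smooth | 20 | knot intervals | "many equidistant knots" P-spline convention; smoothness is governed by τ², not knot count |
| `degree` | 3 | polynomial degree | cubic splines, the standard choice |
| `rw_order` | 2 | — | RW2 shrinks toward linearity; RW1 available per term |
| `a`, `b` | 0.001 | dimensionless | highly dispersed IG hyperprior |
| fixed-prior variance | 10⁶ | log-odds² | effectively flat yet proper |
| `k` (kNN graph) | 3 | neighbours | modest connectivity for ~10 regions |
| iterations/burn-in/thin | 10,000 / 1,000 / 50 | sweeps | standard configuration for this model class |

## Numerical choices

- B-spline evaluation delegates to `scipy.interpolate.BSpline.design_matrix`
  on the extended equidistant knot sequence; interior knots are built with
  `linspace` so the domain endpoints are exact and boundary observations
  are never rejected by floating-point slack. An independently coded
  Cox–de Boor recursion is the test oracle.
- Gaussian block draws use a Cholesky solve; the spatial block uses an
  eigendecomposition-based draw. Intrinsic-matrix ranks are computed once
  with tolerance 1e−8 × (largest eigenvalue); the structure-matrix rank
  uses S − #components directly.
- Constrained GMRF draws: eigendecomposition of the structure matrix,
  noise injected along the positive eigenspace, then exact mean removal.
  An unconstrained draw on a rank-deficient structure is an error.
- Chi-square screening uses Pearson's statistic without continuity
  correction (`scipy.stats.chi2_contingency`), df = levels − 1 for the
  levels × 2 table; zero expected counts raise with advice to merge
  levels. Display percentages are rounded half-up to 2 decimals; full
  precision is kept internally.
- kNN graphs break distance ties by region index order (deterministic)
  and are symmetrised by union, so the structure matrix is symmetric even
  though neighbour counts then differ between regions.
- Degenerate inputs: islands (N_s = 0) are fatal for conditional-prior
  computations, with advice to connect the region manually; factors with
  a single observed level are fatal for screening; fewer than 10 retained
  draws are fatal for percentile summaries.
- Equal-tailed percentile credible intervals throughout; OR-scale
  intervals are exp of the log-odds-scale percentiles, which commutes
  exactly with the monotone transform.
- The risk map's "standard error" surface is the posterior SD of the
  per-region predicted probability at the reference profile (all factors
  at reference, smooths at the observed medians of their covariates).

## Synthetic generator

`default_spec()` encodes the study conditions the package is exercised
under: 11 regions on a k = 3 nearest-neighbour graph over random planar
coordinates, 182 children per region (n = 2,002), a binary residence
factor (75% rural, +0.30 log-odds), a 3-level wealth factor (45/30/25%,
effects 0/−0.20/−0.50 — mortality falling with wealth), a sinusoidal
mother's-age effect (amplitude 0.30) and a U-shaped quadratic family-size
effect (amplitude 0.60), τ_str² = 0.25, τ_unstr² = 0.05, and an intercept
of −1.86 chosen so the implied marginal death fraction is ≈ 0.15,
matching the survey scale the model targets. Covariates are uniform
(continuous) or multinomial (factors) because the real survey's covariate
marginals are not reproducible from published material.

Recovery experiments refit each of 20 replicate surveys with 1,500-sweep
chains (500 burn-in, thinning 5; 200 retained draws) — long enough that
percentile CI endpoints are stable, while the whole suite runs in a few
minutes on one CPU. Reported recovery quantities (pooled fixed-effect CI
coverage, smooth-band coverage, risk-map rank correlation) are computed by
`scripts/acceptance.py` and the acceptance tests at run time.

What the generator does **not** emulate: two-stage cluster sampling and
its weights, nonresponse, missing-data patterns, covariate dependence
(e.g. wealth–residence correlation), and real geography. Passing recovery
tests therefore demonstrate that the estimation machinery recovers the
generating process of this class — not that the model is robust to
survey-design artefacts of real data.

## Design decisions

- Polya-Gamma augmentation over IWLS-Metropolis proposals: exact
  conjugate conditionals, no tuning, and every update is unit-testable
  against closed forms.
- Listwise deletion of incomplete rows at ingestion, with a logged count.
- Reference level = first level of each factor spec, matching the "Ref."
  convention of published odds-ratio tables.
- Survey weights are deliberately ignored in estimation: the model is an
  unweighted likelihood; a weight column is carried for provenance only.
- Screening flags factors at the 5% level but never drops them; which
  covariates enter the model, and as fixed or smooth terms, is a user
  decision via config.
- Both graph entry points (adjacency file, kNN from coordinates) are
  provided; published analyses of this kind are ambiguous about which is
  used.

## Limitations

- Pointwise 95% smooth bands undercover where smoothing bias is large
  (sharp curvature at modest signal-to-noise); this is inherent to
  penalised smoothing, and the recovery suite measures band coverage
  empirically rather than assuming nominal level.
- No DIC or proper-scoring-rule model comparison; no tensor-product
  interactions or time trends; binary response only.
- Maps are exported as per-region values (CSV + simple figures); no
  polygon cartography.
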