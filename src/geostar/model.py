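"""Geoadditive logistic regression fitted by Polya-Gamma Gibbs sampling.

The model for a binary outcome y_i ~ Bernoulli(pi_i) uses the structured
additive predictor

    logit(pi_i) = alpha_0 + w_i' alpha + sum_j f_j(x_ij) + f_str(s_i) + f_unstr(s_i)

with w_i the reference-coded fixed-effect dummies, f_j P-spline smooths
with random-walk priors, f_str an intrinsic GMRF over regions and f_unstr
i.i.d. Gaussian region heterogeneity.  All smoothing/spatial variances
carry inverse-Gamma IG(a, b) hyperpriors; fixed effects get a diffuse
mean-zero Gaussian prior.

Sampling augments each observation with omega_i ~ PG(1, eta_i), after
which every coefficient block has a Gaussian full conditional with
precision B' Omega B + K / tau^2 and every variance an inverse-Gamma full
conditional IG(a + rank(K)/2, b + xi' K xi / 2); the sampler is a
systematic-scan Gibbs sweep (auxiliary -> each coefficient block -> each
variance).  Smooth and structured-spatial blocks are re-centred each sweep
(the removed constant moves into the intercept) so the intercept is
identified.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import linalg, sparse
from scipy.sparse.csgraph import connected_components
from scipy.special import expit

from .data import DesignBlocks, FactorSpec, ObservationTable, encode_design
from .polya_gamma import sample_pg
from .spatial import NeighborhoodGraph, structure_matrix
from .splines import SplineBlock, equidistant_knots, evaluate_basis, \
    make_spline_block

logger = logging.getLogger(__name__)


def inv_logit(eta):
    """Logistic function pi = 1 / (1 + exp(-eta)), overflow-safe."""
    return expit(eta)


def bernoulli_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    """Bernoulli-logit log likelihood sum_i [y_i eta_i - log(1 + e^eta_i)]."""
    y = np.asarray(y, float)
    eta = np.asarray(eta, float)
    if y.shape != eta.shape:
        raise ValueError("y and eta lengths differ")
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters: IG(a, b) for every variance, diffuse fixed prior."""

    a: float = 0.001
    b: float = 0.001
    fixed_prior_variance: float = 1e6

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("inverse-Gamma hyperparameters must be positive")
        if self.fixed_prior_variance <= 0:
            raise ValueError("fixed_prior_variance must be positive")


@dataclass(frozen=True)
class MCMCConfig:
    """Chain length bookkeeping; retained = floor((iterations-burnin)/thin)."""

    iterations: int = 10_000
    burnin: int = 1_000
    thin: int = 50
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.burnin >= self.iterations:
            raise ValueError("burnin must be smaller than iterations")
        if self.thin < 1:
            raise ValueError("thinning must be >= 1")

    @property
    def retained(self) -> int:
        return (self.iterations - self.burnin) // self.thin


@dataclass(frozen=True)
class SmoothSpec:
    """Per-term P-spline settings (segments, degree, random-walk order)."""

    name: str
    segments: int = 20
    degree: int = 3
    rw_order: int = 2


@dataclass
class ModelState:
    """Current values of every sampled quantity during one sweep."""

    intercept: float
    alpha: np.ndarray
    xi: dict[str, np.ndarray]
    f_str: np.ndarray
    f_unstr: np.ndarray
    tau2: dict[str, float]
    tau2_str: float
    tau2_unstr: float
    omega: np.ndarray | None = None


@dataclass
class PosteriorSamples:
    """Retained MCMC draws, draw-major, for every model block.

    ``blocks`` maps block name ("fixed", "smooth:<name>", "f_str",
    "f_unstr") to an (ndraw, dim) array; ``variances`` maps variance name
    ("tau2:<name>", "tau2_str", "tau2_unstr") to an (ndraw,) array.
    """

    blocks: dict[str, np.ndarray]
    variances: dict[str, np.ndarray]
    labels: dict[str, list[str]]
    region_ids: np.ndarray
    config: MCMCConfig
    smooth_meta: dict[str, dict] = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return next(iter(self.blocks.values())).shape[0]

    def chain(self, label: str) -> np.ndarray:
        """Extract the scalar chain for one labelled parameter."""
        if label in self.variances:
            return self.variances[label]
        for name, labs in self.labels.items():
            if label in labs:
                return self.blocks[name][:, labs.index(label)]
        raise KeyError(f"no parameter labelled {label!r}")

    def save(self, directory) -> None:
        """Write a portable columnar archive plus a JSON manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        arrays = {f"block:{k}": v for k, v in self.blocks.items()}
        arrays.update({f"var:{k}": v for k, v in self.variances.items()})
        np.savez(directory / "samples.npz", **arrays)
        manifest = {
            "blocks": {k: list(v.shape) for k, v in self.blocks.items()},
            "variances": sorted(self.variances),
            "labels": self.labels,
            "region_ids": self.region_ids.tolist(),
            "config": {"iterations": self.config.iterations,
                       "burnin": self.config.burnin,
                       "thin": self.config.thin,
                       "seed": self.config.seed},
            "smooth_meta": self.smooth_meta,
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory) -> "PosteriorSamples":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        with np.load(directory / "samples.npz") as npz:
            blocks = {k[len("block:"):]: npz[k] for k in npz.files
                      if k.startswith("block:")}
            variances = {k[len("var:"):]: npz[k] for k in npz.files
                         if k.startswith("var:")}
        cfg = MCMCConfig(**manifest["config"])
        return cls(blocks=blocks, variances=variances,
                   labels=manifest["labels"],
                   region_ids=np.asarray(manifest["region_ids"], dtype=int),
                   config=cfg, smooth_meta=manifest.get("smooth_meta", {}))


def linear_predictor(
    design: DesignBlocks,
    state: ModelState,
    smooth_blocks: dict[str, SplineBlock],
) -> np.ndarray:
    """Assemble eta = alpha_0 + W alpha + sum_j B_j xi_j + Z (f_str + f_unstr)."""
    eta = np.full(design.n, state.intercept, dtype=float)
    if design.fixed.shape[1]:
        if design.fixed.shape[1] != len(state.alpha):
            raise ValueError("fixed-effect dimension mismatch")
        eta = eta + design.fixed @ state.alpha
    for name, block in smooth_blocks.items():
        xi = state.xi[name]
        if block.basis.shape[1] != len(xi):
            raise ValueError(f"smooth {name!r} dimension mismatch")
        eta = eta + block.basis @ xi
    if design.incidence.shape[1] != len(state.f_str):
        raise ValueError("spatial dimension mismatch")
    eta = eta + design.incidence @ (state.f_str + state.f_unstr)
    return eta


def update_auxiliary(y: np.ndarray, eta: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    """Draw the Polya-Gamma auxiliaries omega_i ~ PG(1, eta_i).

    Under the augmentation the full conditional of omega does not depend
    on y; the argument is kept for a uniform update signature.
    """
    del y
    return sample_pg(eta, rng)


def update_coefficient_block(
    B: np.ndarray,
    prior_precision: np.ndarray,
    y: np.ndarray,
    eta_rest: np.ndarray,
    omega: np.ndarray,
    rng: np.random.Generator,
    name: str = "block",
    method: str = "chol",
) -> np.ndarray:
    """Exact Gaussian full-conditional draw for one coefficient block.

    Posterior precision P = B' Omega B + P0 and mean P^{-1} B'(y - 1/2
    - omega * eta_rest), where eta_rest is the predictor excluding this
    block.  ``method="eigh"`` draws through the eigendecomposition of P,
    which makes a single update equivariant under a symmetric permutation
    of the block coordinates (used for the spatial field so region
    relabelling permutes the draw).
    """
    B = np.atleast_2d(np.asarray(B, float))
    p = B.shape[1]
    kappa = np.asarray(y, float) - 0.5
    P = B.T @ (omega[:, None] * B) + prior_precision if B.shape[0] else \
        np.array(prior_precision, float)
    if not np.isfinite(P).all():
        raise FloatingPointError(f"non-finite precision in block {name!r}")
    b = B.T @ (kappa - omega * eta_rest) if B.shape[0] else np.zeros(p)
    z = rng.standard_normal(p)
    if method == "eigh":
        w, V = np.linalg.eigh(P)
        if (w <= 0).any():
            raise FloatingPointError(f"non-PD precision in block {name!r}")
        mean = V @ ((V.T @ b) / w)
        return mean + V @ (z / np.sqrt(w))
    L = linalg.cholesky(P, lower=True)
    mean = linalg.cho_solve((L, True), b)
    return mean + linalg.solve_triangular(L, z, lower=True, trans="T")


def update_variance(
    xi: np.ndarray,
    K: np.ndarray | sparse.spmatrix,
    a: float,
    b: float,
    rng: np.random.Generator,
    rank: int | None = None,
) -> float:
    """Conjugate inverse-Gamma draw tau^2 ~ IG(a + rank(K)/2, b + xi'K xi/2)."""
    if a <= 0 or b <= 0:
        raise ValueError("hyperparameters must be positive")
    Kd = K.toarray() if sparse.issparse(K) else np.asarray(K, float)
    quad = float(xi @ Kd @ xi)
    if not np.isfinite(quad):
        raise FloatingPointError("non-finite quadratic form in variance update")
    if rank is None:
        w = np.linalg.eigvalsh(Kd)
        rank = int((w > 1e-8 * max(w.max(), 1.0)).sum())
    shape = a + rank / 2.0
    rate = b + max(quad, 0.0) / 2.0
    return 1.0 / rng.gamma(shape, 1.0 / rate)


class GeoadditiveLogit:
    """Bayesian structured additive logistic model for survey data.

    Parameters
    ----------
    outcome : (n,) 0/1 array of death indicators.
    design : DesignBlocks from :func:`geostar.data.encode_design`.
    graph : NeighborhoodGraph whose regions match the incidence columns.
    smooths : list of SmoothSpec naming which continuous covariates enter
        as P-spline smooths (default: all continuous columns, 20 cubic
        segments, RW2 penalty).
    priors : PriorSpec hyperparameters.
    """

    def __init__(
        self,
        outcome: np.ndarray,
        design: DesignBlocks,
        graph: NeighborhoodGraph,
        smooths: list[SmoothSpec] | None = None,
        priors: PriorSpec | None = None,
    ):
        self.y = np.asarray(outcome, dtype=float)
        if not np.isin(self.y, (0.0, 1.0)).all():
            raise ValueError("outcome must be 0/1")
        self.design = design
        self.graph = graph
        if list(design.region_ids) != list(graph.regions):
            raise ValueError("design incidence columns must match graph regions")
        self.priors = priors or PriorSpec()

        if smooths is None:
            smooths = [SmoothSpec(name) for name in design.continuous]
        self.smooth_specs = {s.name: s for s in smooths}
        self.smooth_blocks: dict[str, SplineBlock] = {}
        for s in smooths:
            if s.name not in design.continuous:
                raise ValueError(f"no continuous column {s.name!r} in design")
            self.smooth_blocks[s.name] = make_spline_block(
                s.name, design.continuous[s.name],
                segments=s.segments, degree=s.degree, rw_order=s.rw_order,
            )

        self.K_str = structure_matrix(graph)
        ncomp, _ = connected_components(self.K_str != 0, directed=False)
        self.rank_str = graph.S - int(ncomp)
        self.fixed_labels = ["intercept"] + list(design.fixed_labels)

    # ------------------------------------------------------------------
    @classmethod
    def from_dataframe(
        cls,
        df,
        factors: list[FactorSpec],
        smooths: list[SmoothSpec],
        graph: NeighborhoodGraph,
        outcome_col: str = "died",
        region_col: str = "region",
        priors: PriorSpec | None = None,
    ) -> "GeoadditiveLogit":
        """Build the model directly from a tidy per-child DataFrame."""
        continuous = [s.name for s in smooths]
        table = ObservationTable(
            outcome=df[outcome_col].to_numpy(),
            categorical=df[[f.name for f in factors]].astype(str),
            continuous=df[continuous].astype(float),
            region_id=df[region_col].astype(int).to_numpy(),
        )
        unknown = sorted(set(table.region_id) - set(graph.regions))
        if unknown:
            raise ValueError(f"region id(s) {unknown} absent from the graph")
        design = encode_design(table, factors, continuous,
                               regions=list(graph.regions))
        return cls(table.outcome, design, graph, smooths=smooths, priors=priors)

    @classmethod
    def from_table(cls, table: ObservationTable, factors, smooths, graph,
                   priors=None) -> "GeoadditiveLogit":
        design = encode_design(table, factors, [s.name for s in smooths],
                               regions=list(graph.regions))
        return cls(table.outcome, design, graph, smooths=smooths, priors=priors)

    # ------------------------------------------------------------------
    def _initial_state(self, rng: np.random.Generator) -> ModelState:
        p = self.design.fixed.shape[1]
        state = ModelState(
            intercept=0.0,
            alpha=np.zeros(p),
            xi={name: np.zeros(blk.d)
                for name, blk in self.smooth_blocks.items()},
            f_str=np.zeros(self.graph.S),
            f_unstr=np.zeros(self.graph.S),
            tau2={name: 0.1 for name in self.smooth_blocks},
            tau2_str=0.1,
            tau2_unstr=0.1,
        )
        state.omega = sample_pg(np.zeros(len(self.y)), rng)
        return state

    def _eta(self, state: ModelState) -> np.ndarray:
        return linear_predictor(self.design, state, self.smooth_blocks)

    def _sweep(self, state: ModelState, rng: np.random.Generator) -> ModelState:
        y, design = self.y, self.design
        eta = self._eta(state)
        if not np.isfinite(bernoulli_loglik(y, eta)):
            raise FloatingPointError("divergent sweep: non-finite log-likelihood")
        state.omega = update_auxiliary(y, eta, rng)
        omega = state.omega

        # fixed block (intercept + dummies), diffuse Gaussian prior
        Xf = np.column_stack([design.intercept, design.fixed])
        beta = np.concatenate([[state.intercept], state.alpha])
        eta_rest = eta - Xf @ beta
        P0 = np.eye(Xf.shape[1]) / self.priors.fixed_prior_variance
        beta = update_coefficient_block(Xf, P0, y, eta_rest, omega, rng,
                                        name="fixed")
        state.intercept, state.alpha = float(beta[0]), beta[1:]
        eta = eta_rest + Xf @ beta

        # smooth blocks, RW penalty prior, re-centred afterwards
        for name, blk in self.smooth_blocks.items():
            fit_old = blk.basis @ state.xi[name]
            eta_rest = eta - fit_old
            xi = update_coefficient_block(
                blk.basis, blk.penalty / state.tau2[name], y, eta_rest,
                omega, rng, name=f"smooth:{name}")
            shift = float(np.mean(blk.basis @ xi))
            xi = xi - shift           # basis rows sum to 1
            state.intercept += shift
            state.xi[name] = xi
            eta = eta_rest + blk.basis @ xi + shift

        # structured spatial block (eigh draw: label-equivariant update)
        Z = design.incidence
        eta_rest = eta - Z @ state.f_str
        f_str = update_coefficient_block(
            Z, self.K_str.toarray() / state.tau2_str, y, eta_rest, omega,
            rng, name="f_str", method="eigh")
        shift = float(np.mean(f_str))
        f_str = f_str - shift
        state.intercept += shift
        state.f_str = f_str
        eta = eta_rest + Z @ f_str + shift

        # unstructured spatial block, i.i.d. Gaussian prior
        eta_rest = eta - Z @ state.f_unstr
        state.f_unstr = update_coefficient_block(
            Z, np.eye(self.graph.S) / state.tau2_unstr, y, eta_rest, omega,
            rng, name="f_unstr")

        # conjugate variance updates
        a, b = self.priors.a, self.priors.b
        for name, blk in self.smooth_blocks.items():
            state.tau2[name] = update_variance(
                state.xi[name], blk.penalty, a, b, rng,
                rank=blk.d - blk.rw_order)
        state.tau2_str = update_variance(state.f_str, self.K_str, a, b, rng,
                                         rank=self.rank_str)
        state.tau2_unstr = update_variance(
            state.f_unstr, np.eye(self.graph.S), a, b, rng, rank=self.graph.S)
        return state

    def fit(
        self,
        iterations: int = 10_000,
        burnin: int = 1_000,
        thin: int = 50,
        seed: int | None = None,
        progress: bool = False,
    ) -> "GeoadditiveLogitResults":
        """Run the Gibbs sampler and return a results object."""
        config = MCMCConfig(iterations=iterations, burnin=burnin,
                            thin=thin, seed=seed)
        rng = np.random.default_rng(seed)
        state = self._initial_state(rng)

        nkeep = config.retained
        p_fixed = 1 + self.design.fixed.shape[1]
        blocks = {"fixed": np.empty((nkeep, p_fixed)),
                  "f_str": np.empty((nkeep, self.graph.S)),
                  "f_unstr": np.empty((nkeep, self.graph.S))}
        for name, blk in self.smooth_blocks.items():
            blocks[f"smooth:{name}"] = np.empty((nkeep, blk.d))
        variances = {f"tau2:{name}": np.empty(nkeep)
                     for name in self.smooth_blocks}
        variances["tau2_str"] = np.empty(nkeep)
        variances["tau2_unstr"] = np.empty(nkeep)

        kept = 0
        for t in range(1, iterations + 1):
            try:
                state = self._sweep(state, rng)
            except FloatingPointError as exc:
                raise FloatingPointError(f"sweep {t}: {exc}") from exc
            if t > burnin and (t - burnin) % thin == 0:
                blocks["fixed"][kept] = np.concatenate(
                    [[state.intercept], state.alpha])
                blocks["f_str"][kept] = state.f_str
                blocks["f_unstr"][kept] = state.f_unstr
                for name in self.smooth_blocks:
                    blocks[f"smooth:{name}"][kept] = state.xi[name]
                    variances[f"tau2:{name}"][kept] = state.tau2[name]
                variances["tau2_str"][kept] = state.tau2_str
                variances["tau2_unstr"][kept] = state.tau2_unstr
                kept += 1
            if progress and t % max(iterations // 10, 1) == 0:
                logger.info("sweep %d/%d (%d draws retained)",
                            t, iterations, kept)

        labels = {"fixed": self.fixed_labels,
                  "f_str": [f"f_str[{r}]" for r in self.graph.regions],
                  "f_unstr": [f"f_unstr[{r}]" for r in self.graph.regions]}
        smooth_meta = {}
        for name, blk in self.smooth_blocks.items():
            labels[f"smooth:{name}"] = [f"{name}:xi[{m}]"
                                        for m in range(blk.d)]
            kv = blk.knots
            x = self.design.continuous[name]
            smooth_meta[name] = {
                "x_min": kv.x_min, "x_max": kv.x_max,
                "segments": kv.segments, "degree": kv.degree,
                "rw_order": blk.rw_order, "median": float(np.median(x)),
            }
        samples = PosteriorSamples(
            blocks=blocks, variances=variances, labels=labels,
            region_ids=np.asarray(self.graph.regions, dtype=int),
            config=config, smooth_meta=smooth_meta)
        return GeoadditiveLogitResults(samples, model=self)


class GeoadditiveLogitResults:
    """Posterior draws with odds-ratio tables, curves, maps and diagnostics.

    Thin wrapper over :class:`PosteriorSamples`; can be reconstructed from
    a saved archive without the original model (the manifest carries the
    knot and reference-profile metadata needed by the summaries).
    """

    def __init__(self, samples: PosteriorSamples,
                 model: GeoadditiveLogit | None = None):
        self.samples = samples
        self.model = model

    # delegated summaries (implementations in geostar.summary) ---------
    def effect_table(self):
        from .summary import effect_table
        return effect_table(self.samples)

    def smooth_curve(self, name: str, grid: np.ndarray | None = None):
        from .summary import smooth_curve
        return smooth_curve(self.samples, name, grid=grid)

    def region_risk(self):
        from .summary import region_risk
        return region_risk(self.samples)

    def diagnostics(self, label: str, max_lag: int = 50):
        from .summary import diagnostics
        return diagnostics(self.samples, label, max_lag=max_lag)

    def summary(self) -> str:
        """Plain-text summary table of fixed effects and variances."""
        df = self.effect_table()
        lines = ["Geoadditive logistic regression — posterior summary",
                 f"retained draws: {self.samples.n_draws}", ""]
        lines.append(f"{'parameter':<28}{'estimate':>10}{'OR':>8}"
                     f"{'2.5%':>8}{'97.5%':>8}")
        for _, row in df.iterrows():
            lines.append(f"{row['label']:<28}{row['estimate']:>10.3f}"
                         f"{row['OR']:>8.3f}{row['lower']:>8.3f}"
                         f"{row['upper']:>8.3f}")
        lines.append("")
        for name, v in self.samples.variances.items():
            lines.append(f"{name:<28}{np.mean(v):>10.4f}  "
                         f"[{np.percentile(v, 2.5):.4f}, "
                         f"{np.percentile(v, 97.5):.4f}]")
        return "\n".join(lines)

    def save(self, directory) -> None:
        self.samples.save(directory)

    @classmethod
    def load(cls, directory) -> "GeoadditiveLogitResults":
        return cls(PosteriorSamples.load(directory))


def smooth_basis_from_meta(meta: dict, grid: np.ndarray) -> np.ndarray:
    """Rebuild a smooth term's basis on a grid from saved knot metadata."""
    kv = equidistant_knots(meta["x_min"], meta["x_max"],
                           meta["segments"], meta["degree"])
    return evaluate_basis(grid, kv)
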