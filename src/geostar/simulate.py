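"""Synthetic DHS-like survey generator with known ground truth.

Emulates the structure of a national household survey: S regions on a
k-nearest-neighbour graph, children nested in regions, and a Bernoulli
death indicator driven by a structured additive predictor containing
reference-coded fixed effects, smooth nonlinear covariate effects, a
spatially correlated (intrinsic GMRF) region field and i.i.d. region
heterogeneity.  The default specification mirrors the scale of the survey
the model targets: 11 regions, roughly 2,000 children, and an implied
marginal death fraction near 0.15.

Every generated quantity (covariates, fields, outcomes) is reproducible
from a single seed, and the realised truth is returned so fits can be
scored by parameter-recovery coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import FactorSpec, ObservationTable
from .model import PosteriorSamples, inv_logit
from .spatial import NeighborhoodGraph, knn_graph, sample_gmrf, structure_matrix


@dataclass(frozen=True)
class TrueSmooth:
    """A named closed-form smooth effect, analytically centred on its range.

    ``form="sine"``: amplitude * sin(2 pi (x - low) / (high - low)) — zero
    mean over the full period.  ``form="quadratic"``: amplitude * (u^2 -
    1/3) with u = (x - mid) / half-range — zero mean under uniform x.
    """

    form: str
    low: float
    high: float
    amplitude: float

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.form == "sine":
            return self.amplitude * np.sin(
                2.0 * np.pi * (x - self.low) / (self.high - self.low))
        if self.form == "quadratic":
            mid = 0.5 * (self.low + self.high)
            half = 0.5 * (self.high - self.low)
            u = (x - mid) / half
            return self.amplitude * (u ** 2 - 1.0 / 3.0)
        raise ValueError(f"unknown smooth form {self.form!r}")


@dataclass(frozen=True)
class TrueFactor:
    """Factor levels with sampling probabilities and true log-odds effects."""

    levels: tuple[str, ...]
    probs: tuple[float, ...]
    effects: tuple[float, ...]   # effects[0] is the reference, always 0

    def __post_init__(self) -> None:
        if not (len(self.levels) == len(self.probs) == len(self.effects)):
            raise ValueError("levels/probs/effects lengths differ")
        if abs(sum(self.probs) - 1.0) > 1e-9:
            raise ValueError("probs must sum to 1")
        if self.effects[0] != 0.0:
            raise ValueError("reference-level effect must be 0")


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of one synthetic survey's generating process."""

    S: int = 11
    k: int = 3
    households_per_region: int = 182
    intercept: float = -1.86
    factors: dict[str, TrueFactor] = field(default_factory=dict)
    smooths: dict[str, TrueSmooth] = field(default_factory=dict)
    tau2_str: float = 0.25
    tau2_unstr: float = 0.05

    def __post_init__(self) -> None:
        if self.S < 4:
            raise ValueError("need at least 4 regions")
        if self.k >= self.S:
            raise ValueError("k must be smaller than S")
        if self.tau2_str <= 0 or self.tau2_unstr <= 0:
            raise ValueError("variances must be positive")

    @property
    def n_total(self) -> int:
        return self.S * self.households_per_region

    def factor_specs(self) -> list[FactorSpec]:
        return [FactorSpec(name, tf.levels)
                for name, tf in self.factors.items()]

    def fixed_effect_truth(self) -> dict[str, float]:
        """True coefficients keyed by design-column label."""
        out = {}
        for name, tf in self.factors.items():
            for level, eff in zip(tf.levels[1:], tf.effects[1:]):
                out[f"{name}[{level}]"] = eff
        return out


@dataclass
class SyntheticTruth:
    """Realised ground truth of one simulated survey."""

    spec: SyntheticSpec
    coords: np.ndarray
    f_str: np.ndarray
    f_unstr: np.ndarray
    eta: np.ndarray
    pi: np.ndarray

    def __post_init__(self) -> None:
        assert abs(self.f_str.sum()) < 1e-8
        np.testing.assert_allclose(self.pi, inv_logit(self.eta))


def default_spec() -> SyntheticSpec:
    """The default study conditions: 11 regions, ~2,000 children, rate ~0.15.

    Two factors (binary residence, 3-level wealth with mortality falling
    as wealth rises), a sinusoidal mother's-age effect and a U-shaped
    (quadratic) family-size effect, spatial variance 0.25 and unstructured
    variance 0.05.
    """
    return SyntheticSpec(
        factors={
            "residence": TrueFactor(
                levels=("urban", "rural"), probs=(0.25, 0.75),
                effects=(0.0, 0.30)),
            "wealth": TrueFactor(
                levels=("poorest", "middle", "richest"),
                probs=(0.45, 0.30, 0.25),
                effects=(0.0, -0.20, -0.50)),
        },
        smooths={
            "mother_age": TrueSmooth("sine", 15.0, 49.0, 0.30),
            "family_size": TrueSmooth("quadratic", 1.0, 12.0, 0.60),
        },
    )


def simulate_survey(
    spec: SyntheticSpec, rng: np.random.Generator
) -> tuple[ObservationTable, NeighborhoodGraph, SyntheticTruth]:
    """Draw one complete survey: table, region graph and realised truth."""
    coords = rng.uniform(size=(spec.S, 2))
    graph = knn_graph(coords, spec.k)
    K = structure_matrix(graph)
    f_str = sample_gmrf(K, spec.tau2_str, rng, constraint=True)
    f_unstr = rng.normal(0.0, np.sqrt(spec.tau2_unstr), spec.S)

    n = spec.n_total
    region = np.repeat(np.asarray(graph.regions), spec.households_per_region)
    region_index = np.repeat(np.arange(spec.S), spec.households_per_region)

    eta = np.full(n, spec.intercept)
    cat = {}
    for name, tf in spec.factors.items():
        idx = rng.choice(len(tf.levels), size=n, p=tf.probs)
        cat[name] = np.asarray(tf.levels)[idx]
        eta = eta + np.asarray(tf.effects)[idx]
    cont = {}
    for name, ts in spec.smooths.items():
        x = rng.uniform(ts.low, ts.high, n)
        cont[name] = x
        eta = eta + ts(x)
    eta = eta + f_str[region_index] + f_unstr[region_index]

    pi = inv_logit(eta)
    if (pi <= 0).any() or (pi >= 1).any():
        raise ValueError("spec implies degenerate probabilities 0 or 1")
    y = rng.binomial(1, pi)

    table = ObservationTable(
        outcome=y,
        categorical=pd.DataFrame(cat),
        continuous=pd.DataFrame(cont),
        region_id=region,
    )
    truth = SyntheticTruth(spec=spec, coords=coords, f_str=f_str,
                           f_unstr=f_unstr, eta=eta, pi=pi)
    return table, graph, truth


def recovery_report(truth: SyntheticTruth,
                    samples: PosteriorSamples) -> pd.DataFrame:
    """Coverage check: is each true fixed effect inside its 95% CI?

    Rows: parameter, true value, posterior mean, CI bounds (log-odds
    scale) and a coverage indicator.
    """
    wanted = truth.spec.fixed_effect_truth()
    labels = samples.labels["fixed"]
    missing = sorted(set(wanted) - set(labels))
    if missing:
        raise ValueError(f"fitted samples lack fixed-effect column(s) {missing}")
    draws = samples.blocks["fixed"]
    rows = []
    for label, true_val in wanted.items():
        col = draws[:, labels.index(label)]
        lo, hi = np.percentile(col, [2.5, 97.5])
        rows.append({"parameter": label, "true": true_val,
                     "post_mean": float(col.mean()),
                     "lower": float(lo), "upper": float(hi),
                     "covered": bool(lo <= true_val <= hi)})
    return pd.DataFrame(rows)


def smooth_coverage(
    truth: SyntheticTruth,
    samples: PosteriorSamples,
    name: str,
    x_obs: np.ndarray,
    n_grid: int = 50,
) -> float:
    """Fraction of grid points where the true smooth lies in the 95% band.

    The fitted smooth is centred over the observed covariate values, so
    the true curve is centred the same way before comparison.
    """
    from .summary import smooth_curve

    ts = truth.spec.smooths[name]
    est = smooth_curve(samples, name, n_grid=n_grid)
    true_curve = ts(est.grid) - ts(np.asarray(x_obs)).mean()
    inside = (est.lower <= true_curve) & (true_curve <= est.upper)
    return float(inside.mean())
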