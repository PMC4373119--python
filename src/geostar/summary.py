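"""Posterior products: OR tables, smooth curves, risk maps, diagnostics.

Credible intervals throughout are equal-tailed 2.5/97.5 posterior
percentile intervals.  The risk map reports, per region, the posterior
mean and standard deviation of the predicted death probability at a
reference covariate profile (all factors at their reference level, each
smooth evaluated at the observed median of its covariate).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import PosteriorSamples, inv_logit, smooth_basis_from_meta

_MIN_DRAWS = 10


@dataclass
class SmoothEstimate:
    """Pointwise posterior mean and 95% band of one smooth effect."""

    name: str
    grid: np.ndarray
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"grid": self.grid, "mean": self.mean,
                             "lower": self.lower, "upper": self.upper})


@dataclass
class RiskMap:
    """Per-region posterior mean probability and its posterior SD."""

    region_ids: np.ndarray
    mean_prob: np.ndarray
    sd: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"region": self.region_ids,
                             "mean_prob": self.mean_prob, "sd": self.sd})


def effect_table(samples: PosteriorSamples,
                 labels: list[str] | None = None) -> pd.DataFrame:
    """Fixed-effect table: posterior mean, OR = exp(mean), 95% CI (OR scale).

    The interval is exp of the 2.5/97.5 log-odds-scale percentiles, which
    by monotonicity is the percentile interval of the OR draws themselves.
    """
    draws = samples.blocks["fixed"]
    if draws.shape[0] < _MIN_DRAWS:
        raise ValueError(
            f"only {draws.shape[0]} retained draws; need >= {_MIN_DRAWS} "
            "for meaningful percentiles"
        )
    if labels is None:
        labels = samples.labels["fixed"]
    rows = []
    for j, label in enumerate(labels):
        col = draws[:, j]
        est = float(np.mean(col))
        lo, hi = np.exp(np.percentile(col, [2.5, 97.5]))
        rows.append({"label": label, "estimate": est, "OR": float(np.exp(est)),
                     "lower": float(lo), "upper": float(hi)})
    return pd.DataFrame(rows)


def smooth_curve(samples: PosteriorSamples, name: str,
                 grid: np.ndarray | None = None,
                 n_grid: int = 100) -> SmoothEstimate:
    """Posterior mean curve and 95% band of smooth f_name on a grid."""
    key = f"smooth:{name}"
    if key not in samples.blocks:
        raise KeyError(f"no smooth term {name!r} in the samples")
    meta = samples.smooth_meta[name]
    if grid is None:
        grid = np.linspace(meta["x_min"], meta["x_max"], n_grid)
    grid = np.asarray(grid, dtype=float)
    if (grid < meta["x_min"]).any() or (grid > meta["x_max"]).any():
        raise ValueError("grid outside the knot domain")
    B = smooth_basis_from_meta(meta, grid)
    curves = samples.blocks[key] @ B.T          # (ndraw, ngrid)
    lo, hi = np.percentile(curves, [2.5, 97.5], axis=0)
    return SmoothEstimate(name=name, grid=grid, mean=curves.mean(axis=0),
                          lower=lo, upper=hi)


def region_risk(samples: PosteriorSamples) -> RiskMap:
    """Predicted probability map at the reference covariate profile.

    Per draw and region: inv_logit(intercept + smooths at their covariate
    medians + f_str(s) + f_unstr(s)); fixed factors sit at their reference
    level so contribute nothing.  Mean over draws gives the risk surface,
    the SD over draws its "standard error" companion.
    """
    for key in ("f_str", "f_unstr"):
        if key not in samples.blocks:
            raise KeyError(f"samples missing spatial block {key!r}")
    intercept = samples.blocks["fixed"][:, 0]
    ref = intercept.copy()
    for name, meta in samples.smooth_meta.items():
        B = smooth_basis_from_meta(meta, np.array([meta["median"]]))
        ref = ref + (samples.blocks[f"smooth:{name}"] @ B.T).ravel()
    eta = ref[:, None] + samples.blocks["f_str"] + samples.blocks["f_unstr"]
    prob = inv_logit(eta)                        # (ndraw, S)
    return RiskMap(region_ids=samples.region_ids,
                   mean_prob=prob.mean(axis=0), sd=prob.std(axis=0, ddof=0))


def autocorrelation(chain: np.ndarray, max_lag: int) -> np.ndarray:
    """Sample autocorrelation at lags 0..max_lag (biased normalisation)."""
    chain = np.asarray(chain, dtype=float)
    n = len(chain)
    x = chain - chain.mean()
    var = float(x @ x)
    if var == 0.0:
        raise ValueError("constant chain: autocorrelation undefined")
    max_lag = min(max_lag, n - 1)
    return np.array([(x[: n - k] @ x[k:]) / var for k in range(max_lag + 1)])


def effective_sample_size(chain: np.ndarray) -> float:
    """ESS via Geyer's initial-positive-sequence truncation.

    Successive autocorrelation pairs Gamma_t = rho_{2t} + rho_{2t+1} are
    summed while positive; ESS = n / (1 + 2 sum rho).
    """
    n = len(chain)
    rho = autocorrelation(chain, max_lag=n - 1)
    s = 0.0
    t = 1
    while t + 1 < len(rho):
        gamma = rho[t] + rho[t + 1]
        if gamma <= 0:
            break
        s += gamma
        t += 2
    return n / (1.0 + 2.0 * s)


def diagnostics(samples: PosteriorSamples, label: str,
                max_lag: int = 50) -> tuple[np.ndarray, np.ndarray, float]:
    """Trace, autocorrelation-by-lag and ESS for one labelled parameter."""
    chain = samples.chain(label)
    acf = autocorrelation(chain, max_lag)
    return chain, acf, effective_sample_size(chain)


def diagnostics_table(samples: PosteriorSamples,
                      labels: list[str] | None = None,
                      max_lag: int = 20) -> pd.DataFrame:
    if labels is None:
        labels = list(samples.labels["fixed"]) + sorted(samples.variances)
    rows = []
    for label in labels:
        chain, acf, ess = diagnostics(samples, label, max_lag=max_lag)
        rows.append({"label": label, "mean": float(chain.mean()),
                     "sd": float(chain.std(ddof=1)),
                     "acf_lag1": float(acf[1]) if len(acf) > 1 else np.nan,
                     "ess": ess})
    return pd.DataFrame(rows)


def plot_smooth(est: SmoothEstimate, ax=None):
    """Line plot of a smooth effect with dashed 95% credible band."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(est.grid, est.mean, color="C0")
    ax.plot(est.grid, est.lower, "--", color="C0", alpha=0.7)
    ax.plot(est.grid, est.upper, "--", color="C0", alpha=0.7)
    ax.axhline(0.0, color="grey", lw=0.5)
    ax.set_xlabel(est.name)
    ax.set_ylabel(f"f({est.name})")
    return ax


def plot_risk_map(risk: RiskMap, ax=None, what: str = "mean"):
    """Bar rendering of the per-region risk (or SD) surface."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    values = risk.mean_prob if what == "mean" else risk.sd
    ax.bar([str(r) for r in risk.region_ids], values, color="C3", alpha=0.8)
    ax.set_xlabel("region")
    ax.set_ylabel("posterior mean risk" if what == "mean" else "posterior SD")
    return ax
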