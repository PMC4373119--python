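import numpy as np
import pandas as pd
import pytest

from geostar.data import FactorSpec, ObservationTable
from geostar.model import MCMCConfig, PosteriorSamples
from geostar.spatial import NeighborhoodGraph


@pytest.fixture
def path_graph() -> NeighborhoodGraph:
    """Three regions in a path: 1 - 2 - 3."""
    return NeighborhoodGraph(
        regions=[1, 2, 3],
        neighbors={1: {2}, 2: {1, 3}, 3: {2}},
    )


@pytest.fixture
def small_table() -> ObservationTable:
    rng = np.random.default_rng(5)
    n = 60
    return ObservationTable(
        outcome=rng.integers(0, 2, n),
        categorical=pd.DataFrame({
            "residence": rng.choice(["urban", "rural"], n),
            "wealth": rng.choice(["poorest", "middle", "richest"], n),
        }),
        continuous=pd.DataFrame({"mother_age": rng.uniform(15, 49, n)}),
        region_id=rng.choice([1, 2, 3], n),
    )


@pytest.fixture
def factor_specs() -> list[FactorSpec]:
    return [
        FactorSpec("residence", ("urban", "rural")),
        FactorSpec("wealth", ("poorest", "middle", "richest")),
    ]


def make_samples(fixed_draws: np.ndarray,
                 labels: list[str] | None = None,
                 f_str: np.ndarray | None = None,
                 f_unstr: np.ndarray | None = None,
                 smooth: tuple[str, np.ndarray, dict] | None = None,
                 ) -> PosteriorSamples:
    """Assemble a PosteriorSamples object from raw draw arrays."""
    fixed_draws = np.atleast_2d(np.asarray(fixed_draws, float))
    ndraw, p = fixed_draws.shape
    if labels is None:
        labels = ["intercept"] + [f"b{j}" for j in range(1, p)]
    S = 3
    blocks = {
        "fixed": fixed_draws,
        "f_str": np.zeros((ndraw, S)) if f_str is None else f_str,
        "f_unstr": np.zeros((ndraw, S)) if f_unstr is None else f_unstr,
    }
    all_labels = {
        "fixed": labels,
        "f_str": [f"f_str[{r}]" for r in (1, 2, 3)],
        "f_unstr": [f"f_unstr[{r}]" for r in (1, 2, 3)],
    }
    smooth_meta = {}
    if smooth is not None:
        name, draws, meta = smooth
        blocks[f"smooth:{name}"] = draws
        all_labels[f"smooth:{name}"] = [f"{name}:xi[{m}]"
                                        for m in range(draws.shape[1])]
        smooth_meta[name] = meta
    variances = {"tau2_str": np.full(ndraw, 0.1),
                 "tau2_unstr": np.full(ndraw, 0.1)}
    return PosteriorSamples(
        blocks=blocks, variances=variances, labels=all_labels,
        region_ids=np.arange(1, blocks["f_str"].shape[1] + 1),
        config=MCMCConfig(iterations=max(2 * ndraw, 2), burnin=0,
                          thin=max(2 * ndraw, 2) // max(ndraw, 1)),
        smooth_meta=smooth_meta)
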