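"""Survey data ingestion and design-matrix construction.

The observation table holds one row per child: a binary death indicator
(1 = died before age five), categorical covariates, continuous covariates,
and a 1-based region identifier matching a companion neighbourhood graph.
Categorical covariates are expanded to reference-coded dummies (first level
of each :class:`FactorSpec` is the reference, matching the "Ref." convention
of published odds-ratio tables); continuous covariates pass through
untransformed for later spline expansion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FactorSpec:
    """A categorical covariate: ordered levels, first level = reference."""

    name: str
    levels: tuple[str, ...]

    def __post_init__(self) -> None:
        levels = tuple(str(l) for l in self.levels)
        object.__setattr__(self, "levels", levels)
        if len(levels) < 2:
            raise ValueError(f"factor {self.name!r} needs >= 2 levels")
        if len(set(levels)) != len(levels):
            raise ValueError(f"factor {self.name!r} has duplicate levels")

    @property
    def reference(self) -> str:
        return self.levels[0]


@dataclass
class ObservationTable:
    """Validated per-child survey records.

    ``outcome`` is 0/1, ``region_id`` is 1-based, and ``n_dropped`` counts
    rows removed by listwise deletion of missing values at ingestion.
    """

    outcome: np.ndarray
    categorical: pd.DataFrame
    continuous: pd.DataFrame
    region_id: np.ndarray
    n_dropped: int = 0
    weights: np.ndarray | None = None  # read if present, deliberately unused

    def __post_init__(self) -> None:
        self.outcome = np.asarray(self.outcome, dtype=int)
        self.region_id = np.asarray(self.region_id, dtype=int)
        bad = ~np.isin(self.outcome, (0, 1))
        if bad.any():
            idx = int(np.nonzero(bad)[0][0])
            raise ValueError(
                f"outcome must be 0/1; row {idx} has value {self.outcome[idx]}"
            )
        n = len(self.outcome)
        if len(self.categorical) != n or len(self.continuous) != n:
            raise ValueError("covariate frames must match outcome length")
        if len(self.region_id) != n:
            raise ValueError("region_id must match outcome length")

    @property
    def n(self) -> int:
        return len(self.outcome)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"died": self.outcome, "region": self.region_id})
        return pd.concat(
            [df, self.categorical.reset_index(drop=True),
             self.continuous.reset_index(drop=True)], axis=1
        )


@dataclass
class DesignBlocks:
    """Design matrices for one model fit.

    ``fixed`` stacks reference-coded dummy columns in factor-spec order
    (a p-level factor contributes p−1 columns; reference rows are all-zero
    in that factor's columns).  ``incidence`` is the n × S region indicator
    matrix with exactly one 1 per row.
    """

    intercept: np.ndarray
    fixed: np.ndarray
    fixed_labels: list[str]
    continuous: dict[str, np.ndarray]
    incidence: np.ndarray
    region_ids: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def n(self) -> int:
        return len(self.intercept)


def read_observation_table(
    path,
    factor_specs: list[FactorSpec],
    continuous_names: list[str],
    graph=None,
    outcome_col: str = "died",
    region_col: str = "region",
) -> ObservationTable:
    """Read and validate a survey CSV.

    Rows with any missing required field are removed (listwise deletion)
    and the removal count is logged and recorded on the table.  If a
    :class:`~geostar.spatial.NeighborhoodGraph` is supplied, every region
    id must be present in it.
    """
    df = pd.read_csv(path)
    required = [outcome_col, region_col] + [f.name for f in factor_specs] + list(
        continuous_names
    )
    for col in required:
        if col not in df.columns:
            raise ValueError(f"required column {col!r} missing from {path}")

    n_raw = len(df)
    df = df.dropna(subset=required).reset_index(drop=True)
    n_dropped = n_raw - len(df)
    if n_dropped:
        logger.info("dropped %d row(s) with missing values", n_dropped)

    outcome = df[outcome_col].to_numpy()
    if not np.isin(outcome, (0, 1)).all():
        idx = int(np.nonzero(~np.isin(outcome, (0, 1)))[0][0])
        raise ValueError(f"outcome value outside {{0,1}} at row {idx}")

    region = df[region_col].astype(int).to_numpy()
    if graph is not None:
        known = set(graph.regions)
        unknown = sorted(set(region) - known)
        if unknown:
            raise ValueError(f"region id(s) {unknown} absent from the graph")

    table = ObservationTable(
        outcome=outcome,
        categorical=df[[f.name for f in factor_specs]].astype(str),
        continuous=df[list(continuous_names)].astype(float),
        region_id=region,
        n_dropped=n_dropped,
        weights=df["weight"].to_numpy(float) if "weight" in df.columns else None,
    )
    return table


def encode_design(
    table: ObservationTable,
    factor_specs: list[FactorSpec],
    continuous_names: list[str],
    regions: list[int] | None = None,
) -> DesignBlocks:
    """Build the fixed-effect, continuous and region-incidence blocks.

    ``regions`` fixes the region column ordering (defaults to the sorted
    region ids observed in the table); pass the graph's region list so the
    incidence matrix covers unobserved regions too.
    """
    n = table.n
    cols: list[np.ndarray] = []
    labels: list[str] = []
    for spec in factor_specs:
        observed = table.categorical[spec.name].astype(str)
        extra = sorted(set(observed) - set(spec.levels))
        if extra:
            raise ValueError(
                f"factor {spec.name!r}: observed level(s) {extra} absent from spec"
            )
        for level in spec.levels[1:]:
            cols.append((observed == level).to_numpy(dtype=float))
            labels.append(f"{spec.name}[{level}]")
    fixed = np.column_stack(cols) if cols else np.empty((n, 0))

    if regions is None:
        regions = sorted(np.unique(table.region_id).tolist())
    region_index = {r: j for j, r in enumerate(regions)}
    incidence = np.zeros((n, len(regions)))
    for i, r in enumerate(table.region_id):
        incidence[i, region_index[int(r)]] = 1.0

    return DesignBlocks(
        intercept=np.ones(n),
        fixed=fixed,
        fixed_labels=labels,
        continuous={name: table.continuous[name].to_numpy(float)
                    for name in continuous_names},
        incidence=incidence,
        region_ids=np.asarray(regions, dtype=int),
    )
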