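"""Region neighbourhood structure and intrinsic GMRF machinery.

The structured spatial effect f_str carries an intrinsic Gaussian Markov
random field prior: conditionally on its neighbours, a region's effect is
Gaussian with mean the neighbour average and variance tau_str^2 / N_s,
where N_s is the neighbour count.  Jointly this is the improper density
proportional to exp(-f' K f / (2 tau_str^2)) with K the graph structure
matrix (diagonal N_s, off-diagonal -1 for neighbour pairs).  K is rank
deficient — constants per connected component are unpenalised — so draws
are identified by a sum-to-zero constraint.

The unstructured effect f_unstr is i.i.d. mean-zero Gaussian and captures
region heterogeneity with no spatial pattern.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import sparse, stats

logger = logging.getLogger(__name__)


@dataclass
class NeighborhoodGraph:
    """Symmetric region adjacency with 1-based region ids."""

    regions: list[int]
    neighbors: dict[int, set[int]]

    def __post_init__(self) -> None:
        self.regions = [int(r) for r in self.regions]
        self.neighbors = {int(r): {int(v) for v in nb}
                          for r, nb in self.neighbors.items()}
        known = set(self.regions)
        for r in self.regions:
            nb = self.neighbors.setdefault(r, set())
            if r in nb:
                raise ValueError(f"region {r} lists itself as a neighbor")
            for v in nb:
                if v not in known:
                    raise ValueError(f"region {r} lists unknown neighbor {v}")
                if r not in self.neighbors.get(v, set()):
                    raise ValueError(
                        f"asymmetric adjacency: {r} lists {v} but not vice versa"
                    )
        for r in self.regions:
            if not self.neighbors[r]:
                logger.warning("region %d has no neighbors (island)", r)

    @property
    def S(self) -> int:
        return len(self.regions)

    def neighbor_counts(self) -> np.ndarray:
        return np.array([len(self.neighbors[r]) for r in self.regions])

    def index_of(self, region: int) -> int:
        return self.regions.index(int(region))


def read_graph(path) -> NeighborhoodGraph:
    """Parse a plain-text adjacency list.

    One line per region, ``region_id: comma-separated neighbor ids``;
    lines starting with ``#`` are ignored.  The listing must be symmetric
    and self-neighbours are rejected.
    """
    neighbors: dict[int, set[int]] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            head, _, rest = line.partition(":")
            r = int(head.strip())
            nb = {int(tok) for tok in rest.replace(",", " ").split()}
            if r in neighbors:
                raise ValueError(f"region {r} listed twice in {path}")
            neighbors[r] = nb
    regions = sorted(neighbors)
    return NeighborhoodGraph(regions=regions, neighbors=neighbors)


def write_graph(graph: NeighborhoodGraph, path) -> None:
    """Write the adjacency-list format read by :func:`read_graph`."""
    with open(path, "w") as fh:
        fh.write("# region_id: neighbor ids\n")
        for r in graph.regions:
            nb = ",".join(str(v) for v in sorted(graph.neighbors[r]))
            fh.write(f"{r}: {nb}\n")


def knn_graph(coords: np.ndarray, k: int,
              region_ids: list[int] | None = None) -> NeighborhoodGraph:
    """Build a k-nearest-neighbour graph from planar coordinates.

    Each region is linked to its k nearest neighbours by Euclidean
    distance; the edge set is then symmetrised by union so the GMRF
    structure matrix is symmetric (neighbour counts may exceed k).
    Distance ties are broken deterministically by region index order.
    """
    coords = np.asarray(coords, dtype=float)
    S = len(coords)
    if k >= S:
        raise ValueError(f"k={k} must be smaller than the region count S={S}")
    if k < 1:
        raise ValueError("k must be >= 1")
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
    off_diag = ~np.eye(S, dtype=bool)
    if (d2[off_diag] == 0).any():
        raise ValueError("duplicate coordinates")
    if region_ids is None:
        region_ids = list(range(1, S + 1))

    neighbors: dict[int, set[int]] = {r: set() for r in region_ids}
    for i in range(S):
        order = np.lexsort((np.arange(S), d2[i]))  # distance, then index
        nearest = [j for j in order if j != i][:k]
        for j in nearest:
            neighbors[region_ids[i]].add(region_ids[j])
            neighbors[region_ids[j]].add(region_ids[i])  # union symmetrisation
    return NeighborhoodGraph(regions=list(region_ids), neighbors=neighbors)


def structure_matrix(graph: NeighborhoodGraph) -> sparse.csr_matrix:
    """The S × S intrinsic GMRF structure matrix (sparse).

    Diagonal N_s, off-diagonal -1 for neighbour pairs; every row sums to
    zero and the rank is S minus the number of connected components.
    """
    index = {r: j for j, r in enumerate(graph.regions)}
    rows, cols, vals = [], [], []
    for r in graph.regions:
        j = index[r]
        rows.append(j)
        cols.append(j)
        vals.append(float(len(graph.neighbors[r])))
        for v in graph.neighbors[r]:
            rows.append(j)
            cols.append(index[v])
            vals.append(-1.0)
    S = graph.S
    return sparse.csr_matrix((vals, (rows, cols)), shape=(S, S))


def conditional_spatial_params(
    region: int, f: np.ndarray, graph: NeighborhoodGraph, tau2_str: float
) -> tuple[float, float]:
    """Full-conditional mean and variance of one region's structured effect.

    mean = average of neighbouring values, variance = tau_str^2 / N_s.
    """
    nb = graph.neighbors[int(region)]
    if not nb:
        raise ValueError(
            f"region {region} has no neighbors; conditional prior undefined "
            "(connect islands manually in the graph file)"
        )
    idx = [graph.index_of(v) for v in sorted(nb)]
    mean = float(np.mean(f[idx]))
    return mean, float(tau2_str) / len(nb)


def sample_gmrf(
    structure: sparse.spmatrix | np.ndarray,
    tau2: float,
    rng: np.random.Generator,
    constraint: bool = True,
) -> np.ndarray:
    """Draw a spatial field from the intrinsic GMRF prior.

    With ``constraint=True`` the draw is from N(0, tau2 * K^+) projected to
    sum to zero (K^+ the Moore–Penrose pseudo-inverse of the structure
    matrix); this is the proper distribution of the intrinsic field under
    the sum-to-zero identifiability constraint.  An unconstrained draw is
    only defined for full-rank structure matrices.
    """
    K = np.asarray(structure.todense() if sparse.issparse(structure) else structure,
                   dtype=float)
    S = K.shape[0]
    w, V = np.linalg.eigh(K)
    tol = 1e-8 * max(w.max(), 1.0)
    positive = w > tol
    if not constraint:
        if not positive.all():
            raise ValueError(
                "unconstrained draw requested on a rank-deficient structure"
            )
        z = rng.standard_normal(S)
        return V @ (np.sqrt(tau2) * z / np.sqrt(w))
    z = rng.standard_normal(int(positive.sum()))
    f = V[:, positive] @ (np.sqrt(tau2) * z / np.sqrt(w[positive]))
    return f - f.mean()  # exact sum-to-zero


def unstructured_prior_logdensity(v: np.ndarray, tau2_unstr: float) -> float:
    """Log density of the i.i.d. N(0, tau_unstr^2) unstructured effects."""
    if tau2_unstr <= 0:
        raise ValueError("tau2_unstr must be positive")
    return float(stats.norm.logpdf(np.asarray(v, float),
                                   scale=np.sqrt(tau2_unstr)).sum())
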