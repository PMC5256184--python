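"""Pearson connectivity matrices and density-thresholded binary graphs.

A subject's network is built by correlating every pair of cleaned region
signals and binarizing the correlation matrix at a grid of edge densities.
At density d the round(d * N(N-1)/2) strongest connections become edges, so
the resulting adjacency stack is nested: every edge present at a lower
density survives at all higher densities.  Thresholding keeps the largest
signed correlations by default (an ``absolute`` switch ranks |r| instead),
and depends only on the rank order of the weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .preprocess import RoiTimeSeries

SYMMETRY_TOL = 1e-12


@dataclass
class ConnectivityMatrix:
    """Symmetric N x N Pearson correlation matrix with zero diagonal."""

    subject_id: str
    node_labels: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        n = len(self.node_labels)
        if self.r.shape != (n, n):
            raise ValueError(f"expected {n}x{n} matrix, got {self.r.shape}")
        if np.abs(self.r - self.r.T).max(initial=0.0) > SYMMETRY_TOL:
            raise ValueError("correlation matrix not symmetric")
        if np.abs(np.diag(self.r)).max(initial=0.0) != 0.0:
            raise ValueError("diagonal must be zero")
        if np.abs(self.r).max(initial=0.0) > 1.0 + 1e-12:
            raise ValueError("correlations must lie in [-1, 1]")

    @property
    def n_nodes(self) -> int:
        return self.r.shape[0]


@dataclass(frozen=True)
class DensityGrid:
    """Evenly spaced edge densities, default 0.10 to 0.40 in steps of 0.01
    (31 densities)."""

    start: float = 0.10
    stop: float = 0.40
    step: float = 0.01

    def __post_init__(self) -> None:
        if not (0.0 < self.start <= self.stop < 1.0) or self.step <= 0:
            raise ValueError("require 0 < start <= stop < 1 and step > 0")

    @property
    def densities(self) -> list[float]:
        n = int(round((self.stop - self.start) / self.step)) + 1
        return [round(self.start + i * self.step, 10) for i in range(n)]

    def __len__(self) -> int:
        return len(self.densities)


def edge_count(density: float, n_nodes: int) -> int:
    """Number of undirected edges retained at a density (nearest-integer)."""
    return int(round(density * n_nodes * (n_nodes - 1) / 2))


@dataclass
class AdjacencyStack:
    """Per-density binary symmetric adjacency matrices for one subject.

    ``matrices`` maps density -> N x N uint8 array; edge sets are nested
    across increasing densities.
    """

    subject_id: str
    node_labels: list[str]
    grid: DensityGrid
    matrices: dict[float, np.ndarray] = field(default_factory=dict)

    def __getitem__(self, density: float) -> np.ndarray:
        return self.matrices[density]

    @property
    def densities(self) -> list[float]:
        return self.grid.densities


def correlation_matrix(ts: RoiTimeSeries) -> ConnectivityMatrix:
    """Pairwise Pearson correlations of the region signals, diagonal zeroed.

    Zero-variance regions produce undefined correlations; those rows/columns
    are set to 0 with a warning naming the regions.
    """
    if ts.n_timepoints < 3:
        raise ValueError("need at least 3 time points for correlation")
    dead = np.flatnonzero(np.ptp(ts.values, axis=0) == 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(ts.values, rowvar=False)
    if dead.size:
        warnings.warn(
            "zero-variance node(s) "
            f"{[ts.node_labels[i] for i in dead]}; correlations set to 0",
            stacklevel=2,
        )
        r[dead, :] = 0.0
        r[:, dead] = 0.0
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 0.0)
    return ConnectivityMatrix(ts.subject_id, list(ts.node_labels), r)


def _ranked_pairs(r: np.ndarray, absolute: bool) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle pairs sorted by decreasing weight, ties broken by
    lexicographic (i, j) order for determinism."""
    n = r.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = np.abs(r[iu, ju]) if absolute else r[iu, ju]
    order = np.lexsort((ju, iu, -w))
    return iu[order], ju[order]


def threshold_by_density(
    cm: ConnectivityMatrix, grid: DensityGrid | None = None, absolute: bool = False
) -> AdjacencyStack:
    """Binarize a connectivity matrix at every density of the grid.

    For each density the round(d * N(N-1)/2) top-ranked node pairs become
    edges (signed ranking by default).  Nestedness across densities is a
    consequence of taking prefixes of a single ranking.
    """
    grid = grid or DensityGrid()
    n = cm.n_nodes
    n_pairs = n * (n - 1) // 2
    k_max = edge_count(grid.densities[-1], n)
    if k_max > n_pairs:
        raise ValueError(
            f"density {grid.densities[-1]} requests {k_max} edges but only "
            f"{n_pairs} pairs exist"
        )
    iu, ju = _ranked_pairs(cm.r, absolute)
    stack = AdjacencyStack(cm.subject_id, list(cm.node_labels), grid)
    for d in grid.densities:
        k = edge_count(d, n)
        a = np.zeros((n, n), dtype=np.uint8)
        a[iu[:k], ju[:k]] = 1
        a |= a.T
        stack.matrices[d] = a
    return stack


def mean_connectivity(
    matrices: list[ConnectivityMatrix], subject_id: str = "group_mean"
) -> ConnectivityMatrix:
    """Element-wise mean of connectivity matrices sharing one label set."""
    if len(matrices) < 1:
        raise ValueError("need at least one matrix")
    labels = matrices[0].node_labels
    for m in matrices[1:]:
        if m.node_labels != labels:
            raise ValueError(
                f"node label mismatch between {matrices[0].subject_id} "
                f"and {m.subject_id}"
            )
    mean_r = np.mean([m.r for m in matrices], axis=0)
    np.fill_diagonal(mean_r, 0.0)
    return ConnectivityMatrix(subject_id, list(labels), mean_r)
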