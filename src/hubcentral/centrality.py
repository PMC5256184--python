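"""Nodal centrality metrics and modularity partitions of binary graphs.

Four complementary node-importance measures are computed on each binary
adjacency matrix:

* degree ``K_i = sum_j a_ij`` — number of incident edges;
* betweenness ``B_i = sum_{h!=j!=i} sigma_hj(i) / sigma_hj`` — summed
  fraction of shortest paths passing through i, counted over ordered pairs
  (so a path-graph midpoint scores 2, not 1); unreachable pairs contribute 0;
* within-module degree ``Z_i`` — z-score of i's intra-module degree against
  the intra-module degree distribution of its own module (population sd;
  Z = 0 when the sd is 0);
* participation coefficient ``P_i = 1 - sum_m (K_im / K_i)^2`` — 0 for a
  provincial node, approaching 1 for a connector hub spreading its edges
  uniformly over modules (P = 0 for isolated nodes).

Z and P require a module partition; partitions are found by maximizing
Newman modularity Q with Louvain restarts — the best Q over ``n_restarts``
randomized runs (default 100) is kept, recomputed independently at every
density because the graphs differ.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .graphs import AdjacencyStack, ConnectivityMatrix, DensityGrid
from .graphs import threshold_by_density

METRICS = ("degree", "betweenness", "within_module_degree", "participation")

DEFAULT_N_RESTARTS = 100


@dataclass
class Partition:
    """Node-to-module assignment with its Newman modularity Q."""

    labels: np.ndarray  # module id 1..M per node
    q: float
    n_restarts_used: int
    seed: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.min(initial=1) < 1:
            raise ValueError("module labels must start at 1")
        if not -1.0 <= self.q <= 1.0:
            raise ValueError(f"modularity {self.q} outside [-1, 1]")

    @property
    def n_modules(self) -> int:
        return len(np.unique(self.labels))


def _as_adj(adj: np.ndarray) -> np.ndarray:
    a = np.asarray(adj)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.array_equal(a, a.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.diag(a) != 0):
        raise ValueError("adjacency must have zero diagonal")
    if not np.isin(a, (0, 1)).all():
        raise ValueError("adjacency must be binary")
    return a.astype(np.int64)


def degree(adj: np.ndarray) -> np.ndarray:
    """Per-node degree K (row sums of the binary adjacency)."""
    return _as_adj(adj).sum(axis=1)


def betweenness(adj: np.ndarray, normalized: bool = False) -> np.ndarray:
    """Per-node betweenness over ordered node pairs.

    With ``normalized`` the values are divided by (N-1)(N-2), the number of
    ordered pairs excluding the node itself.
    """
    a = _as_adj(adj)
    g = nx.from_numpy_array(a)
    bc = nx.betweenness_centrality(g, normalized=False)
    # networkx sums over unordered pairs for undirected graphs; double to
    # count ordered pairs (h, j) and (j, h).
    b = 2.0 * np.array([bc[i] for i in range(a.shape[0])])
    if normalized:
        n = a.shape[0]
        if n > 2:
            b = b / ((n - 1) * (n - 2))
    return b


def best_partition(
    adj: np.ndarray, n_restarts: int = DEFAULT_N_RESTARTS, seed: int = 0
) -> Partition:
    """Max-Q module partition over Louvain restarts.

    Each restart runs Louvain with its own RNG seed (drawn sequentially from
    ``seed``, so increasing ``n_restarts`` extends — never changes — the
    restart stream) and the partition with the largest Newman Q wins.
    An edgeless graph yields a single module with Q defined as 0.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    a = _as_adj(adj)
    n = a.shape[0]
    g = nx.from_numpy_array(a)
    if g.number_of_edges() == 0:
        warnings.warn("edgeless graph: single-module partition, Q=0",
                      stacklevel=2)
        return Partition(np.ones(n, dtype=int), 0.0, n_restarts, seed)
    rng = np.random.default_rng(seed)
    best_q, best_comms = -np.inf, None
    for _ in range(n_restarts):
        s = int(rng.integers(0, 2**31 - 1))
        comms = nx.community.louvain_communities(g, seed=s)
        q = nx.community.modularity(g, comms)
        if q > best_q:
            best_q, best_comms = q, comms
    labels = np.empty(n, dtype=int)
    for m, comm in enumerate(best_comms, start=1):
        labels[list(comm)] = m
    return Partition(labels, float(best_q), n_restarts, seed)


def within_module_degree(adj: np.ndarray, partition: Partition) -> np.ndarray:
    """Z-score of intra-module degree within each node's own module."""
    a = _as_adj(adj)
    labels = partition.labels
    if labels.shape[0] != a.shape[0]:
        raise ValueError("partition does not cover all nodes")
    z = np.zeros(a.shape[0], dtype=float)
    for m in np.unique(labels):
        idx = np.flatnonzero(labels == m)
        kin = a[np.ix_(idx, idx)].sum(axis=1).astype(float)
        sd = kin.std()  # population sd over the module
        if sd > 0:
            z[idx] = (kin - kin.mean()) / sd
    return z


def participation_coefficient(adj: np.ndarray, partition: Partition) -> np.ndarray:
    """P_i = 1 - sum_m (K_im / K_i)^2, with P_i = 0 for isolated nodes."""
    a = _as_adj(adj)
    labels = partition.labels
    if labels.shape[0] != a.shape[0]:
        raise ValueError("partition does not cover all nodes")
    k = a.sum(axis=1).astype(float)
    p = np.zeros(a.shape[0], dtype=float)
    nz = k > 0
    frac_sq = np.zeros(a.shape[0], dtype=float)
    for m in np.unique(labels):
        kim = a[:, labels == m].sum(axis=1).astype(float)
        frac_sq[nz] += (kim[nz] / k[nz]) ** 2
    p[nz] = 1.0 - frac_sq[nz]
    return p


@dataclass
class CentralityProfile:
    """All four metrics per node per density plus per-density modularity.

    ``values`` is long format (node, density, metric, value); the
    density-averaged profile (the quantity entering clinical correlations)
    is derived by :meth:`density_averaged`.
    """

    subject_id: str
    node_labels: list[str]
    grid: DensityGrid
    values: pd.DataFrame
    modularity: dict[float, float] = field(default_factory=dict)
    partitions: dict[float, Partition] = field(default_factory=dict)

    def density_averaged(self) -> pd.DataFrame:
        """Node x metric table of values averaged across all densities."""
        wide = self.values.pivot_table(
            index="node", columns="metric", values="value", aggfunc="mean"
        )
        return wide.reindex(index=self.node_labels, columns=list(METRICS))

    def metric_matrix(self, metric: str) -> pd.DataFrame:
        """Node x density table for one metric."""
        if metric not in METRICS:
            raise KeyError(f"unknown metric {metric!r}")
        sub = self.values[self.values["metric"] == metric]
        return sub.pivot(index="node", columns="density", values="value").reindex(
            index=self.node_labels
        )


def profile_subject(
    stack: AdjacencyStack,
    n_restarts: int = DEFAULT_N_RESTARTS,
    seed: int = 0,
) -> CentralityProfile:
    """Compute the full centrality profile of one subject's adjacency stack.

    Per density: find the max-Q partition, then evaluate all four metrics on
    that density's graph alone.
    """
    records = []
    modularity: dict[float, float] = {}
    partitions: dict[float, Partition] = {}
    rng = np.random.default_rng(seed)
    for d in stack.densities:
        a = stack[d]
        part = best_partition(a, n_restarts, int(rng.integers(0, 2**31 - 1)))
        vals = {
            "degree": degree(a).astype(float),
            "betweenness": betweenness(a),
            "within_module_degree": within_module_degree(a, part),
            "participation": participation_coefficient(a, part),
        }
        modularity[d] = part.q
        partitions[d] = part
        for metric, arr in vals.items():
            for node, v in zip(stack.node_labels, arr):
                records.append(
                    {"node": node, "density": d, "metric": metric,
                     "value": float(v)}
                )
    values = pd.DataFrame.from_records(records)
    return CentralityProfile(
        stack.subject_id, list(stack.node_labels), stack.grid, values,
        modularity, partitions,
    )


@dataclass
class GroupNetworkSummary:
    """Module structure of a group-average network at one density, with each
    query node's neighbors split into same-module vs other-module lists."""

    density: float
    partition: Partition
    node_labels: list[str]
    neighbors: dict[str, dict[str, list[str]]]

    def n_intermodular(self, node: str) -> int:
        return len(self.neighbors[node]["other_module"])


def group_network_modules(
    matrices: list[ConnectivityMatrix],
    density: float = 0.30,
    query_nodes: list[str] | None = None,
    n_restarts: int = DEFAULT_N_RESTARTS,
    seed: int = 0,
) -> GroupNetworkSummary:
    """Average connectivity matrices, threshold at one density, partition,
    and report each query node's intra- vs inter-module links.

    This is the group-level summary used to ask which modules a putative
    hub reaches: in a healthy-control average the thalamus typically links
    only within its own module, while a tremor-dominant average shows it
    connecting into other modules.
    """
    if len(matrices) < 2:
        raise ValueError("need at least 2 matrices for a group average")
    from .graphs import mean_connectivity

    mean_cm = mean_connectivity(matrices)
    grid = DensityGrid(density, density, 1.0)
    stack = threshold_by_density(mean_cm, grid)
    a = stack[grid.densities[0]]
    part = best_partition(a, n_restarts, seed)
    labels = mean_cm.node_labels
    query = query_nodes if query_nodes is not None else labels
    neighbors: dict[str, dict[str, list[str]]] = {}
    for qn in query:
        if qn not in labels:
            raise KeyError(f"query node {qn!r} not in node labels")
        i = labels.index(qn)
        nbr = np.flatnonzero(a[i])
        same = [labels[j] for j in nbr if part.labels[j] == part.labels[i]]
        other = [labels[j] for j in nbr if part.labels[j] != part.labels[i]]
        neighbors[qn] = {"same_module": same, "other_module": other}
    return GroupNetworkSummary(density, part, list(labels), neighbors)
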