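"""Density thresholding and binary graph topology.

Association matrices are binarized by keeping the k strongest edges, with
k = round(d * N(N-1)/2) at density d.  Thresholding by largest signed
correlation (positive edges first) follows structural-covariance
convention; negative edges are only admitted when a density demands more
edges than there are positive correlations (with a warning).  Because the
same edge ranking serves every density, edge sets are nested along the
grid, which makes degree curves monotone and lets the permutation engine
binarize a whole grid from one sort.

Metrics are implemented directly on adjacency arrays (the permutation
engine evaluates them tens of thousands of times); networkx and exhaustive
enumeration serve as independent oracles in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components, shortest_path

GLOBAL_METRICS = ("path_length", "global_efficiency", "clustering", "small_worldness")
NODAL_METRICS = ("degree", "betweenness", "clustering")


@dataclass(frozen=True)
class DensityGrid:
    """Ordered density grid [d_min, d_max] in fixed steps (default 2%)."""

    d_min: float
    d_max: float
    step: float = 0.02

    def __post_init__(self) -> None:
        if not (0 < self.d_min <= self.d_max <= 1):
            raise ValueError(f"invalid density bounds ({self.d_min}, {self.d_max}]")
        if self.step <= 0:
            raise ValueError("step must be positive")

    @property
    def densities(self) -> np.ndarray:
        n = int(np.floor((self.d_max - self.d_min) / self.step + 1e-9)) + 1
        return self.d_min + self.step * np.arange(n)

    def __len__(self) -> int:
        return len(self.densities)


@dataclass
class MetricCurve:
    """One topology metric as a function of density (the FDA unit of analysis)."""

    metric: str
    scope: str  # node name or "global"
    densities: np.ndarray
    values: np.ndarray


@dataclass
class AdjacencyStack:
    group: str
    grid: DensityGrid
    adjacency: list[np.ndarray]

    @property
    def edge_counts(self) -> list[int]:
        return [int(A.sum()) // 2 for A in self.adjacency]


@dataclass
class HubReport:
    hubs: list[str]
    criterion: str
    degrees: dict[str, float] = field(default_factory=dict)


def edge_count_at_density(n_nodes: int, d: float) -> int:
    """k = round(d * N(N-1)/2), half rounded away from zero."""
    if not (0 < d <= 1):
        raise ValueError(f"density must be in (0, 1], got {d}")
    return int(np.floor(d * n_nodes * (n_nodes - 1) / 2 + 0.5))


def rank_edges(weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Edge endpoints (i, j), i<j, ordered by descending weight.

    Ties break by (row, column) lexicographic order of node indices, so the
    ranking — and every thresholded graph — is deterministic.
    """
    W = np.asarray(weights, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("weights must be a square matrix")
    if not np.allclose(W, W.T, atol=1e-10):
        raise ValueError("weights must be symmetric")
    ii, jj = np.triu_indices(W.shape[0], k=1)
    order = np.lexsort((jj, ii, -W[ii, jj]))
    return ii[order], jj[order]


def binarize_at_density(weights: np.ndarray, d: float) -> np.ndarray:
    """Binary adjacency keeping the k largest-weight edges at density d."""
    W = np.asarray(weights, dtype=float)
    n = W.shape[0]
    k = edge_count_at_density(n, d)
    ii, jj = rank_edges(W)
    if k > 0 and W[ii[k - 1], jj[k - 1]] < 0:
        warnings.warn(
            f"density {d:.3f} admits negative-weight edges "
            f"({int((W[ii[:k], jj[:k]] < 0).sum())} of {k})",
            stacklevel=2,
        )
    A = np.zeros((n, n), dtype=np.int8)
    A[ii[:k], jj[:k]] = 1
    return A | A.T


def adjacency_stack(weights: np.ndarray, grid: DensityGrid, group: str = "") -> AdjacencyStack:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mats = [binarize_at_density(weights, d) for d in grid.densities]
    return AdjacencyStack(group=group, grid=grid, adjacency=mats)


def is_connected(adjacency: np.ndarray) -> bool:
    n_comp, _ = connected_components(np.asarray(adjacency), directed=False)
    return n_comp == 1


def find_dmin(weight_matrices: list[np.ndarray], step: float = 0.02) -> float:
    """Smallest grid-aligned density at which every group's graph is connected."""
    if not weight_matrices:
        raise ValueError("need at least one weight matrix")
    n = weight_matrices[0].shape[0]
    ranked = [rank_edges(W) for W in weight_matrices]
    for m in range(1, int(np.ceil(1.0 / step)) + 1):
        d = m * step
        k = edge_count_at_density(n, min(d, 1.0))
        ok = True
        for ii, jj in ranked:
            A = np.zeros((n, n), dtype=np.int8)
            A[ii[:k], jj[:k]] = 1
            if not is_connected(A | A.T):
                ok = False
                break
        if ok:
            return float(round(d, 10))
    raise ValueError("no density <= 1 connects all groups")


# ---------------------------------------------------------------------------
# metrics


def nodal_degree(adjacency: np.ndarray) -> np.ndarray:
    A = np.asarray(adjacency)
    return A.sum(axis=1).astype(int)


def nodal_betweenness(adjacency: np.ndarray) -> np.ndarray:
    """Unnormalized betweenness: pair-counts of shortest paths through each node.

    Brandes' accumulation on the unweighted graph; each unordered pair
    {s, t} contributes the fraction of its shortest paths passing through
    the node (a 4-node star's center scores C(3,2) = 3).
    """
    A = np.asarray(adjacency, dtype=bool)
    n = A.shape[0]
    neighbors = [np.flatnonzero(A[v]) for v in range(n)]
    bc = np.zeros(n)
    for s in range(n):
        stack: list[int] = []
        preds: list[list[int]] = [[] for _ in range(n)]
        sigma = np.zeros(n)
        sigma[s] = 1.0
        dist = np.full(n, -1)
        dist[s] = 0
        queue = [s]
        while queue:
            v = queue.pop(0)
            stack.append(v)
            for w in neighbors[v]:
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        delta = np.zeros(n)
        while stack:
            w = stack.pop()
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    return bc / 2.0  # undirected: each pair counted twice


def _pairwise_distances(adjacency: np.ndarray) -> np.ndarray:
    A = np.asarray(adjacency, dtype=float)
    return shortest_path(A, method="D", unweighted=True, directed=False)


def characteristic_path_length(adjacency: np.ndarray) -> tuple[float, bool]:
    """Mean shortest-path length over connected ordered pairs.

    Returns (value, fully_connected). For disconnected graphs the mean is
    restricted to connected pairs and the flag is False; an edgeless graph
    yields nan.
    """
    D = _pairwise_distances(adjacency)
    n = D.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(D) & off
    connected = bool(finite.sum() == n * (n - 1))
    if finite.sum() == 0:
        return float("nan"), False
    return float(D[finite].mean()), connected


def global_efficiency(adjacency: np.ndarray) -> float:
    """Mean inverse shortest-path length over pairs; disconnected pairs contribute 0."""
    D = _pairwise_distances(adjacency)
    n = D.shape[0]
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(D) & (D > 0), 1.0 / D, 0.0)
    return float(inv[off].mean())


def clustering_coefficient(adjacency: np.ndarray) -> tuple[np.ndarray, float]:
    """Binary local clustering per node and its global (mean) value."""
    A = np.asarray(adjacency, dtype=float)
    k = A.sum(axis=1)
    triangles = np.einsum("ij,jk,ki->i", A, A, A)  # 2 * triangles through each node
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        local = np.where(denom > 0, triangles / denom, 0.0)
    return local, float(local.mean())


def small_worldness(
    adjacency: np.ndarray, c_rand: float, l_rand: float
) -> float:
    """sigma = (C / C_rand) / (L / L_rand) against matched null summaries."""
    if c_rand <= 0 or l_rand <= 0:
        raise ValueError("null clustering and path length must be positive")
    _, c = clustering_coefficient(adjacency)
    length, _ = characteristic_path_length(adjacency)
    if not np.isfinite(length) or length <= 0:
        return float("nan")
    return (c / c_rand) / (length / l_rand)


def identify_hubs(degree: dict[str, float], k_sd: float = 2.0) -> HubReport:
    """Nodes whose degree exceeds mean + k_sd * SD across nodes."""
    names = list(degree)
    vals = np.array([degree[n] for n in names], dtype=float)
    cut = vals.mean() + k_sd * vals.std()
    hubs = [n for n, v in zip(names, vals) if v > cut]
    return HubReport(
        hubs=hubs,
        criterion=f"degree > mean + {k_sd:g}*SD (cut={cut:.3f})",
        degrees=dict(zip(names, vals.tolist())),
    )


# ---------------------------------------------------------------------------
# curves


def _metric_values(A: np.ndarray, metric: str) -> np.ndarray | float:
    if metric == "degree":
        return nodal_degree(A).astype(float)
    if metric == "betweenness":
        return nodal_betweenness(A)
    if metric == "path_length":
        return characteristic_path_length(A)[0]
    if metric == "global_efficiency":
        return global_efficiency(A)
    if metric == "clustering":
        return clustering_coefficient(A)[1]
    raise ValueError(f"unknown metric {metric!r}")


def metric_curves(
    weights: np.ndarray,
    grid: DensityGrid,
    metrics: tuple[str, ...] = ("degree",),
    node_names: list[str] | None = None,
) -> list[MetricCurve]:
    """Evaluate metrics at every grid density on the thresholded graphs.

    Per-node metrics (degree, betweenness) yield one curve per node;
    the rest yield a single "global" curve.
    """
    n = weights.shape[0]
    names = node_names if node_names is not None else [str(i) for i in range(n)]
    densities = grid.densities
    stack = adjacency_stack(weights, grid)
    per_node = {m: np.zeros((n, len(densities))) for m in metrics if m in ("degree", "betweenness")}
    global_vals = {m: np.zeros(len(densities)) for m in metrics if m not in per_node}
    for t, A in enumerate(stack.adjacency):
        for m in per_node:
            per_node[m][:, t] = _metric_values(A, m)
        for m in global_vals:
            global_vals[m][t] = _metric_values(A, m)
    curves: list[MetricCurve] = []
    for m, mat in per_node.items():
        for i, name in enumerate(names):
            curves.append(MetricCurve(m, name, densities.copy(), mat[i].copy()))
    for m, vals in global_vals.items():
        curves.append(MetricCurve(m, "global", densities.copy(), vals))
    return curves
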