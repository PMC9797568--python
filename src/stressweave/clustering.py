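"""Markov clustering (MCL) of the enhanced graph, modularity, and cluster
selection.

MCL simulates flow on the graph: a column-stochastic transition matrix is
alternately *expanded* (matrix power — flow spreads along walks) and
*inflated* (entrywise power followed by renormalization — strong currents
are reinforced, weak ones starved) until the process reaches an attractor
structure from which clusters are read. Inflation r > 1 controls
granularity: larger r yields finer clusters. The inflation is tuned by
maximizing Newman's weighted modularity Q of the resulting partition.

Cluster post-processing mirrors the study design: per-cluster fold-change
quartiles are computed, clusters are labelled up/down/mixed from the sign
of non-outlier members (outliers = beyond 1.5 x IQR whiskers), and a
cluster is selected for downstream characterization only if it has more
than ``min_size`` genes and its whisker-trimmed fold changes all lie
strictly on one side of zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import ParameterError

logger = logging.getLogger(__name__)

_EPS = 1e-9  # attractor / support detection floor


@dataclass(frozen=True)
class MCLConfig:
    expansion: int = 2
    inflation: float = 2.0
    pruning: float = 1e-5
    max_iterations: int = 200
    tolerance: float = 1e-8
    weight: str | None = "enhanced_score"  # None = binary topology

    def __post_init__(self) -> None:
        if int(self.expansion) != self.expansion or self.expansion < 2:
            raise ParameterError("expansion must be an integer >= 2")
        if self.inflation <= 1:
            raise ParameterError("inflation must exceed 1")
        if not 0 <= self.pruning <= 0.01:
            raise ParameterError("pruning threshold must lie in [0, 0.01]")
        if self.tolerance <= 0:
            raise ParameterError("tolerance must be positive")


@dataclass
class ClusterStats:
    size: int
    median: float
    q1: float
    q3: float
    iqr: float
    direction: str  # up | down | mixed


@dataclass
class ClusterSolution:
    """A hard partition of graph nodes with bookkeeping.

    ``partition`` maps gene -> cluster id (0..k-1, ids ordered by
    decreasing size then lexicographically smallest member). ``stats`` is
    filled when node fold changes are available.
    """

    partition: dict[str, int]
    inflation: float
    modularity: float | None = None
    converged: bool = True
    stats: dict[int, ClusterStats] = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(set(self.partition.values()))

    def members(self, cluster_id: int) -> list[str]:
        return sorted(g for g, c in self.partition.items() if c == cluster_id)

    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for g, c in self.partition.items():
            out.setdefault(c, []).append(g)
        return {c: sorted(v) for c, v in out.items()}


def _stochastic_matrix(graph: nx.Graph, weight: str | None) -> tuple[np.ndarray, list]:
    nodes = sorted(graph.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    m = np.zeros((n, n))
    for u, v, data in graph.edges(data=True):
        if u == v:
            continue
        w = 1.0 if weight is None else float(data.get(weight, 1.0))
        if w < 0:
            raise ParameterError("edge weights must be non-negative")
        m[idx[u], idx[v]] = w
        m[idx[v], idx[u]] = w
    # self-loops: standard MCL stabilization; weight = max incident weight
    # so the loop never dominates, 1.0 for isolated nodes
    for i in range(n):
        col_max = m[:, i].max() if n else 0.0
        m[i, i] = col_max if col_max > 0 else 1.0
    return m / m.sum(axis=0, keepdims=True), nodes


def _inflate(m: np.ndarray, r: float, pruning: float) -> np.ndarray:
    m = np.power(m, r)
    if pruning > 0:
        # never prune a column's largest entry (keeps columns stochastic)
        keep = m >= pruning
        keep[m.argmax(axis=0), np.arange(m.shape[1])] = True
        m = np.where(keep, m, 0.0)
    return m / m.sum(axis=0, keepdims=True)


def _read_clusters(m: np.ndarray, nodes: list) -> dict:
    """Interpret the limit matrix: attractors have positive diagonal; an
    attractor's cluster is the set of nodes it attracts. Attractors that
    attract one another form one attractor system (one cluster)."""
    n = len(nodes)
    attractors = [i for i in range(n) if m[i, i] > _EPS]
    if not attractors:  # degenerate; fall back to support components
        attractors = list(range(n))
    parent = {a: a for a in attractors}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a in attractors:
        for b in attractors:
            if a < b and (m[a, b] > _EPS or m[b, a] > _EPS):
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[rb] = ra
    systems: dict[int, set[int]] = {}
    for a in attractors:
        systems.setdefault(find(a), set()).add(a)
    clusters = {root: set(members) for root, members in systems.items()}

    attracted_by = {root: set() for root in clusters}
    for j in range(n):
        if j in parent and find(j) in clusters and j in clusters[find(j)]:
            continue
        cands = {find(a) for a in attractors if m[a, j] > _EPS}
        if not cands:
            clusters[j] = {j}  # orphan: own singleton cluster
            attracted_by[j] = set()
            continue
        if len(cands) > 1:
            # tie-break: larger attractor system, then smallest member label
            cands = sorted(
                cands,
                key=lambda r: (-len(clusters[r]), min(str(nodes[i]) for i in clusters[r])),
            )
            root = cands[0]
        else:
            root = next(iter(cands))
        attracted_by.setdefault(root, set()).add(j)
    out = {}
    for root, members in clusters.items():
        out[root] = members | attracted_by.get(root, set())
    return out


def _canonical_partition(raw: dict, nodes: list) -> dict:
    groups = sorted(
        (sorted(str(nodes[i]) for i in members) for members in raw.values()),
        key=lambda g: (-len(g), g[0]),
    )
    return {gene: cid for cid, group in enumerate(groups) for gene in group}


def mcl(graph: nx.Graph, config: MCLConfig = MCLConfig()) -> ClusterSolution:
    """Run Markov clustering; returns the partition (stats unfilled).

    Columns of the flow matrix remain stochastic (sum 1 +/- 1e-9) after
    every step. Non-convergence within ``max_iterations`` yields a
    best-effort partition flagged ``converged=False`` with a warning.
    """
    if graph.number_of_nodes() == 0:
        raise ParameterError("cannot cluster an empty graph")
    m, nodes = _stochastic_matrix(graph, config.weight)
    converged = False
    for _ in range(config.max_iterations):
        prev = m
        m = np.linalg.matrix_power(m, config.expansion)
        m = _inflate(m, config.inflation, config.pruning)
        assert np.allclose(m.sum(axis=0), 1.0, atol=1e-9)
        if np.abs(m - prev).max() < config.tolerance:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"MCL did not converge in {config.max_iterations} iterations; "
            "returning best-effort partition",
            stacklevel=2,
        )
    raw = _read_clusters(m, nodes)
    partition = _canonical_partition(raw, nodes)
    return ClusterSolution(
        partition=partition, inflation=config.inflation, converged=converged
    )


def modularity(graph: nx.Graph, partition: dict[str, int]) -> float:
    """Weighted Newman modularity Q of *partition* on *graph*.

    Q = (1/2m) sum_ij [A_ij - k_i k_j / 2m] delta(c_i, c_j) with weights
    taken from ``enhanced_score`` (1.0 where absent) and self-loops
    excluded. An empty edge set yields Q = 0 with a warning.
    """
    missing = set(graph.nodes) - set(partition)
    if missing:
        raise ParameterError(f"partition does not cover nodes: {sorted(missing)[:5]}")
    g = graph.copy()
    g.remove_edges_from(nx.selfloop_edges(g))
    if g.number_of_edges() == 0:
        warnings.warn("modularity of an empty edge set defined as 0", stacklevel=2)
        return 0.0
    for _, _, data in g.edges(data=True):
        data.setdefault("enhanced_score", 1.0)
    communities: dict[int, set] = {}
    for node, cid in partition.items():
        if node in g:
            communities.setdefault(cid, set()).add(node)
    return float(
        nx.community.modularity(g, communities.values(), weight="enhanced_score")
    )


def tune_inflation(
    graph: nx.Graph,
    grid: tuple[float, ...] = tuple(np.round(np.arange(1.2, 5.01, 0.2), 1)),
    config: MCLConfig = MCLConfig(),
) -> tuple[float, ClusterSolution]:
    """Run MCL for each inflation in *grid*, return the argmax-Q solution.

    Ties in Q are broken toward the smaller inflation.
    """
    if not len(grid):
        raise ParameterError("inflation grid must be non-empty")
    best: tuple[float, float, ClusterSolution] | None = None
    for r in sorted(float(r) for r in grid):
        sol = mcl(graph, MCLConfig(
            expansion=config.expansion,
            inflation=r,
            pruning=config.pruning,
            max_iterations=config.max_iterations,
            tolerance=config.tolerance,
            weight=config.weight,
        ))
        sol.modularity = modularity(graph, sol.partition)
        if best is None or sol.modularity > best[1] + 1e-12:
            best = (r, sol.modularity, sol)
    assert best is not None
    logger.info("tuned inflation r=%.2f (Q=%.4f)", best[0], best[1])
    return best[0], best[2]


def annotate_solution(solution: ClusterSolution, log2fc: dict[str, float]) -> None:
    """Fill per-cluster fold-change stats and up/down/mixed labels in place."""
    for cid, members in solution.clusters().items():
        vals = np.array([log2fc[g] for g in members], dtype=float)
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        iqr = q3 - q1
        inside = vals[(vals >= q1 - 1.5 * iqr) & (vals <= q3 + 1.5 * iqr)]
        if len(inside) and np.all(inside > 0):
            direction = "up"
        elif len(inside) and np.all(inside < 0):
            direction = "down"
        else:
            direction = "mixed"
        solution.stats[cid] = ClusterStats(
            size=len(members), median=float(med), q1=float(q1), q3=float(q3),
            iqr=float(iqr), direction=direction,
        )


def filter_clusters(solution: ClusterSolution, min_size: int = 20) -> list[int]:
    """Cluster ids passing the selection filter.

    A cluster is kept iff it has strictly more than *min_size* genes and
    every member fold change inside the 1.5 x IQR whiskers lies strictly
    on one side of zero (the cluster is coherently up- or down-regulated;
    whisker outliers stay members but do not veto the label).
    """
    if not solution.stats:
        raise ParameterError("per-cluster stats missing; call annotate_solution first")
    return sorted(
        cid
        for cid, st in solution.stats.items()
        if st.size > min_size and st.direction in ("up", "down")
    )
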