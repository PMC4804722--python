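"""Weighted TFBS co-occurrence networks and Markov clustering (MCL).

The network is undirected: nodes are TFBS (PWM) identifiers, edge weights are
the observed pair frequencies.  The adjacency matrix A is row-normalized into
a row-stochastic Markov matrix M = D^-1 * A (D the diagonal degree matrix),
after optional self-loops are added to the diagonal.  MCL then alternates
Expand (M <- M x M) and Inflate (entrywise power r followed by row
renormalization) until the matrix stops changing; clusters are read off the
attractors of the converged flow.

Self-loops: the plain M = D^-1 A formulation has none, but classic MCL needs
them for convergence on bipartite-like structures.  The default adds, per
node, a self-loop equal to its maximum incident edge weight; setting
``self_loop_weight=0`` recovers the literal loop-free normalization.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .composites import PairFrequencyTable

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class MCLParams:
    """Tuning knobs of the Markov clustering loop.

    inflation : float
        Entrywise exponent r > 1; larger values give finer clusters.
    self_loop_weight : float or None
        Diagonal weight added before normalization; ``None`` uses each node's
        maximum incident edge weight, ``0`` disables self-loops.
    tolerance : float
        Convergence threshold on the max absolute entrywise change.
    max_iter : int
        Iteration cap; non-convergence is logged, not raised.
    prune : float
        Entries below this are zeroed before renormalization; also the cutoff
        for attractor detection.
    """

    inflation: float = 2.0
    self_loop_weight: float | None = None
    tolerance: float = 1e-6
    max_iter: int = 200
    prune: float = 1e-9

    def __post_init__(self) -> None:
        if self.inflation <= 1.0:
            raise ValueError("inflation must be > 1")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")


@dataclasses.dataclass
class ClusterSet:
    """Disjoint node clusters for one stage; singletons retained but flagged."""

    stage: str
    clusters: list[list[str]]

    def __post_init__(self) -> None:
        self.clusters = [sorted(c) for c in self.clusters]
        self.clusters.sort(key=lambda c: (-len(c), c))
        seen: set[str] = set()
        for c in self.clusters:
            if not c:
                raise ValueError("clusters must be non-empty")
            for node in c:
                if node in seen:
                    raise ValueError(f"node {node} assigned to multiple clusters")
                seen.add(node)

    @property
    def nodes(self) -> set[str]:
        return {n for c in self.clusters for n in c}

    def non_singletons(self) -> list[list[str]]:
        return [c for c in self.clusters if len(c) > 1]

    def cluster_of(self, node: str) -> list[str] | None:
        for c in self.clusters:
            if node in c:
                return c
        return None


def build_network(
    freq: PairFrequencyTable,
    pair_nodes: Mapping[str, tuple[str, str]],
) -> nx.Graph:
    """Weighted undirected TFBS network from a pair frequency table.

    Edge weight equals the pair frequency; two pairs mapping to the same
    unordered node pair have their weights summed.  Homotypic pairs (both
    sides the same node) would be self-edges and are dropped with a warning.

    Raises
    ------
    KeyError
        for a pair id absent from ``pair_nodes``.
    """
    net = nx.Graph()
    for pair_id, weight in freq.weights.items():
        if pair_id not in pair_nodes:
            raise KeyError(f"unmapped pair id: {pair_id}")
        a, b = pair_nodes[pair_id]
        if a == b:
            logger.warning("dropping homotypic pair %s (self-edge on %s)", pair_id, a)
            continue
        if net.has_edge(a, b):
            net[a][b]["weight"] += weight
        else:
            net.add_edge(a, b, weight=float(weight))
    return net


def adjacency(net: nx.Graph) -> tuple[np.ndarray, list[str]]:
    """Symmetric weighted adjacency matrix and its (sorted) node ordering."""
    nodes = sorted(net.nodes)
    a = nx.to_numpy_array(net, nodelist=nodes, weight="weight")
    return a, nodes


def to_markov(net: nx.Graph, params: MCLParams) -> tuple[np.ndarray, list[str]]:
    """Row-stochastic Markov matrix M = D^-1 (A + S), S the self-loop diagonal."""
    if net.number_of_nodes() == 0:
        raise ValueError("network must be non-empty")
    a, nodes = adjacency(net)
    if params.self_loop_weight is None:
        loops = a.max(axis=1)
        loops[loops == 0] = 1.0  # lone node: unit self-loop gives M = [1]
    else:
        loops = np.full(len(nodes), float(params.self_loop_weight))
        if params.self_loop_weight == 0:
            isolated = a.sum(axis=1) == 0
            loops[isolated] = 1.0
    np.fill_diagonal(a, np.diag(a) + loops)
    m = a / a.sum(axis=1, keepdims=True)
    return m, nodes


def _check_row_stochastic(m: np.ndarray, tol: float = 1e-9) -> None:
    if np.any(m < -tol):
        raise ValueError("matrix entries must be non-negative")
    if not np.allclose(m.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("matrix rows must sum to 1")


def expand(m: np.ndarray) -> np.ndarray:
    """Expand step: M <- M x M (flow spreads along length-2 paths)."""
    return m @ m


def inflate(m: np.ndarray, r: float, prune: float = 1e-9) -> np.ndarray:
    """Inflate step: entrywise power r, pruning, then row renormalization."""
    if r <= 1.0:
        raise ValueError("inflation parameter must be > 1")
    p = np.power(m, r)
    p[p < prune] = 0.0
    sums = p.sum(axis=1, keepdims=True)
    if np.any(sums == 0):
        raise ValueError("a row became all-zero after pruning; cannot renormalize")
    return p / sums


def run_mcl(
    m: np.ndarray,
    params: MCLParams | None = None,
    nodes: Sequence[str] | None = None,
    stage: str = "",
) -> tuple[np.ndarray, ClusterSet]:
    """Iterate Expand/Inflate to convergence and extract clusters.

    Convergence is a max absolute entrywise change below ``params.tolerance``;
    hitting ``max_iter`` first logs a warning and extracts from the last
    iterate.  Non-finite entries raise.
    """
    params = params or MCLParams()
    m = np.asarray(m, dtype=float)
    _check_row_stochastic(m)
    if nodes is None:
        nodes = [str(i) for i in range(m.shape[0])]
    converged = False
    for _ in range(params.max_iter):
        m_next = inflate(expand(m), params.inflation, params.prune)
        if not np.all(np.isfinite(m_next)):
            raise ValueError("non-finite entries during MCL iteration")
        if np.abs(m_next - m).max() < params.tolerance:
            m = m_next
            converged = True
            break
        m = m_next
    if not converged:
        logger.warning(
            "MCL did not converge within %d iterations (stage %r)",
            params.max_iter,
            stage,
        )
    clusters = extract_clusters(m, nodes, prune=params.prune)
    return m, ClusterSet(stage=stage, clusters=clusters)


def extract_clusters(
    m: np.ndarray, nodes: Sequence[str], prune: float = 1e-9
) -> list[list[str]]:
    """Read clusters off a converged flow matrix.

    Attractors are nodes with a positive diagonal entry.  Every node is
    assigned to the attractor it sends maximal flow to (ties: the
    lexicographically smaller attractor id, logged); attractors that share a
    supporter, or flow into one another, merge into one cluster.  The result
    partitions the node set.
    """
    n = m.shape[0]
    nodes = list(nodes)
    attractors = [i for i in range(n) if m[i, i] > prune]
    if not attractors:
        # pathological (e.g. unconverged oscillation): fall back to row argmax
        attractors = sorted({int(np.argmax(m[i])) for i in range(n)})

    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    attractor_set = set(attractors)
    assignment: dict[int, int] = {}
    for i in range(n):
        flows = {a: m[i, a] for a in attractors if m[i, a] > prune}
        if not flows:
            assignment[i] = i if i in attractor_set else int(np.argmax(m[i]))
            continue
        best = max(flows.values())
        tied = sorted((a for a, f in flows.items() if np.isclose(f, best)),
                      key=lambda a: nodes[a])
        if len(tied) > 1:
            logger.info(
                "node %s ties between attractors %s; assigning to %s",
                nodes[i],
                [nodes[a] for a in tied],
                nodes[tied[0]],
            )
        assignment[i] = tied[0]
        # attractors reached by the same supporter belong to one cluster
        for a in flows:
            union(tied[0], a)

    for i, a in assignment.items():
        union(a, i)

    groups: dict[int, list[str]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(nodes[i])
    return [sorted(g) for g in groups.values()]


def cluster_network(
    net: nx.Graph, params: MCLParams | None = None, stage: str = ""
) -> tuple[np.ndarray, ClusterSet]:
    """Convenience wrapper: network -> Markov matrix -> MCL clusters."""
    params = params or MCLParams()
    m, nodes = to_markov(net, params)
    return run_mcl(m, params, nodes=nodes, stage=stage)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_network_tsv(net: nx.Graph, path: str | Path) -> None:
    lines = ["node_a\tnode_b\tweight"]
    for a, b in sorted(net.edges, key=lambda e: tuple(sorted(e))):
        x, y = sorted((a, b))
        lines.append(f"{x}\t{y}\t{net[a][b]['weight']:g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_network_tsv(path: str | Path) -> nx.Graph:
    net = nx.Graph()
    lines = Path(path).read_text().splitlines()
    for line in lines[1:]:
        if not line.strip():
            continue
        a, b, w = line.split("\t")
        net.add_edge(a, b, weight=float(w))
    return net


def save_clusters(
    cs: ClusterSet, path: str | Path, params: MCLParams | None = None
) -> None:
    payload = {
        "stage": cs.stage,
        "clusters": cs.clusters,
        "params": dataclasses.asdict(params) if params else None,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_clusters(path: str | Path) -> ClusterSet:
    payload = json.loads(Path(path).read_text())
    return ClusterSet(stage=payload["stage"], clusters=payload["clusters"])
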