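"""Barabasi-Albert population graphs, rewiring and degree statistics.

The interaction network starts from two fully connected nodes; each arriving
node attaches two links to distinct existing nodes chosen proportionally to
current degree (growth + preferential attachment, m = 2).  The resulting
simple graph has exactly 1 + 2(N - 2) edges, which every later rewiring
conserves.  This seeding differs from :func:`networkx.barabasi_albert_graph`
(whose seed graph is empty), so the construction is done directly on top of a
:class:`networkx.Graph` container.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

__all__ = [
    "build_ba_network",
    "assign_strategies",
    "rewire",
    "sample_new_neighbor",
    "degree_distribution",
    "DegreeReport",
    "expected_edge_count",
    "write_edgelist",
    "read_edgelist",
    "write_strategies",
    "read_strategies",
]

STRATEGY_ATTR = "strategy"


def expected_edge_count(n: int) -> int:
    """Edge count of the construction: 1 seed edge plus 2 per arriving node."""
    return 1 + 2 * (n - 2) if n >= 2 else 0


def build_ba_network(n: int, rng: np.random.Generator) -> nx.Graph:
    """Grow a scale-free graph of ``n`` nodes by preferential attachment.

    Targets for each arriving node are sampled proportional to degree via the
    repeated-nodes trick, resampling until the two targets are distinct, so
    the graph stays simple.
    """
    if n < 2:
        raise ValueError(f"population size must be >= 2, got {n}")
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edge(0, 1)
    # each endpoint appears once per unit of degree
    repeated = [0, 1]
    for new in range(2, n):
        t1 = repeated[rng.integers(len(repeated))]
        t2 = t1
        while t2 == t1:
            t2 = repeated[rng.integers(len(repeated))]
        g.add_edge(new, t1)
        g.add_edge(new, t2)
        repeated.extend((t1, t2, new, new))
    return g


def assign_strategies(
    graph: nx.Graph, strategy_labels: tuple, rng: np.random.Generator
) -> nx.Graph:
    """Assign one of four labels to every node with equal probability 1/4."""
    if len(strategy_labels) != 4:
        raise ValueError("exactly 4 strategy labels are required")
    nodes = list(graph.nodes)
    picks = rng.integers(0, 4, size=len(nodes))
    for node, k in zip(nodes, picks):
        graph.nodes[node][STRATEGY_ATTR] = strategy_labels[k]
    return graph


def sample_new_neighbor(
    n: int, i: int, excluded: set[int], rng: np.random.Generator
) -> int | None:
    """Uniform draw from nodes outside ``{i} | excluded``; None if empty.

    Rejection sampling keeps the draw O(1) on sparse graphs; when more than
    half the population is excluded an explicit candidate list is used
    instead so the loop terminates quickly.
    """
    n_eligible = n - 1 - len(excluded - {i})
    if n_eligible <= 0:
        return None
    if len(excluded) > n // 2:
        candidates = [v for v in range(n) if v != i and v not in excluded]
        return int(candidates[rng.integers(len(candidates))])
    while True:
        k = int(rng.integers(n))
        if k != i and k not in excluded:
            return k


def rewire(
    graph: nx.Graph, i: int, j: int, rng: np.random.Generator
) -> int | None:
    """Replace edge (i, j) by (i, k) with k uniform over non-neighbors of i.

    The candidate pool is evaluated after removing j, so the dropped neighbor
    itself is eligible again.  Returns the new neighbor id, or None when node
    i is adjacent to every other node (the edge is then retained unchanged).
    """
    if not graph.has_edge(i, j):
        raise ValueError(f"edge ({i}, {j}) does not exist")
    if graph.degree[i] >= graph.number_of_nodes() - 1:
        return None  # adjacent to everyone: nothing to rewire to
    graph.remove_edge(i, j)
    k = sample_new_neighbor(graph.number_of_nodes(), i, set(graph.adj[i]), rng)
    assert k is not None  # pool contains at least j after removal
    graph.add_edge(i, k)
    return k


@dataclass
class DegreeReport:
    """Degree histogram(s): ``counts[d]`` is the number of nodes of degree d."""

    counts: np.ndarray
    mean: float
    variance_to_mean: float
    per_strategy: dict | None = None


def _histogram(degrees: np.ndarray) -> np.ndarray:
    return np.bincount(degrees) if degrees.size else np.zeros(1, dtype=int)


def degree_distribution(graph: nx.Graph, by_strategy: bool = False) -> DegreeReport:
    """Overall (and optionally per-strategy) degree histograms.

    The variance-to-mean ratio of the degree sequence is the report's
    heavy-tail summary: it is large for scale-free graphs and close to the
    Poisson value after sustained random rewiring.
    """
    nodes = list(graph.nodes)
    degrees = np.array([graph.degree[v] for v in nodes], dtype=int)
    mean = float(degrees.mean()) if degrees.size else 0.0
    vmr = float(degrees.var() / mean) if mean > 0 else 0.0
    per = None
    if by_strategy:
        per = {}
        labels = {graph.nodes[v].get(STRATEGY_ATTR) for v in nodes}
        for lab in sorted(labels, key=str):
            sub = np.array(
                [graph.degree[v] for v in nodes if graph.nodes[v].get(STRATEGY_ATTR) == lab],
                dtype=int,
            )
            per[lab] = _histogram(sub)
    return DegreeReport(counts=_histogram(degrees), mean=mean, variance_to_mean=vmr, per_strategy=per)


def write_edgelist(graph: nx.Graph, path: str | Path) -> None:
    """Tab-separated edge list, one unordered pair per line, 0-based ids."""
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in graph.edges):
            fh.write(f"{u}\t{v}\n")


def read_edgelist(path: str | Path) -> nx.Graph:
    return nx.read_edgelist(path, delimiter="\t", nodetype=int, data=False)


def write_strategies(graph: nx.Graph, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["node_id", "strategy_label"])
        for v in sorted(graph.nodes):
            w.writerow([v, graph.nodes[v].get(STRATEGY_ATTR, "")])


def read_strategies(path: str | Path) -> dict[int, str]:
    out: dict[int, str] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out[int(row["node_id"])] = row["strategy_label"]
    return out
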