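"""Deterministic test fixtures, generated programmatically.

Three tiny populations used throughout the test suite and the examples:

* a 4-node path C - C - D - D with full trust (the pair whose C-D and D-D
  links must eventually break under the trust dynamics);
* a 50-node scale-free graph with a seeded strategy assignment;
* a minimal two-agent, single-edge population.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np

from .network import (
    STRATEGY_ATTR,
    assign_strategies,
    build_ba_network,
    write_edgelist,
    write_strategies,
)
from .trust import TrustLedger

__all__ = ["path4_fixture", "ba50_fixture", "dyad_fixture", "generate_fixtures"]


def path4_fixture() -> tuple[nx.Graph, TrustLedger]:
    """Path 0-1-2-3 with strategies C, C, D, D and full mutual trust."""
    g = nx.path_graph(4)
    for node, lab in enumerate(("C", "C", "D", "D")):
        g.nodes[node][STRATEGY_ATTR] = lab
    return g, TrustLedger.from_edges(g.edges)


def ba50_fixture(seed: int = 1234) -> tuple[nx.Graph, TrustLedger]:
    """50-node scale-free graph (97 edges) with a seeded 4-way assignment."""
    rng = np.random.default_rng(seed)
    g = build_ba_network(50, rng)
    assign_strategies(g, ("C", "D", "QA", "QB"), rng)
    return g, TrustLedger.from_edges(g.edges)


def dyad_fixture() -> tuple[nx.Graph, TrustLedger]:
    """Two agents, one edge, strategies C and D, full trust."""
    g = nx.Graph()
    g.add_edge(0, 1)
    g.nodes[0][STRATEGY_ATTR] = "C"
    g.nodes[1][STRATEGY_ATTR] = "D"
    return g, TrustLedger.from_edges(g.edges)


def generate_fixtures(out_dir: str | Path, seed: int = 1234) -> list[Path]:
    """Write the three fixtures as edge-list TSV + strategy CSV + trust CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, (g, ledger) in {
        "path4": path4_fixture(),
        "ba50": ba50_fixture(seed),
        "dyad": dyad_fixture(),
    }.items():
        edge_path = out / f"{name}.edges.tsv"
        strat_path = out / f"{name}.strategies.csv"
        trust_path = out / f"{name}.trust.csv"
        write_edgelist(g, edge_path)
        write_strategies(g, strat_path)
        ledger.write_snapshot(trust_path)
        written.extend([edge_path, strat_path, trust_path])
    return written
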