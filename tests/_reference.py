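"""Reference step implementation composed from the per-operation API.

Replays one coevolution step on a networkx graph + TrustLedger using only
the public operations (weight, update_trust, broken_links, resolve_rewirer,
rewire, reset_new_link) and the engine's documented RNG draw order.  Used to
hold the vectorized engine and the per-operation semantics equal.
"""

import numpy as np

from qcoevo import TrustLedger, imitation_probability
from qcoevo.network import STRATEGY_ATTR, rewire


def reference_step(graph, ledger, payoff_table, strat_of, config, rng):
    """One play/imitate/trust/rewire step; mutates graph and ledger,
    returns the new strategy map and the per-agent totals."""
    n = graph.number_of_nodes()

    # play: actual payoff through each link is weight * quantum payoff
    received = {i: {} for i in graph.nodes}
    for i, j in graph.edges:
        w = ledger.weight(i, j)
        received[i][j] = w * payoff_table[strat_of[i], strat_of[j]]
        received[j][i] = w * payoff_table[strat_of[j], strat_of[i]]
    totals = {i: sum(received[i].values()) for i in graph.nodes}

    # imitate: same draw order as the engine (N picks then N adoption coins)
    def cmp_payoff(i):
        k = graph.degree[i]
        if config.fermi_payoff_mode == "average":
            return totals[i] / k if k else 0.0
        return totals[i]

    r_pick = rng.random(n)
    r_adopt = rng.random(n)
    new_strat = dict(strat_of)
    for i in range(n):
        nbrs = sorted(graph.adj[i])
        if not nbrs:
            continue
        j = nbrs[int(r_pick[i] * len(nbrs))]
        if cmp_payoff(j) > cmp_payoff(i):
            if r_adopt[i] < imitation_probability(cmp_payoff(i), cmp_payoff(j), config.lam):
                new_strat[i] = strat_of[j]

    # trust re-evaluation from this round's payoffs
    if config.eta > 0:
        for i in graph.nodes:
            if received[i]:
                ledger.update_trust(i, received[i], config.eta, config.b)

    # break and rewire zero-trust links, ascending canonical edge order
    if config.rewiring_enabled:
        for link in ledger.broken_links():
            winner = ledger.resolve_rewirer(link, rng)
            loser = link.edge[1] if winner == link.edge[0] else link.edge[0]
            k = rewire(graph, winner, loser, rng)
            if k is not None:
                ledger.drop_edge(winner, loser)
                ledger.reset_new_link(winner, k)

    for i, s in new_strat.items():
        graph.nodes[i][STRATEGY_ATTR] = s
    return new_strat, totals


def minimal_spatial_game(graph, strat_of, payoff_table, lam, mode, rng, n_steps):
    """Independent weight-free spatial game: unit-weight payoffs plus Fermi
    imitation on a static graph (no trust, no rewiring).  Written directly
    from the update rule, without the package's step machinery."""
    n = graph.number_of_nodes()
    strat = dict(strat_of)
    history = []
    for _ in range(n_steps):
        totals = {i: 0.0 for i in graph.nodes}
        for i, j in graph.edges:
            totals[i] += payoff_table[strat[i], strat[j]]
            totals[j] += payoff_table[strat[j], strat[i]]
        cmp = {
            i: (totals[i] / graph.degree[i] if graph.degree[i] else 0.0)
            if mode == "average"
            else totals[i]
            for i in graph.nodes
        }
        history.append(np.bincount([strat[i] for i in range(n)], minlength=4) / n)
        r_pick = rng.random(n)
        r_adopt = rng.random(n)
        new = dict(strat)
        for i in range(n):
            nbrs = sorted(graph.adj[i])
            if not nbrs:
                continue
            j = nbrs[int(r_pick[i] * len(nbrs))]
            if cmp[j] > cmp[i] and r_adopt[i] < 1.0 / (1.0 + np.exp(-lam * (cmp[j] - cmp[i]))):
                new[i] = strat[j]
        strat = new
    return strat, history
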