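"""Synchronous coevolution of strategies, trust and network structure.

One time step advances the whole population through four phases:

1. play    — every pair of neighbors plays the maximally entangled quantum
             prisoner's dilemma; the payoff actually received through a link
             is the cached quantum expected payoff scaled by the link weight
             (the mean of the two directed trusts).
2. imitate — every agent picks one neighbor uniformly at random and, if the
             neighbor's comparison payoff strictly exceeds its own, adopts
             the neighbor's strategy with the Fermi probability
             1 / (1 + exp(-lambda * (U_j - U_i))); all adoptions are applied
             synchronously.
3. trust   — every agent re-evaluates its neighbors against the mean of its
             received payoffs (see :mod:`qcoevo.trust`).
4. rewire  — links whose trust reached zero on either side are broken; the
             zero-trust side (or a coin-flip winner when both are at zero)
             rewires to a uniformly random non-neighbor and the new link
             starts at full mutual trust.  Edge count is conserved.

The engine keeps the population in flat numpy arrays (edge list, per-edge
directed trust, per-node strategy index) so that a 10^3-agent, 10^3-step run
stays inexpensive; the per-operation semantics live in :mod:`qcoevo.trust`
and :mod:`qcoevo.network` and the two routes are held equal by regression
tests.  The RNG draw order per step is part of the engine contract:
imitation consumes ``rng.random(N)`` for neighbor picks then ``rng.random(N)``
for adoption coins; rewiring consumes draws per broken edge in ascending
canonical edge order (one coin if contested, then target draws).

Strategy indices are fixed as C=0, D=1 and the run's two quantum draws QA=2,
QB=3; the Q1/Q2 relabeling by final abundance happens in
:mod:`qcoevo.experiments`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.special import expit

from . import network as netmod
from .quantum import (
    PayoffParams,
    QuantumStrategy,
    classical_C,
    classical_D,
    profile_payoff_table,
    random_strategy,
)
from .trust import TrustLedger, resolve_rewirer_values

__all__ = [
    "STRATEGY_LABELS",
    "PAIR_TYPES",
    "SimulationConfig",
    "SimulationState",
    "StepRecord",
    "RunResult",
    "initialize",
    "play_round",
    "imitation_probability",
    "imitate",
    "step",
    "detect_steady_state",
    "run_simulation",
]

STRATEGY_LABELS: tuple[str, ...] = ("C", "D", "QA", "QB")
#: the 10 unordered strategy-pair types of 4 strategies, as (low, high) indices
PAIR_TYPES: tuple[tuple[int, int], ...] = tuple(
    (a, b) for a in range(4) for b in range(a, 4)
)
_PAIR_INDEX = {p: k for k, p in enumerate(PAIR_TYPES)}
# lookup from flattened (low*4 + high) strategy code to pair-type index
_PAIR_CODE = np.full(16, -1, dtype=int)
for (_a, _b), _k in _PAIR_INDEX.items():
    _PAIR_CODE[_a * 4 + _b] = _k


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of one coevolution run.

    Defaults follow the study conditions: selection intensity lambda = 0.05,
    trust gain eta = 0.2, at most 10^3 steps with the steady-state stop
    (variance of every strategy fraction over a trailing 10-step window below
    0.01, checked after a 100-step burn-in), maximal entanglement.
    """

    n_agents: int = 5000
    b: float = 1.5
    lam: float = 0.05
    eta: float = 0.2
    t_max: int = 1000
    rewiring_enabled: bool = True
    seed: int = 0
    steady_window: int = 10
    steady_var: float = 0.01
    steady_burnin: int = 100
    fermi_payoff_mode: str = "average"
    gamma: float = math.pi / 2

    def validate(self) -> None:
        if self.n_agents < 2:
            raise ValueError(f"n_agents must be >= 2, got {self.n_agents}")
        if not 1.0 < self.b <= 2.0:
            raise ValueError(f"b must satisfy 1 < b <= 2, got {self.b}")
        if self.lam <= 0:
            raise ValueError(f"lam must be > 0, got {self.lam}")
        if self.eta < 0:
            # eta = 0 disables trust adaptation (fixed unit weights)
            raise ValueError(f"eta must be >= 0, got {self.eta}")
        if self.t_max < 1:
            raise ValueError(f"t_max must be >= 1, got {self.t_max}")
        if self.steady_var <= 0:
            raise ValueError(f"steady_var must be > 0, got {self.steady_var}")
        if self.fermi_payoff_mode not in ("total", "average"):
            raise ValueError(
                f"fermi_payoff_mode must be 'total' or 'average', got {self.fermi_payoff_mode!r}"
            )
        if not 0.0 <= self.gamma <= math.pi / 2:
            raise ValueError(f"gamma must be in [0, pi/2], got {self.gamma}")


@dataclass
class SimulationState:
    """Population state at time t, in flat arrays.

    ``edges[e] = (u, v)`` with directed trusts ``trust[e, 0] = a(u->v)`` and
    ``trust[e, 1] = a(v->u)``; ``strat[i]`` is the strategy index of agent i;
    ``adj[i]`` maps each neighbor of i to the incident edge index.  After
    :func:`play_round`, ``pay_u``/``pay_v`` hold the per-edge actual payoffs
    and ``totals``/``degrees`` the per-agent sums.
    """

    n_agents: int
    b: float
    edges: np.ndarray
    trust: np.ndarray
    strat: np.ndarray
    adj: list[dict[int, int]]
    payoff_table: np.ndarray
    t: int = 0
    pay_u: np.ndarray | None = None
    pay_v: np.ndarray | None = None
    totals: np.ndarray | None = None
    degrees: np.ndarray | None = None

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_agents))
        g.add_edges_from((int(u), int(v)) for u, v in self.edges)
        for i in range(self.n_agents):
            g.nodes[i][netmod.STRATEGY_ATTR] = STRATEGY_LABELS[self.strat[i]]
        return g

    def to_ledger(self) -> TrustLedger:
        ledger = TrustLedger()
        for e, (u, v) in enumerate(self.edges):
            ledger._a[(int(u), int(v))] = float(self.trust[e, 0])
            ledger._a[(int(v), int(u))] = float(self.trust[e, 1])
        return ledger


@dataclass(frozen=True)
class StepRecord:
    """Per-step statistics, sampled after play and before any mutation."""

    t: int
    frac: np.ndarray
    pair_frac: np.ndarray
    pair_weight: np.ndarray
    edge_count: int


@dataclass
class RunResult:
    """Full trajectory of one Monte Carlo run plus its final state."""

    config: SimulationConfig
    strategies: list[QuantumStrategy]
    records: list[StepRecord]
    state: SimulationState
    initial_degrees: np.ndarray
    reached_steady_state: bool
    q1_index: int | None = None

    @property
    def final_fractions(self) -> np.ndarray:
        return self.records[-1].frac


def initialize(config: SimulationConfig, rng: np.random.Generator) -> SimulationState:
    """Fresh state: BA graph, equiprobable strategies, full trust, cached
    quantum payoff table for {C, D, QA, QB}."""
    config.validate()
    graph = netmod.build_ba_network(config.n_agents, rng)
    strat = rng.integers(0, 4, size=config.n_agents).astype(np.int8)
    qa = random_strategy(rng, label="QA")
    qb = random_strategy(rng, label="QB")
    strategies = [classical_C(), classical_D(), qa, qb]
    table = profile_payoff_table(
        strategies, PayoffParams.from_temptation(config.b), config.gamma
    )
    edges = np.array(sorted(tuple(sorted(e)) for e in graph.edges), dtype=np.int64)
    trust = np.ones((len(edges), 2), dtype=float)
    adj: list[dict[int, int]] = [dict() for _ in range(config.n_agents)]
    for e, (u, v) in enumerate(edges):
        adj[int(u)][int(v)] = e
        adj[int(v)][int(u)] = e
    state = SimulationState(
        n_agents=config.n_agents,
        b=config.b,
        edges=edges,
        trust=trust,
        strat=strat,
        adj=adj,
        payoff_table=table,
    )
    state._strategies = strategies  # type: ignore[attr-defined]
    return state


def play_round(state: SimulationState) -> SimulationState:
    """All pairs of neighbors play; actual payoffs are weight-scaled.

    P_t(ij) = w_t(ij) * $_i(ij) with w the mean of the two directed trusts
    and $ the cached quantum expected payoff; totals are per-agent sums and
    isolated agents get total 0.
    """
    u = state.edges[:, 0]
    v = state.edges[:, 1]
    w = state.trust.mean(axis=1)
    state.pay_u = w * state.payoff_table[state.strat[u], state.strat[v]]
    state.pay_v = w * state.payoff_table[state.strat[v], state.strat[u]]
    n = state.n_agents
    state.totals = np.bincount(u, weights=state.pay_u, minlength=n) + np.bincount(
        v, weights=state.pay_v, minlength=n
    )
    state.degrees = np.bincount(u, minlength=n) + np.bincount(v, minlength=n)
    return state


def imitation_probability(u_i: float, u_j: float, lam: float) -> float:
    """Fermi rule: p = 1 / (1 + exp(-lam * (U_j - U_i))); overflow-safe."""
    if lam <= 0:
        raise ValueError(f"lam must be > 0, got {lam}")
    return float(expit(lam * (np.asarray(u_j, dtype=float) - u_i)))


def _comparison_payoffs(state: SimulationState, mode: str) -> np.ndarray:
    if mode == "total":
        return state.totals
    deg = state.degrees
    out = np.zeros_like(state.totals)
    np.divide(state.totals, deg, out=out, where=deg > 0)
    return out


def imitate(state: SimulationState, rng: np.random.Generator, lam: float, mode: str = "average") -> SimulationState:
    """Synchronous strategy imitation via the Fermi rule.

    Each agent draws one uniform neighbor; only a strictly larger comparison
    payoff (total or degree-averaged, per ``mode``) triggers an imitation
    attempt.  Isolated agents skip.  Consumes exactly 2N uniforms.
    """
    n = state.n_agents
    cmp = _comparison_payoffs(state, mode)
    r_pick = rng.random(n)
    r_adopt = rng.random(n)
    chosen = np.full(n, -1, dtype=np.int64)
    adj = state.adj
    for i in range(n):
        k = len(adj[i])
        if k:
            chosen[i] = sorted(adj[i])[int(r_pick[i] * k)]
    has = chosen >= 0
    idx = np.nonzero(has)[0]
    j = chosen[idx]
    better = cmp[j] > cmp[idx]
    p = expit(lam * (cmp[j] - cmp[idx]))
    adopt = better & (r_adopt[idx] < p)
    new_strat = state.strat.copy()
    new_strat[idx[adopt]] = state.strat[j[adopt]]
    state.strat = new_strat
    return state


def _update_trust(state: SimulationState, eta: float) -> None:
    u = state.edges[:, 0]
    v = state.edges[:, 1]
    mean_rec = np.zeros_like(state.totals)
    np.divide(state.totals, state.degrees, out=mean_rec, where=state.degrees > 0)
    np.clip(state.trust[:, 0] + eta * (state.pay_u - mean_rec[u]) / state.b, 0.0, 1.0, out=state.trust[:, 0])
    np.clip(state.trust[:, 1] + eta * (state.pay_v - mean_rec[v]) / state.b, 0.0, 1.0, out=state.trust[:, 1])


def _rewire_broken(state: SimulationState, rng: np.random.Generator) -> None:
    broken = np.nonzero((state.trust[:, 0] <= 0.0) | (state.trust[:, 1] <= 0.0))[0]
    if broken.size == 0:
        return
    # deterministic processing order: ascending canonical (low, high) pair
    canon = [
        (min(int(state.edges[e, 0]), int(state.edges[e, 1])),
         max(int(state.edges[e, 0]), int(state.edges[e, 1])), int(e))
        for e in broken
    ]
    for a, c, e in sorted(canon):
        u, v = int(state.edges[e, 0]), int(state.edges[e, 1])
        a_uv, a_vu = float(state.trust[e, 0]), float(state.trust[e, 1])
        a_ac = a_uv if u == a else a_vu  # trust along canonical orientation
        winner = resolve_rewirer_values(a, c, a_ac, a_uv + a_vu - a_ac, rng)
        loser = c if winner == a else a
        if len(state.adj[winner]) >= state.n_agents - 1:
            continue  # winner adjacent to everyone: keep the old link
        del state.adj[winner][loser]
        del state.adj[loser][winner]
        k = netmod.sample_new_neighbor(state.n_agents, winner, set(state.adj[winner]), rng)
        state.edges[e, 0] = winner
        state.edges[e, 1] = k
        state.trust[e, 0] = 1.0
        state.trust[e, 1] = 1.0
        state.adj[winner][k] = e
        state.adj[k][winner] = e


def _record(state: SimulationState) -> StepRecord:
    n_edges = len(state.edges)
    frac = np.bincount(state.strat, minlength=4).astype(float) / state.n_agents
    su = state.strat[state.edges[:, 0]].astype(int)
    sv = state.strat[state.edges[:, 1]].astype(int)
    code = np.minimum(su, sv) * 4 + np.maximum(su, sv)
    pidx = _PAIR_CODE[code]
    counts = np.bincount(pidx, minlength=10).astype(float)
    w = state.trust.mean(axis=1)
    wsum = np.bincount(pidx, weights=w, minlength=10)
    with np.errstate(invalid="ignore"):
        pair_weight = np.where(counts > 0, wsum / np.maximum(counts, 1), np.nan)
    return StepRecord(
        t=state.t,
        frac=frac,
        pair_frac=counts / n_edges,
        pair_weight=pair_weight,
        edge_count=n_edges,
    )


def step(
    state: SimulationState, config: SimulationConfig, rng: np.random.Generator
) -> tuple[SimulationState, StepRecord]:
    """Advance one synchronous step: play, record, imitate, trust, rewire."""
    play_round(state)
    record = _record(state)
    imitate(state, rng, config.lam, config.fermi_payoff_mode)
    if config.eta > 0:
        _update_trust(state, config.eta)
    if config.rewiring_enabled:
        _rewire_broken(state, rng)
    state.t += 1
    return state, record


def detect_steady_state(history: list[StepRecord], config: SimulationConfig) -> bool:
    """Stationarity stop: after the burn-in, every strategy's fraction has
    variance below ``steady_var`` over the trailing ``steady_window`` records."""
    if len(history) < config.steady_window:
        return False
    if history[-1].t <= config.steady_burnin:
        return False
    window = np.stack([r.frac for r in history[-config.steady_window:]])
    return bool(np.all(window.var(axis=0) < config.steady_var))


def run_simulation(config: SimulationConfig) -> RunResult:
    """One full Monte Carlo run, reproducible from ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    state = initialize(config, rng)
    initial_degrees = np.array(
        [len(state.adj[i]) for i in range(state.n_agents)], dtype=int
    )
    records: list[StepRecord] = []
    steady = False
    for _ in range(config.t_max):
        state, record = step(state, config, rng)
        records.append(record)
        if detect_steady_state(records, config):
            steady = True
            break
    return RunResult(
        config=config,
        strategies=state._strategies,  # type: ignore[attr-defined]
        records=records,
        state=state,
        initial_degrees=initial_degrees,
        reached_steady_state=steady,
    )
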