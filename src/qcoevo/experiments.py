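"""Monte Carlo batch drivers: temptation sweeps, link-pair dynamics,
degree-distribution and payoff-distribution reports.

Each run draws its own network and its own pair of random quantum strategies,
so quantum labels are only comparable after relabeling: within a run the
quantum strategy with the larger final abundance is Q1, the other Q2 (ties go
to the first-drawn).  Averaging across runs always happens after relabeling.
Per-run seeds are derived from the master seed by a fixed counter scheme so
any single run can be re-created in isolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .coevolution import (
    PAIR_TYPES,
    RunResult,
    SimulationConfig,
    StepRecord,
    run_simulation,
)
from .network import degree_distribution
from .quantum import sample_payoff_distribution

__all__ = [
    "RELABELED_STRATEGIES",
    "derive_seed",
    "relabel_quantum",
    "relabeled_fractions",
    "SweepResult",
    "sweep_b",
    "link_pair_timeseries",
    "degree_distribution_report",
    "DegreeDistributionReport",
    "payoff_distribution_report",
]

#: strategy order after Q1/Q2 relabeling
RELABELED_STRATEGIES: tuple[str, ...] = ("C", "D", "Q1", "Q2")
#: the 10 unordered pair-type names after relabeling, aligned with PAIR_TYPES
PAIR_TYPE_NAMES: tuple[str, ...] = tuple(
    f"{RELABELED_STRATEGIES[a]}-{RELABELED_STRATEGIES[b]}" for a, b in PAIR_TYPES
)


def derive_seed(master_seed: int, counter: int) -> int:
    """Per-run seed from (master seed, run counter); stable and < 2^31."""
    return int(np.random.SeedSequence([master_seed, counter]).generate_state(1)[0] % (2**31))


def relabel_quantum(run: RunResult) -> RunResult:
    """Fix Q labels within a run: the quantum strategy with the larger final
    fraction becomes Q1 (strategy index 2); ties keep the first-drawn as Q1.
    C and D are untouched."""
    final = run.records[-1].frac
    run.q1_index = 3 if final[3] > final[2] else 2
    return run


def _strategy_permutation(run: RunResult) -> np.ndarray:
    """old strategy index -> relabeled index, with index 2 = Q1, 3 = Q2."""
    if run.q1_index is None:
        relabel_quantum(run)
    if run.q1_index == 2:
        return np.array([0, 1, 2, 3])
    return np.array([0, 1, 3, 2])


def relabeled_fractions(run: RunResult, record: StepRecord | None = None) -> np.ndarray:
    """Strategy fractions in (C, D, Q1, Q2) order."""
    perm = _strategy_permutation(run)
    frac = (record or run.records[-1]).frac
    out = np.empty(4)
    out[perm] = frac
    return out


def _pair_permutation(perm: np.ndarray) -> np.ndarray:
    """Pair-type index map induced by a strategy permutation."""
    out = np.empty(len(PAIR_TYPES), dtype=int)
    for k, (a, b) in enumerate(PAIR_TYPES):
        na, nb = sorted((perm[a], perm[b]))
        out[k] = PAIR_TYPES.index((na, nb))
    return out


def relabeled_pair_stats(run: RunResult, record: StepRecord) -> tuple[np.ndarray, np.ndarray]:
    """(pair_frac, pair_weight) of a record in relabeled pair-type order."""
    pperm = _pair_permutation(_strategy_permutation(run))
    frac = np.empty(len(PAIR_TYPES))
    weight = np.empty(len(PAIR_TYPES))
    frac[pperm] = record.pair_frac
    weight[pperm] = record.pair_weight
    return frac, weight


@dataclass
class SweepResult:
    """Mean final strategy fractions per temptation value.

    ``mean_frac[i, s]`` is the mean (over runs, after relabeling) final
    fraction of strategy ``RELABELED_STRATEGIES[s]`` at ``b_values[i]``.
    """

    b_values: list[float]
    mean_frac: np.ndarray
    n_runs: int
    variant: str
    runs: list[list[RunResult]] | None = None


def sweep_b(
    config_template: SimulationConfig,
    b_values: list[float],
    n_runs: int,
    master_seed: int,
    variant: str = "coevolving",
    keep_runs: bool = False,
) -> SweepResult:
    """Reproduce a strategy-dominance-versus-temptation curve.

    For each b, runs ``n_runs`` independent simulations (fresh network and
    fresh quantum draws per run), relabels each run, and averages the final
    strategy fractions.  ``variant`` is ``"static"`` (trust adapts, network
    fixed) or ``"coevolving"`` (zero-trust links rewire).
    """
    if variant not in ("static", "coevolving"):
        raise ValueError(f"variant must be 'static' or 'coevolving', got {variant!r}")
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    mean = np.zeros((len(b_values), 4))
    all_runs: list[list[RunResult]] = []
    counter = 0
    for i, b in enumerate(b_values):
        runs_b: list[RunResult] = []
        for _ in range(n_runs):
            cfg = replace(
                config_template,
                b=float(b),
                rewiring_enabled=(variant == "coevolving"),
                seed=derive_seed(master_seed, counter),
            )
            counter += 1
            run = relabel_quantum(run_simulation(cfg))
            mean[i] += relabeled_fractions(run)
            runs_b.append(run)
        mean[i] /= n_runs
        all_runs.append(runs_b)
    return SweepResult(
        b_values=[float(b) for b in b_values],
        mean_frac=mean,
        n_runs=n_runs,
        variant=variant,
        runs=all_runs if keep_runs else None,
    )


def link_pair_timeseries(runs: list[RunResult]) -> tuple[np.ndarray, np.ndarray]:
    """Mean link-pair fractions and mean pair weights per time step.

    Runs that stopped early (steady state) contribute their final record to
    all later time points.  Returns ``(pair_frac, pair_weight)`` with shape
    ``(T, 10)`` in relabeled pair-type order; a pair weight is averaged only
    over runs where that pair type exists at that step (NaN if none).
    """
    if not runs:
        raise ValueError("need at least one run")
    t_len = max(len(r.records) for r in runs)
    frac = np.zeros((t_len, len(PAIR_TYPES)))
    weight = np.full((len(runs), t_len, len(PAIR_TYPES)), np.nan)
    for ri, run in enumerate(runs):
        for t in range(t_len):
            rec = run.records[min(t, len(run.records) - 1)]
            f, w = relabeled_pair_stats(run, rec)
            frac[t] += f
            weight[ri, t] = w
    frac /= len(runs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean_weight = np.nanmean(weight, axis=0)
    return frac, mean_weight


@dataclass
class DegreeDistributionReport:
    """Initial and final degree histograms, averaged over runs.

    Histograms are mean counts per degree (mass sums to N); the
    variance-to-mean ratios summarize Poissonization: the initial scale-free
    degree sequence is overdispersed, sustained random rewiring pushes the
    ratio toward the Poisson value.
    """

    initial_hist: np.ndarray
    final_hist: np.ndarray
    final_per_strategy: dict[str, np.ndarray]
    initial_vmr: float
    final_vmr: float


def _mean_hists(hists: list[np.ndarray], n_runs: int) -> np.ndarray:
    width = max(len(h) for h in hists)
    out = np.zeros(width)
    for h in hists:
        out[: len(h)] += h
    return out / n_runs


def degree_distribution_report(runs: list[RunResult]) -> DegreeDistributionReport:
    """Averaged degree histograms before and after coevolution, overall and
    per final (relabeled) strategy."""
    init_hists, final_hists = [], []
    per: dict[str, list[np.ndarray]] = {s: [] for s in RELABELED_STRATEGIES}
    init_vmr, final_vmr = [], []
    for run in runs:
        perm = _strategy_permutation(run)
        init = run.initial_degrees
        init_hists.append(np.bincount(init))
        init_vmr.append(float(init.var() / init.mean()))
        g = run.state.to_networkx()
        # relabel node strategies to C/D/Q1/Q2 before splitting
        for v in g.nodes:
            old = run.state.strat[v]
            g.nodes[v]["strategy"] = RELABELED_STRATEGIES[perm[old]]
        rep = degree_distribution(g, by_strategy=True)
        final_hists.append(rep.counts)
        final_vmr.append(rep.variance_to_mean)
        for s in RELABELED_STRATEGIES:
            if rep.per_strategy and s in rep.per_strategy:
                per[s].append(rep.per_strategy[s])
    n_runs = len(runs)
    return DegreeDistributionReport(
        initial_hist=_mean_hists(init_hists, n_runs),
        final_hist=_mean_hists(final_hists, n_runs),
        # a strategy extinct in some runs still averages over all runs,
        # so the per-strategy masses partition the population size
        final_per_strategy={s: _mean_hists(h, n_runs) for s, h in per.items() if h},
        initial_vmr=float(np.mean(init_vmr)),
        final_vmr=float(np.mean(final_vmr)),
    )


def payoff_distribution_report(
    n: int, b_values: list[float], seed: int, bins: int = 40
) -> dict[float, dict[str, tuple[np.ndarray, np.ndarray]]]:
    """Payoff histograms over strategy profiles, one set per temptation value,
    all from one seeded stream."""
    rng = np.random.default_rng(seed)
    return {float(b): sample_payoff_distribution(n, float(b), rng, bins=bins) for b in b_values}
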