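"""Synchronous coevolution step: play, Fermi imitation, trust, rewiring.

The array engine is held equal to a reference built purely from the
per-operation API (tests/_reference.py) on a 50-node fixture, and to an
independently written minimal spatial game in the no-trust limit.
"""

import math

import numpy as np
import pytest

from qcoevo import (
    STRATEGY_LABELS,
    SimulationConfig,
    SimulationState,
    StepRecord,
    detect_steady_state,
    imitate,
    imitation_probability,
    initialize,
    play_round,
    run_simulation,
    step,
)
from qcoevo.network import STRATEGY_ATTR

from _reference import minimal_spatial_game, reference_step


def make_dyad_state(payoff_table, strats=(0, 1), trust=(1.0, 1.0), b=2.0):
    return SimulationState(
        n_agents=2,
        b=b,
        edges=np.array([[0, 1]]),
        trust=np.array([list(trust)], dtype=float),
        strat=np.array(strats, dtype=np.int8),
        adj=[{1: 0}, {0: 0}],
        payoff_table=payoff_table,
    )


class TestPlayRound:
    def test_mutual_cooperation_full_trust(self):
        table = np.array([[1.0, 0.0], [2.0, 0.0]])
        table = np.pad(table, ((0, 2), (0, 2)))
        state = make_dyad_state(table, strats=(0, 0))
        play_round(state)
        np.testing.assert_allclose(state.totals, [1.0, 1.0])

    def test_half_trust_halves_actual_payoffs(self):
        table = np.pad(np.array([[1.0, 0.0], [2.0, 0.0]]), ((0, 2), (0, 2)))
        state = make_dyad_state(table, strats=(0, 0), trust=(0.5, 0.5))
        play_round(state)
        np.testing.assert_allclose(state.totals, [0.5, 0.5])

    def test_totals_are_sums_of_received_payoffs(self, rng):
        cfg = SimulationConfig(n_agents=60, b=1.8, seed=2, t_max=5)
        state = initialize(cfg, np.random.default_rng(2))
        play_round(state)
        n = state.n_agents
        manual = np.zeros(n)
        for e, (u, v) in enumerate(state.edges):
            manual[u] += state.pay_u[e]
            manual[v] += state.pay_v[e]
        np.testing.assert_allclose(state.totals, manual, atol=1e-9)
        assert np.all(state.pay_u >= -1e-12) and np.all(state.pay_u <= cfg.b + 1e-12)


class TestImitationProbability:
    def test_symmetric_point(self):
        assert imitation_probability(5.0, 5.0, lam=0.05) == 0.5

    def test_known_value(self):
        assert imitation_probability(0.0, 20.0, lam=0.05) == pytest.approx(
            1.0 / (1.0 + math.exp(-1.0)), abs=1e-12
        )

    def test_limit_without_overflow(self):
        assert imitation_probability(0.0, 1e9, lam=0.05) == 1.0
        assert imitation_probability(1e9, 0.0, lam=0.05) == 0.0

    def test_rejects_nonpositive_intensity(self):
        with pytest.raises(ValueError):
            imitation_probability(0.0, 1.0, lam=0.0)


class TestImitate:
    def test_no_adoption_when_neighbor_not_better(self):
        table = np.pad(np.array([[1.0, 0.0], [2.0, 0.0]]), ((0, 2), (0, 2)))
        state = make_dyad_state(table, strats=(1, 0))  # D vs C: totals (2w, 0)
        play_round(state)
        rng = np.random.default_rng(0)
        imitate(state, rng, lam=0.05, mode="total")
        assert state.strat[0] == 1  # the better-off defector never switches

    def test_adoption_frequency_matches_fermi(self):
        """Two-agent fixture with payoff gap 20: adoption frequency over
        10^4 trials within 3 SE of 1/(1+e^-1)."""
        table = np.zeros((4, 4))
        rng = np.random.default_rng(99)
        n_trials = 10_000
        adopted = 0
        for _ in range(n_trials):
            state = make_dyad_state(table, strats=(0, 1))
            state.totals = np.array([0.0, 20.0])
            state.degrees = np.array([1, 1])
            imitate(state, rng, lam=0.05, mode="total")
            adopted += int(state.strat[0] == 1)
        p = 1.0 / (1.0 + math.exp(-1.0))
        se = math.sqrt(p * (1 - p) / n_trials)
        assert abs(adopted / n_trials - p) < 3 * se

    def test_uniform_population_is_fixed_point(self):
        cfg = SimulationConfig(n_agents=40, b=1.5, seed=3)
        state = initialize(cfg, np.random.default_rng(3))
        state.strat[:] = 2
        play_round(state)
        imitate(state, np.random.default_rng(1), lam=0.05)
        assert np.all(state.strat == 2)


class TestStep:
    def test_rewiring_conserves_edge_count_and_changes_edge_set(self):
        cfg = SimulationConfig(n_agents=120, b=2.0, seed=8, t_max=200)
        rng = np.random.default_rng(8)
        state = initialize(cfg, rng)
        e0 = {tuple(sorted(e)) for e in state.edges.tolist()}
        changed = False
        for _ in range(120):
            state, rec = step(state, cfg, rng)
            assert rec.edge_count == len(e0)
            now = {tuple(sorted(e)) for e in state.edges.tolist()}
            assert len(now) == len(e0)  # still simple: no duplicate edges
            if now != e0:
                changed = True
        assert changed

    def test_static_variant_keeps_edge_set(self):
        cfg = SimulationConfig(n_agents=80, b=2.0, seed=4, rewiring_enabled=False)
        rng = np.random.default_rng(4)
        state = initialize(cfg, rng)
        e0 = state.edges.copy()
        for _ in range(50):
            state, _ = step(state, cfg, rng)
        np.testing.assert_array_equal(state.edges, e0)

    def test_all_cooperators_full_trust_is_invariant(self):
        """Every payoff equals every mean, so the tie rule freezes trust and
        no imitation can change anything but time."""
        cfg = SimulationConfig(n_agents=50, b=1.5, seed=5)
        rng = np.random.default_rng(5)
        state = initialize(cfg, rng)
        state.strat[:] = 0
        strat0 = state.strat.copy()
        trust0 = state.trust.copy()
        edges0 = state.edges.copy()
        for _ in range(10):
            state, _ = step(state, cfg, rng)
        np.testing.assert_array_equal(state.strat, strat0)
        np.testing.assert_array_equal(state.trust, trust0)
        np.testing.assert_array_equal(state.edges, edges0)

    def test_first_rewire_strictly_after_first_step(self):
        """Time-scale separation: strategies can change from step 1, but the
        bounded trust step (delta <= eta < 1) delays the first broken link."""
        cfg = SimulationConfig(n_agents=200, b=2.0, seed=6)
        rng = np.random.default_rng(6)
        state = initialize(cfg, rng)
        e0 = {tuple(sorted(e)) for e in state.edges.tolist()}
        state, _ = step(state, cfg, rng)
        assert {tuple(sorted(e)) for e in state.edges.tolist()} == e0
        assert np.all(state.trust > 0.0)

    def test_record_invariants_along_a_run(self):
        run = run_simulation(SimulationConfig(n_agents=150, b=1.6, seed=7, t_max=150))
        for rec in run.records:
            assert rec.frac.sum() == pytest.approx(1.0, abs=1e-9)
            assert rec.pair_frac.sum() == pytest.approx(1.0, abs=1e-9)
            finite = rec.pair_weight[~np.isnan(rec.pair_weight)]
            assert np.all((finite >= 0.0) & (finite <= 1.0))


class TestEngineMatchesReferenceOps:
    @pytest.mark.parametrize("rewiring", [True, False])
    def test_step_equals_per_operation_composition(self, rewiring):
        """The vectorized engine and the composition of the public per-op
        API (ledger updates, broken_links, resolve_rewirer, rewire,
        reset_new_link) agree exactly over 40 steps on a 50-node fixture."""
        cfg = SimulationConfig(
            n_agents=50, b=2.0, seed=21, eta=0.3, rewiring_enabled=rewiring
        )
        rng_e = np.random.default_rng(21)
        state = initialize(cfg, rng_e)
        graph = state.to_networkx()
        ledger = state.to_ledger()
        strat_of = {i: int(state.strat[i]) for i in range(50)}
        # reference replays the engine's stream from after initialization
        rng_r = np.random.default_rng(21)
        initialize(cfg, rng_r)
        for _ in range(40):
            state, _ = step(state, cfg, rng_e)
            strat_of, _ = reference_step(
                graph, ledger, state.payoff_table, strat_of, cfg, rng_r
            )
            assert strat_of == {i: int(state.strat[i]) for i in range(50)}
            assert {tuple(sorted(e)) for e in state.edges.tolist()} == {
                tuple(sorted(e)) for e in graph.edges
            }
            ref = state.to_ledger()
            for pair in ledger.directed_pairs():
                assert ledger.get(*pair) == pytest.approx(ref.get(*pair), abs=1e-12)

    def test_no_trust_limit_reduces_to_spatial_game(self):
        """With eta = 0 and no rewiring the model is a plain weighted-free
        spatial game; an independently written implementation reproduces the
        strategy trajectory exactly."""
        cfg = SimulationConfig(
            n_agents=50, b=1.8, seed=33, eta=0.0, rewiring_enabled=False
        )
        rng_e = np.random.default_rng(33)
        state = initialize(cfg, rng_e)
        graph = state.to_networkx()
        strat_of = {i: int(state.strat[i]) for i in range(50)}
        rng_r = np.random.default_rng(33)
        initialize(cfg, rng_r)
        final_ref, _ = minimal_spatial_game(
            graph, strat_of, state.payoff_table, cfg.lam, cfg.fermi_payoff_mode, rng_r, 30
        )
        for _ in range(30):
            state, _ = step(state, cfg, rng_e)
        assert final_ref == {i: int(state.strat[i]) for i in range(50)}
        assert np.all(state.trust == 1.0)


class TestSteadyState:
    @staticmethod
    def records(fracs, t_last):
        recs = []
        for k, f in enumerate(fracs):
            recs.append(
                StepRecord(
                    t=t_last - len(fracs) + 1 + k,
                    frac=np.asarray(f, dtype=float),
                    pair_frac=np.zeros(10),
                    pair_weight=np.zeros(10),
                    edge_count=1,
                )
            )
        return recs

    def test_constant_after_burnin(self):
        cfg = SimulationConfig(n_agents=10, b=1.5)
        recs = self.records([[0.25] * 4] * 10, t_last=150)
        assert detect_steady_state(recs, cfg)

    def test_not_before_burnin(self):
        cfg = SimulationConfig(n_agents=10, b=1.5)
        recs = self.records([[0.25] * 4] * 10, t_last=50)
        assert not detect_steady_state(recs, cfg)

    def test_alternating_fraction_is_not_steady(self):
        cfg = SimulationConfig(n_agents=10, b=1.5)
        fracs = [[0.0, 0.5, 0.25, 0.25], [0.5, 0.0, 0.25, 0.25]] * 5
        recs = self.records(fracs, t_last=200)
        # variance of a 0/0.5 alternation is 0.0625 >= 0.01
        assert not detect_steady_state(recs, cfg)

    def test_short_history_is_not_steady(self):
        cfg = SimulationConfig(n_agents=10, b=1.5)
        assert not detect_steady_state(self.records([[0.25] * 4] * 5, t_last=200), cfg)


class TestRunSimulation:
    def test_same_seed_identical_trajectories(self):
        cfg = SimulationConfig(n_agents=100, b=1.7, seed=13, t_max=150)
        r1 = run_simulation(cfg)
        r2 = run_simulation(cfg)
        assert len(r1.records) == len(r2.records)
        for a, b in zip(r1.records, r2.records):
            np.testing.assert_array_equal(a.frac, b.frac)
            np.testing.assert_array_equal(a.pair_frac, b.pair_frac)
        np.testing.assert_array_equal(r1.state.edges, r2.state.edges)
        np.testing.assert_array_equal(r1.state.trust, r2.state.trust)

    def test_trajectory_bounded_by_t_max(self):
        run = run_simulation(SimulationConfig(n_agents=60, b=1.5, seed=1, t_max=30))
        assert len(run.records) <= 30
        assert not run.reached_steady_state  # cannot trigger before burn-in

    def test_invalid_config_rejected_before_allocation(self):
        with pytest.raises(ValueError):
            run_simulation(SimulationConfig(n_agents=100, b=3.0))
        with pytest.raises(ValueError):
            run_simulation(SimulationConfig(n_agents=100, b=1.5, fermi_payoff_mode="median"))

    def test_state_export_round_trip(self):
        run = run_simulation(SimulationConfig(n_agents=40, b=1.5, seed=2, t_max=20))
        g = run.state.to_networkx()
        assert g.number_of_edges() == run.records[-1].edge_count
        labels = {g.nodes[v][STRATEGY_ATTR] for v in g.nodes}
        assert labels <= set(STRATEGY_LABELS)
        ledger = run.state.to_ledger()
        assert len(ledger) == 2 * g.number_of_edges()
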