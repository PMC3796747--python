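# qcoevo

Coevolution of quantum and classical strategies with adaptive degrees of
trust on scale-free networks.

## The problem

Why does cooperation survive when defection pays better?  One influential
answer is coevolution: agents do not only change their *strategies*, they
also change their *relationships*.  `qcoevo` implements an agent-based model
in which both processes run together, and in which the strategy space is the
full quantum strategy space of the Eisert–Wilkens–Lewenstein (EWL) prisoner's
dilemma rather than the classical {C, D} pair.  It is aimed at researchers in
evolutionary game theory and quantum game theory who want a reproducible,
tested implementation of this model family for simulation studies.

## The model

**The game.**  Each pair of neighbors plays the maximally entangled quantum
prisoner's dilemma.  In the EWL scheme the joint state starts in |00⟩ with
C ~ |0⟩, D ~ |1⟩, is entangled by J = exp(iγ/2 σₓ⊗σₓ) with γ = π/2, each
player applies a local unitary

U(θ, α, β) = [[e^{iα} cos(θ/2), i e^{iβ} sin(θ/2)],
              [i e^{−iβ} sin(θ/2), e^{−iα} cos(θ/2)]],
θ ∈ [0, π], α, β ∈ [−π, π],

and after disentangling (J†) a projective measurement yields outcome
probabilities over {CC, CD, DC, DD}.  The expected payoff uses the weak
prisoner's dilemma values R = 1, T = b with 1 < b ≤ 2, S = P = 0, so the
classical game is embedded exactly: C = U(0,0,0) and D = U(π,0,0) reproduce
the classical payoff matrix at γ = π/2.  Each run uses four strategies:
C, D and two quantum strategies drawn uniformly from the parameter space.

**The population.**  N agents occupy a Barabási–Albert scale-free network
(seeded with two connected nodes, each arrival attaching m = 2 links by
preferential attachment; 1 + 2(N−2) edges, conserved forever after).

**Trust.**  Every link (i, j) carries two directed degrees of trust
a(i→j), a(j→i) ∈ [0, 1], both starting at 1.  The payoff agent i actually
receives through a link is w·$ where w = [a(i→j)+a(j→i)]/2 is the link
weight and $ the quantum expected payoff.  After each round, agent i
compares the payoff received from each neighbor with the mean of all its
received payoffs and moves trust up (above average) or down (below) by
δ = η·|P(ij) − P̄ᵢ|/b, with gain η = 0.2 by default.

**Imitation.**  Each agent picks one random neighbor; if the neighbor's
(degree-averaged) payoff is strictly higher, it adopts the neighbor's
strategy with the Fermi probability 1/(1 + e^{−λΔU}), λ = 0.05.  Updates
are synchronous.

**Rewiring.**  When a directed trust hits zero, the link breaks; the
zero-trust side (a coin decides if both are at zero) rewires to a uniformly
random non-neighbor and the fresh link starts at full mutual trust.  A run
stops when every strategy's abundance has variance < 0.01 over 10
consecutive steps (after a 100-step burn-in), or after t_max = 10³ steps.

## A worked example

```python
from qcoevo import SimulationConfig, relabel_quantum, run_simulation
from qcoevo.experiments import relabeled_fractions

cfg = SimulationConfig(n_agents=1000, b=1.8, seed=3, t_max=1000)
run = relabel_quantum(run_simulation(cfg))
print(len(run.records), run.reached_steady_state)
print(relabeled_fractions(run))   # fractions of C, D, Q1, Q2
```

Running `python examples/single_run.py` (the same computation plus link-pair
statistics) prints:

```
steps simulated: 102 (steady state: True)
  final fraction C: 0.000
  final fraction D: 0.195
  final fraction Q1: 0.805
  final fraction Q2: 0.000
most common link pairs at the end (fraction, mean weight):
  Q1-Q1: 0.628, 0.769
  D-Q1: 0.322, 0.829
  D-D: 0.050, 0.735
```

Within each run the quantum strategy with the larger final abundance is
relabeled Q1.  Here, at temptation b = 1.8, the run reached the
stationarity criterion after 102 steps with the dominant quantum strategy
at 80.5% of the population and defectors at 19.5% — the characteristic
defector plateau near 20% — while most surviving links connect Q1 players
with high mutual trust.

The other scripts in `examples/` each demonstrate one capability: the bare
quantum game (`quantum_game_basics.py`), dominance-versus-temptation sweeps
for static and coevolving networks (`temptation_sweep.py`), payoff
distributions of random quantum strategies (`payoff_distributions.py`),
link-pair dynamics (`link_pair_dynamics.py`) and degree-distribution
Poissonization (`degree_poissonization.py`).  A thin CLI wraps the same
drivers: `qcoevo simulate --n 1000 --b 1.8 --seed 3 --out runs/`.

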