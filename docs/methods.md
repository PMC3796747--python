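# Methods

## Model overview

`qcoevo` simulates a finite population of N agents on an evolving network.
Three coupled processes run on different effective time scales:

1. **Game play** (every step): each pair of neighbors plays the maximally
   entangled EWL quantum prisoner's dilemma.  The payoff an agent actually
   receives through a link is the quantum expected payoff multiplied by the
   link weight (mean of the two directed trusts), so eroding trust directly
   erodes income.
2. **Strategy imitation** (every step, synchronous): Fermi-rule imitation of
   a randomly chosen neighbor, conditioned on the neighbor being strictly
   better off.
3. **Structural change** (occasional): a link breaks when a directed trust
   reaches zero, and is rewired to a random non-neighbor.  Because one trust
   update can move a value by at most η < 1, breaking a fresh link takes
   several negative evaluations; structure therefore changes more slowly
   than strategies, which is the intended separation of time scales.

## The quantum game

The EWL circuit is |ψ⟩ = J†(U_A ⊗ U_B)J|00⟩ with J = exp(iγ/2 σₓ⊗σₓ) and
the focal payoff R·p₀₀ + S·p₀₁ + T·p₁₀ + P·p₁₁ over the measurement
probabilities.  Conventions fixed here:

* U(θ,α,β) = [[e^{iα}cos(θ/2), ie^{iβ}sin(θ/2)], [ie^{−iβ}sin(θ/2),
  e^{−iα}cos(θ/2)]]; C = U(0,0,0), D = U(π,0,0).  This pairing embeds the
  classical game exactly at γ = π/2 (verified against a brute-force
  matrix-exponential oracle in the test suite); other phase conventions for
  D would change intermediate states only by global phases, which are
  ignored everywhere.
* The focal player is the first tensor factor; basis order is
  |focal, opponent⟩ with C ↔ |0⟩.  Opponent payoffs exchange S and T
  (symmetric game), which coincides with evaluating the swapped profile.
* γ defaults to π/2 (maximal entanglement) and is exposed for sensitivity
  runs on [0, π/2]; at γ = 0 the game factorizes into the classical one.
* Random quantum strategies are uniform in the parameters (θ, α, β), not
  Haar-uniform on SU(2).  Uniform-in-parameters is the natural reading of
  drawing the three angles at random over their ranges; Haar sampling would
  weight θ differently and is easy to add externally if wanted, since
  `QuantumStrategy` accepts arbitrary in-range triples.
* Payoffs are in the weak-PD parameterization R = 1, T = b ∈ (1, 2],
  S = P = 0, so all per-link payoffs lie in [0, b].

Each run touches only four strategies, so the engine caches the 4×4 focal
payoff table once per run; every simulated game is then a table lookup.

## Trust dynamics

Directed trust a(i→j) ∈ [0, 1] starts at 1 on every link (and resets to 1
on both sides of a rewired link).  After each round, with P(ij) the actual
(weight-scaled) payoff i received from j and P̄ᵢ the mean over i's
neighbors:

    a(i→j) ← clip(a(i→j) + η · (P(ij) − P̄ᵢ)/b, 0, 1).

Equivalently, trust rises by η|P−P̄|/b above the mean, falls by the same
magnitude below it, and an exact tie (including the single-neighbor case,
where the only payoff equals the mean) changes nothing.  Design choices
behind this increment:

* **Magnitude.**  The step is proportional to the absolute deviation from
  the mean and normalized by the maximum per-link payoff b, so a single
  update moves trust by at most η.  With the default η = 0.2 no link can go
  from full trust to broken in one round; a hostile link needs at least
  ⌈1/η⌉ = 5 consecutive negative evaluations, typically more because the
  deviation shrinks as weights decay.  η is a configuration key
  (`eta`); `eta = 0` disables trust adaptation entirely (fixed unit
  weights), which is the reduction used in testing.
* **The reference payoff** P̄ᵢ is the mean of the current round's received
  payoffs, including the focal link's own contribution; no history enters.
* **Asymmetry** is intrinsic: a(i→j) and a(j→i) evolve from different
  reference means and generally differ.

With rewiring disabled (the static-network variant), zero-trust links
persist; trust can recover later if the payoff ordering around an agent
changes.

## Population network and rewiring

The initial graph is grown from two connected nodes; each arriving node
attaches two links to distinct existing nodes with probability proportional
to current degree (resampling to avoid duplicates), giving exactly
1 + 2(N−2) edges and the scale-free tail (empirical variance-to-mean ratio
of degrees > 2 at N = 2000).  This differs from
`networkx.barabasi_albert_graph` only in the seed graph (K₂ here), hence
the in-package construction.

A broken link is rewired by the zero-trust side; when both directed trusts
are zero the two endpoints compete and a fair coin picks the winner.  The
new neighbor is drawn uniformly from nodes that are neither the rewirer nor
its current neighbors, the pool being evaluated after the old link is
removed (so the dropped neighbor is eligible again — a deliberate,
documented choice; excluding it would bias the draw with no qualitative
effect).  If the rewirer is adjacent to every other node the rewire is
skipped and the link retained.  Rewiring conserves the edge count and graph
simplicity; agents can become isolated and remain eligible targets.  Broken
links within a step are processed in ascending canonical edge order with
the run's single RNG stream, making whole runs bit-reproducible from the
seed.

## The coevolution step and stopping rule

Within one step the order is: play → record statistics → imitate → update
trust → break/rewire.  Statistics (strategy fractions, the 10 unordered
link-pair fractions, mean pair weights) are sampled after play and before
any mutation.  Imitation compares degree-averaged payoffs by default
(`fermi_payoff_mode="average"`); raw totals are available as `"total"`.
The average mode also enters the Fermi exponent, which with λ = 0.05 and
per-link payoffs in [0, b] makes accepted imitations nearly neutral
coin-flips — selection acts mostly through the strict "better off"
condition, and hubs gain no automatic advantage from degree alone.

A run stops early when, after a 100-step burn-in, the variance of every
strategy's fraction over the trailing 10 records is below 0.01.  On this
model the criterion usually fires at the first opportunity (fractions drift
by ≪ 0.1 per window once transients pass), so typical runs last ~100–150
steps; `t_max = 1000` is the hard cap.

## Monte Carlo protocol

Quantum labels are run-specific: each run draws two fresh random strategies,
and the one with the larger final abundance is relabeled Q1 ("topmost
curve"), ties keeping the first-drawn.  Relabeling happens per run, before
any averaging; it permutes only the two quantum indices, so C and D
statistics are unaffected.  Per-run seeds derive from the master seed via
`SeedSequence([master, counter])`, so run k of a sweep can be re-created
alone.  Time-series averaging pads runs that stopped early with their final
record.

Default study conditions are N = 5000 agents, 10³ steps and 100 runs per
setting; the bundled tests and the acceptance script use a reduced profile
(N = 1000, 20 runs per temptation, 10 for the static variant) that
reproduces the qualitative results — cooperator dominance at small b,
quantum dominance beyond the critical temptation, the ~20% defector
plateau, and degree-distribution Poissonization — with Monte Carlo error a
few percentage points wide.  Full-scale settings are plain configuration
changes.

## What the simulations do and do not show

The generator of study conditions is the model itself: all inputs are
configuration, there is no external data.  Results therefore speak to the
model's internal dynamics, not to any empirical population: trust here is a
scalar bookkeeping device updated by a fixed rule, agents are homogeneous,
and the quantum game is played noiselessly at exact maximal entanglement.
In particular:

* The trust increment is a declared surrogate: the qualitative results
  (which pairs break, the time-scale separation, the defector plateau) are
  robust across moderate η, but exact trajectories and the critical
  temptation depend on it.
* The critical b separating cooperator from quantum dominance is an
  emergent observable with run-to-run scatter at reduced N; it is reported,
  not targeted.
* Single runs frequently fixate on one strategy; the characteristic
  fractions (e.g. the defector plateau) are ensemble averages.

## Numerical choices

* Engine state is flat numpy arrays (edge list, per-edge directed trust,
  strategy codes) with an adjacency index for neighbor draws; the
  per-operation semantics live in `qcoevo.trust` / `qcoevo.network` and the
  two routes are asserted equal, update for update, in the test suite.
* Trust clipping makes zero exact, so "broken" is an exact comparison, not
  a tolerance.
* The Fermi probability uses `scipy.special.expit` (overflow-safe).
* Unitarity, state normalization and the classical embedding are tested to
  1e-10/1e-9; state comparisons are up to global phase.
* Degenerate inputs: N = 2 and N = 3 networks are the forced seed pair and
  triangle; isolated agents play nothing, earn 0 and never imitate; an
  agent adjacent to everyone skips rewiring.

## Known limitations

No asynchronous updates, population turnover, mobility, noise models or
non-maximal entanglement studies beyond the γ parameter; no second-order
trust (trust about a friend's friends); no statistical inference beyond
means and variances.  Mixed or probabilistic strategies are outside the
strategy space by construction.
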