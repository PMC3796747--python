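"""Strategy dominance versus temptation, static and coevolving.

Sweeps the temptation b on a reduced scale (N = 300, 5 runs per b) and
prints the mean final strategy fractions for both model variants: trust
adaptation on a static network versus full coevolution with rewiring.
A full-scale sweep uses N = 5000 and 100 runs via the same call.
"""

from qcoevo import SimulationConfig, sweep_b
from qcoevo.experiments import RELABELED_STRATEGIES

cfg = SimulationConfig(n_agents=300, t_max=400)
b_values = [1.05, 1.4, 1.8, 2.0]

for variant in ("static", "coevolving"):
    res = sweep_b(cfg, b_values, n_runs=5, master_seed=17, variant=variant)
    print(f"\n{variant} networks (mean final fractions over {res.n_runs} runs):")
    print("   b    " + "  ".join(f"{s:>6}" for s in RELABELED_STRATEGIES))
    for i, b in enumerate(res.b_values):
        row = "  ".join(f"{x:6.3f}" for x in res.mean_frac[i])
        print(f"  {b:4.2f}  {row}")

print(
    "\nWith rewiring, cooperators prevail at small b and Q1 takes over"
    "\nbeyond the critical temptation while defectors level off near 20%."
    "\nOn static networks a quantum strategy dominates across the b range"
    "\n(at this reduced demo scale cooperators may still edge it out at the"
    "\nvery smallest temptation; see the full-scale settings in the docs)."
)
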