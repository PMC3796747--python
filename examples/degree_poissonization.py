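"""Degree-distribution Poissonization under sustained rewiring.

Compares the degree statistics of the initial scale-free network with the
final coevolved network: random rewiring of zero-trust links erodes the
power-law tail and drives the variance-to-mean ratio toward the Poisson
regime.
"""

import numpy as np

from qcoevo import SimulationConfig, degree_distribution_report, sweep_b

cfg = SimulationConfig(n_agents=1000, t_max=1000)
res = sweep_b(cfg, [2.0], n_runs=5, master_seed=31, variant="coevolving", keep_runs=True)
rep = degree_distribution_report(res.runs[0])

print(f"initial variance-to-mean ratio: {rep.initial_vmr:.2f} (scale-free, heavy tail)")
print(f"final   variance-to-mean ratio: {rep.final_vmr:.2f} (toward Poisson)")
mode_init = int(np.argmax(rep.initial_hist))
mode_final = int(np.argmax(rep.final_hist))
print(f"modal degree: {mode_init} initially, {mode_final} after coevolution")
top = max(
    rep.final_per_strategy, key=lambda s: len(rep.final_per_strategy[s])
)
print(f"largest final degrees are held by agents playing: {top}")

print(
    "\nRewiring replaces preferential-attachment structure with random"
    "\nattachment, so the degree distribution loses its power-law tail; the"
    "\nhubs that remain belong to the locally dominant strategy."
)
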