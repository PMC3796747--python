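"""The maximally entangled quantum prisoner's dilemma, one game at a time.

Builds the EWL circuit for a few strategy profiles and prints the expected
payoffs, showing that the classical game is embedded exactly and that pure
quantum (phase) strategies can neutralize a defector.
"""

import math

from qcoevo import (
    PayoffParams,
    QuantumStrategy,
    classical_C,
    classical_D,
    expected_payoff,
)

pp = PayoffParams.from_temptation(2.0)
C, D = classical_C(), classical_D()
# the "miracle" phase strategy Q = U(0, pi/2, 0) of the restricted EWL game
Q = QuantumStrategy(0.0, math.pi / 2, 0.0, label="Q")

print(f"weak PD payoffs: R={pp.R}, T=b={pp.T}, S={pp.S}, P={pp.P}\n")
for name, (sA, sB) in {
    "C vs C": (C, C),
    "D vs C": (D, C),
    "D vs D": (D, D),
    "Q vs C": (Q, C),
    "Q vs D": (Q, D),
    "Q vs Q": (Q, Q),
}.items():
    out = expected_payoff(sA, sB, pp)
    print(f"{name}: focal {out.focal_payoff:.4f}  opponent {out.opponent_payoff:.4f}")

print(
    "\nThe four C/D profiles reproduce the classical matrix (embedding);"
    "\nQ vs D zeroes the defector's temptation payoff, which is why quantum"
    "\nstrategies can outcompete defection once entanglement is maximal."
)
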