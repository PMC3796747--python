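"""EWL-quantized 2x2 prisoner's dilemma.

The Eisert-Wilkens-Lewenstein scheme plays a symmetric 2x2 game through a
two-qubit circuit: start in |00>, entangle with J = exp(i*gamma/2 sx x sx),
let each player apply a local unitary U(theta, alpha, beta), disentangle with
J^dagger and measure in the computational basis.  Basis states encode
cooperation and defection as C ~ |0>, D ~ |1>; the first tensor factor is the
focal player.  At maximal entanglement (gamma = pi/2) the classical game is
embedded exactly: the four C/D profiles reproduce the weak prisoner's dilemma
payoff matrix R=1, T=b, S=P=0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "QuantumStrategy",
    "PayoffParams",
    "GameOutcome",
    "strategy_operator",
    "classical_C",
    "classical_D",
    "random_strategy",
    "entangler",
    "final_state",
    "expected_payoff",
    "profile_payoff_table",
    "sample_payoff_distribution",
]

_KET00 = np.array([1.0, 0.0, 0.0, 0.0], dtype=complex)


@dataclass(frozen=True)
class QuantumStrategy:
    """A point (theta, alpha, beta) in the full SU(2)-like strategy space.

    theta in [0, pi], alpha and beta in [-pi, pi].  The classical strategies
    are the endpoints C = (0, 0, 0) and D = (pi, 0, 0).
    """

    theta: float
    alpha: float
    beta: float
    label: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta <= math.pi:
            raise ValueError(f"theta must be in [0, pi], got {self.theta}")
        if not -math.pi <= self.alpha <= math.pi:
            raise ValueError(f"alpha must be in [-pi, pi], got {self.alpha}")
        if not -math.pi <= self.beta <= math.pi:
            raise ValueError(f"beta must be in [-pi, pi], got {self.beta}")


@dataclass(frozen=True)
class PayoffParams:
    """Weak prisoner's dilemma payoffs: R=1, T=b with 1 < b <= 2, S=P=0."""

    R: float = 1.0
    T: float = 1.5
    S: float = 0.0
    P: float = 0.0

    @classmethod
    def from_temptation(cls, b: float) -> "PayoffParams":
        if not 1.0 < b <= 2.0:
            raise ValueError(f"temptation b must satisfy 1 < b <= 2, got {b}")
        return cls(R=1.0, T=float(b), S=0.0, P=0.0)

    @property
    def b(self) -> float:
        return self.T


@dataclass(frozen=True)
class GameOutcome:
    """Measurement distribution over (focal, opponent) in {CC, CD, DC, DD}."""

    probs: np.ndarray = field(repr=False)
    focal_payoff: float = 0.0
    opponent_payoff: float = 0.0


def strategy_operator(s: QuantumStrategy) -> np.ndarray:
    """2x2 unitary U(theta, alpha, beta) acting on one player's qubit.

    U = [[e^{i a} cos(t/2),  i e^{i b} sin(t/2)],
         [i e^{-i b} sin(t/2), e^{-i a} cos(t/2)]]
    """
    c = math.cos(s.theta / 2.0)
    sn = math.sin(s.theta / 2.0)
    ea = np.exp(1j * s.alpha)
    eb = np.exp(1j * s.beta)
    return np.array(
        [[ea * c, 1j * eb * sn], [1j * np.conj(eb) * sn, np.conj(ea) * c]],
        dtype=complex,
    )


def classical_C() -> QuantumStrategy:
    """Cooperation: the identity operator U(0, 0, 0)."""
    return QuantumStrategy(0.0, 0.0, 0.0, label="C")


def classical_D() -> QuantumStrategy:
    """Defection: the (phase-decorated) bit flip U(pi, 0, 0) = i*sigma_x."""
    return QuantumStrategy(math.pi, 0.0, 0.0, label="D")


def random_strategy(rng: np.random.Generator, label: str | None = None) -> QuantumStrategy:
    """Draw a strategy uniform in its parameters: theta ~ U[0, pi], alpha,
    beta ~ U[-pi, pi] (uniform in parameters, not Haar on SU(2))."""
    theta = rng.uniform(0.0, math.pi)
    alpha = rng.uniform(-math.pi, math.pi)
    beta = rng.uniform(-math.pi, math.pi)
    return QuantumStrategy(theta, alpha, beta, label=label)


def entangler(gamma: float = math.pi / 2) -> np.ndarray:
    """The 4x4 entangling gate J = exp(i*gamma/2 * sigma_x (x) sigma_x).

    gamma in [0, pi/2]; gamma = 0 is the separable (classical) limit and
    gamma = pi/2 is maximal entanglement, where J|00> = (|00> + i|11>)/sqrt(2).
    Since (sx x sx)^2 = I the exponential closes: J = cos(g/2) I + i sin(g/2) sx x sx.
    """
    if not 0.0 <= gamma <= math.pi / 2:
        raise ValueError(f"gamma must be in [0, pi/2], got {gamma}")
    sxsx = np.fliplr(np.eye(4))
    return math.cos(gamma / 2.0) * np.eye(4, dtype=complex) + 1j * math.sin(gamma / 2.0) * sxsx


def final_state(
    sA: QuantumStrategy, sB: QuantumStrategy, gamma: float = math.pi / 2
) -> np.ndarray:
    """Pre-measurement state J^dagger (U_A (x) U_B) J |00>, unit norm."""
    J = entangler(gamma)
    U = np.kron(strategy_operator(sA), strategy_operator(sB))
    return J.conj().T @ (U @ (J @ _KET00))


def expected_payoff(
    sA: QuantumStrategy,
    sB: QuantumStrategy,
    payoffs: PayoffParams,
    gamma: float = math.pi / 2,
) -> GameOutcome:
    """Expected payoffs of both players from the measurement distribution.

    focal = R|<00|psi>|^2 + S|<01|psi>|^2 + T|<10|psi>|^2 + P|<11|psi>|^2;
    the opponent's payoff exchanges S and T (symmetric game).
    """
    psi = final_state(sA, sB, gamma)
    probs = np.abs(psi) ** 2
    focal = float(
        payoffs.R * probs[0] + payoffs.S * probs[1] + payoffs.T * probs[2] + payoffs.P * probs[3]
    )
    opp = float(
        payoffs.R * probs[0] + payoffs.T * probs[1] + payoffs.S * probs[2] + payoffs.P * probs[3]
    )
    return GameOutcome(probs=probs, focal_payoff=focal, opponent_payoff=opp)


def profile_payoff_table(
    strategies: list[QuantumStrategy],
    payoffs: PayoffParams,
    gamma: float = math.pi / 2,
) -> np.ndarray:
    """4x4 focal-payoff table over the run's strategy set.

    Entry (i, j) is the focal payoff of strategy_i against strategy_j; by the
    symmetry of the game the opponent's payoff in profile (i, j) is entry
    (j, i).  Caching this table means a whole simulation evaluates the quantum
    circuit only 16 times.
    """
    if len(strategies) != 4:
        raise ValueError("expected exactly the run's 4 strategies")
    table = np.empty((4, 4), dtype=float)
    for i, si in enumerate(strategies):
        for j, sj in enumerate(strategies):
            table[i, j] = expected_payoff(si, sj, payoffs, gamma).focal_payoff
    return table


def sample_payoff_distribution(
    n: int,
    b: float,
    rng: np.random.Generator,
    bins: int = 40,
    gamma: float = math.pi / 2,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Payoff distributions over strategy profiles with random quantum players.

    Draws ``n`` strategies uniform in their parameters and bins the focal
    payoffs of the profile types: Q-Q (consecutive draws paired, both sides
    focal), Q-C, C-Q, Q-D, D-Q, plus the four deterministic classical
    profiles.  Returns ``{profile_type: (bin_edges, counts)}`` with edges
    spanning the payoff range [0, b].
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    params = PayoffParams.from_temptation(b)
    C, D = classical_C(), classical_D()
    draws = [random_strategy(rng) for _ in range(n)]

    samples: dict[str, list[float]] = {k: [] for k in ("QQ", "QC", "CQ", "QD", "DQ", "CC", "CD", "DC", "DD")}
    for k in range(0, n - 1, 2):
        a, bq = draws[k], draws[k + 1]
        out = expected_payoff(a, bq, params, gamma)
        samples["QQ"].append(out.focal_payoff)
        samples["QQ"].append(out.opponent_payoff)
    for q in draws:
        vs_c = expected_payoff(q, C, params, gamma)
        vs_d = expected_payoff(q, D, params, gamma)
        samples["QC"].append(vs_c.focal_payoff)
        samples["CQ"].append(vs_c.opponent_payoff)
        samples["QD"].append(vs_d.focal_payoff)
        samples["DQ"].append(vs_d.opponent_payoff)
    for key, (x, y) in {"CC": (C, C), "CD": (C, D), "DC": (D, C), "DD": (D, D)}.items():
        samples[key].append(expected_payoff(x, y, params, gamma).focal_payoff)

    edges = np.linspace(0.0, b, bins + 1)
    out_hist: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for key, vals in samples.items():
        counts, _ = np.histogram(np.asarray(vals, dtype=float), bins=edges)
        out_hist[key] = (edges, counts)
    return out_hist
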