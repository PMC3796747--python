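"""Directed degrees of trust on links and their adaptive dynamics.

Each live edge (i, j) carries two directed trust values a(i->j), a(j->i) in
[0, 1]; their mean is the link weight that scales ("discounts") the quantum
payoff actually received through that link.  After each round an agent
compares the payoff received from each neighbor with the mean of all its
received payoffs: above-average neighbors gain trust, below-average ones
lose it, by a step proportional to the absolute deviation,

    delta = eta * |P(ij) - Pbar_i| / b,

normalized by the maximum per-link payoff b so that no single update can
drive trust from 1 to 0.  A link whose trust hits zero on either side is
broken; the zero-trust side earns the right to rewire (a fair coin decides
when both sides are at zero), and a fresh link starts at full mutual trust.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

__all__ = ["TrustLedger", "BrokenLink", "resolve_rewirer_values"]


@dataclass(frozen=True)
class BrokenLink:
    """An edge due for breaking: at least one directed trust is zero."""

    edge: tuple[int, int]
    trust_ij: float
    trust_ji: float

    @property
    def contested(self) -> bool:
        return self.trust_ij <= 0.0 and self.trust_ji <= 0.0

    @property
    def breaker(self) -> int | None:
        """The single zero-trust side, or None when contested."""
        if self.contested:
            return None
        return self.edge[0] if self.trust_ij <= 0.0 else self.edge[1]


def resolve_rewirer_values(
    i: int, j: int, a_ij: float, a_ji: float, rng: np.random.Generator
) -> int:
    """Which endpoint rewires a broken link: the zero-trust side, or a fair
    coin when both directed trusts are zero."""
    zi, zj = a_ij <= 0.0, a_ji <= 0.0
    if not (zi or zj):
        raise ValueError(f"edge ({i}, {j}) is not broken: trust ({a_ij}, {a_ji})")
    if zi and zj:
        return i if rng.random() < 0.5 else j
    return i if zi else j


class TrustLedger:
    """Map from ordered node pair (i -> j) over live edges to trust in [0, 1]."""

    def __init__(self) -> None:
        self._a: dict[tuple[int, int], float] = {}

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[int, int]], value: float = 1.0) -> "TrustLedger":
        """Initial ledger: every agent fully trusts its neighbors (a = 1)."""
        ledger = cls()
        for i, j in edges:
            ledger._a[(i, j)] = value
            ledger._a[(j, i)] = value
        return ledger

    def __len__(self) -> int:
        return len(self._a)

    def __contains__(self, pair: tuple[int, int]) -> bool:
        return pair in self._a

    def get(self, i: int, j: int) -> float:
        return self._a[(i, j)]

    def set(self, i: int, j: int, value: float) -> None:
        if (i, j) not in self._a:
            raise KeyError(f"no ledger entry for ({i}, {j})")
        self._a[(i, j)] = float(np.clip(value, 0.0, 1.0))

    def directed_pairs(self) -> list[tuple[int, int]]:
        return sorted(self._a)

    def weight(self, i: int, j: int) -> float:
        """Link weight w(ij) = (a(i->j) + a(j->i)) / 2; symmetric in i, j."""
        if (i, j) not in self._a or (j, i) not in self._a:
            raise KeyError(f"edge ({i}, {j}) has no trust entries")
        return 0.5 * (self._a[(i, j)] + self._a[(j, i)])

    def update_trust(
        self, i: int, received: Mapping[int, float], eta: float, b: float
    ) -> None:
        """Re-evaluate all of i's neighbors from this round's payoffs.

        ``received`` maps each neighbor j to the actual payoff P(ij) and must
        cover exactly i's neighborhood.  Trust moves toward the neighbor by
        eta * |P(ij) - mean| / b, up if above the mean of received payoffs,
        down if below, unchanged on an exact tie (including the single-
        neighbor case), and is clipped into [0, 1].
        """
        if eta <= 0:
            raise ValueError(f"trust gain eta must be > 0, got {eta}")
        if not received:
            return
        mean = sum(received.values()) / len(received)
        for j, pay in received.items():
            if (i, j) not in self._a:
                raise KeyError(f"received payoff from non-neighbor {j} of {i}")
            delta = eta * (pay - mean) / b
            self._a[(i, j)] = float(np.clip(self._a[(i, j)] + delta, 0.0, 1.0))

    def broken_links(self) -> list[BrokenLink]:
        """Edges where either directed trust is zero, each reported once."""
        out = []
        for (i, j), a_ij in self._a.items():
            if i < j:
                a_ji = self._a[(j, i)]
                if a_ij <= 0.0 or a_ji <= 0.0:
                    out.append(BrokenLink((i, j), a_ij, a_ji))
        return sorted(out, key=lambda bl: bl.edge)

    def resolve_rewirer(self, link: BrokenLink, rng: np.random.Generator) -> int:
        i, j = link.edge
        return resolve_rewirer_values(i, j, self._a[(i, j)], self._a[(j, i)], rng)

    def drop_edge(self, i: int, j: int) -> None:
        del self._a[(i, j)]
        del self._a[(j, i)]

    def reset_new_link(self, i: int, k: int) -> None:
        """Fresh link: both directed trusts start at the maximum, 1."""
        if (i, k) in self._a or (k, i) in self._a:
            raise ValueError(f"ledger already has entries for ({i}, {k})")
        self._a[(i, k)] = 1.0
        self._a[(k, i)] = 1.0

    def write_snapshot(self, path) -> None:
        """CSV (source, target, trust) with 0-based node ids."""
        with open(path, "w") as fh:
            fh.write("source,target,trust\n")
            for (i, j) in self.directed_pairs():
                fh.write(f"{i},{j},{self._a[(i, j)]!r}\n")
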