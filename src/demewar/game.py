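"""Game stage: random pairing within each deme and the fitness update.

Each generation every deme forms a uniform random perfect matching of
its members (one individual sits out if the size is odd) and each pair
plays exactly one round of the prisoner's dilemma.  The round payoff G
is folded into a generation-accumulated fitness

    f' = (1 - w) f + w G,

a convex combination whose iterates under a constant payoff converge to
that payoff, so fitness is bounded above by the temptation T.  With the
default w = 1/2 the n-th iterate from f0 = 0 under constant G is
G (1 - 2^-n) exactly.
"""

from __future__ import annotations

import numpy as np

from .model import ModelParams, PayoffMatrix, PopulationState, Strategy

__all__ = ["payoff_pair", "pair_deme", "update_fitness", "play_generation"]


def payoff_pair(a: Strategy, b: Strategy, payoffs: PayoffMatrix) -> tuple[float, float]:
    """Payoffs to (a, b) for one round: (C,C)->(R,R), (D,D)->(P,P), (C,D)->(S,T)."""
    tbl = payoffs.table()
    return float(tbl[int(a), int(b)]), float(tbl[int(b), int(a)])


def pair_deme(n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, int]:
    """Draw a uniform random matching of ``n`` members.

    Returns index arrays ``(a, b)`` of the floor(n/2) pairs and the index
    of the leftover individual (-1 if n is even).  Uniformity comes from
    a uniform shuffle followed by adjacent pairing.  Consumes exactly one
    ``rng.permutation(n)`` call when n >= 2, none otherwise.
    """
    if n < 2:
        return (np.empty(0, np.intp), np.empty(0, np.intp), 0 if n == 1 else -1)
    perm = rng.permutation(n)
    k = n // 2
    a = perm[0 : 2 * k : 2]
    b = perm[1 : 2 * k : 2]
    leftover = int(perm[2 * k]) if n % 2 else -1
    return a, b, leftover


def update_fitness(f_prev: float, G: float, w: float) -> float:
    """One fitness update f' = (1 - w) f + w G."""
    return (1.0 - w) * f_prev + w * G


def play_generation(
    state: PopulationState, params: ModelParams, rng: np.random.Generator
) -> PopulationState:
    """Run the game stage in every deme, in deme-id order, in place.

    Strategies and deme sizes never change here.  An unpaired individual
    keeps its fitness unless ``leftover_decay`` is set, in which case it
    takes payoff 0.
    """
    tbl = params.payoffs.table()
    w = params.w
    for s, f in zip(state.strategies, state.fitness):
        n = len(s)
        if n < 2:
            if n == 1 and params.leftover_decay:
                f[0] = (1.0 - w) * f[0]
            continue
        a, b, leftover = pair_deme(n, rng)
        ga = tbl[s[a], s[b]]
        gb = tbl[s[b], s[a]]
        f[a] = (1.0 - w) * f[a] + w * ga
        f[b] = (1.0 - w) * f[b] + w * gb
        if leftover >= 0 and params.leftover_decay:
            f[leftover] = (1.0 - w) * f[leftover]
    return state
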