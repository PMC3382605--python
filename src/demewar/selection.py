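"""Selection stage: threshold elimination, then restore carrying capacity.

Selection is strictly local to each deme and runs in two steps.  First
every individual whose fitness lies strictly below the elimination
threshold E is removed (f = E survives).  Then one of three
configurations holds:

1. the deme is exactly at capacity N0 — nothing else happens;
2. the deme exceeds N0 (possible only through migration) — the least
   fit individual is removed, repeatedly, until size N0 (ties broken
   uniformly at random);
3. the deme is below N0 but non-empty — it expands back to N0 by
   fitness-proportional (roulette-wheel) replication: each daughter
   inherits its parent's strategy but starts at fitness 0.

An emptied deme stays empty; it can only be recolonised by migration.
"""

from __future__ import annotations

import logging

import numpy as np

from .model import ModelParams, PopulationState

__all__ = [
    "eliminate_below_threshold",
    "cull_to_capacity",
    "expand_to_capacity",
    "select_generation",
]

logger = logging.getLogger(__name__)


def eliminate_below_threshold(
    s: np.ndarray, f: np.ndarray, E: float
) -> tuple[np.ndarray, np.ndarray]:
    """Remove every individual with fitness strictly below E, order preserved."""
    keep = f >= E
    if keep.all():
        return s, f
    return s[keep], f[keep]


def cull_to_capacity(
    s: np.ndarray, f: np.ndarray, N0: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Repeatedly remove a minimum-fitness individual until size N0.

    A tie among minima is broken by one ``rng.integers(n_ties)`` draw;
    a unique minimum consumes no randomness.
    """
    n = len(s)
    if n <= N0:
        raise ValueError(f"cull_to_capacity needs size > N0, got {n} <= {N0}")
    while n > N0:
        ties = np.flatnonzero(f == f.min())
        victim = ties[rng.integers(len(ties))] if len(ties) > 1 else ties[0]
        s = np.delete(s, victim)
        f = np.delete(f, victim)
        n -= 1
    return s, f


def expand_to_capacity(
    s: np.ndarray, f: np.ndarray, N0: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Fitness-proportional expansion back to N0.

    Parents are drawn with replacement from the pre-expansion survivors
    with probability proportional to fitness (negative fitness, possible
    only under user-configured S < 0 with E < 0, counts as weight 0).
    Each birth consumes one ``rng.random()`` draw — or one
    ``rng.integers(n)`` draw under the uniform fallback when every
    weight is zero.  Daughters inherit the parent's strategy, not its
    fitness: they start at 0.
    """
    n = len(s)
    if not (0 < n < N0):
        raise ValueError(f"expand_to_capacity needs 0 < size < N0, got {n}, N0={N0}")
    weights = np.maximum(f, 0.0)
    cum = np.cumsum(weights)
    total = float(cum[-1])  # sequential sum: the roulette wheel's exact span
    births = N0 - n
    if total > 0.0:
        parents = np.searchsorted(cum, rng.random(births) * total, side="right")
        parents = np.minimum(parents, n - 1)  # guard float edge at u*total == total
    else:
        logger.debug("all survivor weights zero: uniform parent choice (n=%d)", n)
        parents = rng.integers(0, n, size=births)
    s_out = np.concatenate([s, s[parents]])
    f_out = np.concatenate([f, np.zeros(births)])
    return s_out, f_out


def select_generation(
    state: PopulationState, params: ModelParams, rng: np.random.Generator
) -> PopulationState:
    """Apply elimination then capacity restoration to every deme, in id order.

    Afterwards every deme has size N0 or 0.
    """
    N0 = params.N0
    for d in range(state.n_demes):
        s, f = eliminate_below_threshold(state.strategies[d], state.fitness[d], params.E)
        n = len(s)
        if n > N0:
            s, f = cull_to_capacity(s, f, N0, rng)
        elif 0 < n < N0:
            s, f = expand_to_capacity(s, f, N0, rng)
        state.strategies[d] = s
        state.fitness[d] = f
    return state
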